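"""Synthetic ribosome-profiling worlds with planted stop codon readthrough.

The generator emits everything the pipeline consumes — transcriptome FASTA,
CDS sidecar TSV, noncoding-RNA FASTA, proteome FASTA and single-end FASTQ —
plus truth tables, so every stage of the screen can be validated by
parameter recovery.

The read model emulates 80S footprints:

* a narrow length mixture (24/25/26 nt dominant),
* footprint 5' ends placed 12 nt upstream of the decoded codon's first nt,
* per-gene frame bias around 0.80/0.15/0.05, drawn from a Dirichlet so that
  periodicity varies between genes the way it does between real genes
  (this inter-gene spread is what the screen's reference SD measures),
* a readthrough gene of efficiency ``e`` receives ISR reads at ``e`` times
  its local CDS rate, with a dwell-time weight on the canonical stop codon
  (recoding a stop is slow, so readthrough ribosomes pile up there),
* terminating ribosomes contribute a footprint at the stop codon of every
  gene, readthrough or not,
* a low uniform 3'UTR background with no frame bias,
* optional noncoding-RNA contamination and 3' adapter.

Raw reads carry three extra transcript nucleotides at the 5' end, mimicking
the low-quality bases the preprocessing step trims; after the standard
``trim5=3`` the true footprint is recovered.

Frameshift decoys receive ISR reads whose frame distribution is rotated by
+1: a periodicity test must reject these as non-readthrough.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .reads import reverse_complement
from .screen import ScreenResult
from .transcripts import TranscriptRecord, find_inframe_stop

SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in {"TAA", "TAG", "TGA"}
)

_NCRNA_CLASSES = ("rRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")


@dataclass
class SimSpec:
    """Parameters of a synthetic world.  ``seed`` is mandatory."""

    seed: int
    n_genes: int = 100
    # structure (nt); CDS/ISR lengths are rounded to whole codons
    utr5_len_range: tuple[int, int] = (30, 60)
    cds_len_range: tuple[int, int] = (300, 1800)
    isr_len_range: tuple[int, int] = (60, 300)
    utr3_len_range: tuple[int, int] = (60, 400)  # rest-of-3'UTR after the downstream stop
    #: geometry override for genes that carry planted ISR signal
    #: (readthrough, decoys, annotation collisions); None = same as above
    signal_cds_len_range: tuple[int, int] | None = None
    signal_isr_len_range: tuple[int, int] | None = None
    signal_utr3_len_range: tuple[int, int] | None = None
    # stop codon usage
    stop_weights: dict = field(
        default_factory=lambda: {"TAA": 0.36, "TAG": 0.20, "TGA": 0.44}
    )
    rt_stop_weights: dict | None = None  # stop usage of readthrough genes, if biased
    # planted events
    n_readthrough: int = 20
    efficiency_range: tuple[float, float] = (0.1, 0.8)
    n_frameshift_decoys: int = 0
    decoy_efficiency_range: tuple[float, float] = (0.3, 0.8)
    n_annotation_collisions: int = 0
    n_cds_collisions: int = 0
    plant_short_isr: int = 0
    plant_short_utr: int = 0
    plant_no_downstream_stop: int = 0
    # isoforms per gene: {count: probability}
    isoform_weights: dict = field(default_factory=lambda: {1: 1.0})
    # read model
    length_mix: dict = field(default_factory=lambda: {24: 0.25, 25: 0.40, 26: 0.35})
    frame_probs: tuple[float, float, float] = (0.80, 0.15, 0.05)
    frame_concentration: float = 200.0
    jitter_prob: float = 0.0  # +/-1 nt 5'-end jitter (imperfect digestion)
    p_site_offset: int = 12
    stop_pause_isr: float = 3.0  # dwell weight of the recoded stop codon
    # depth
    expression_mean: float = 400.0  # median CDS reads per gene (log-normal)
    expression_sigma: float = 0.6
    target_isr_depth: float | None = None  # expected ISR reads for signal genes
    expression_cap: float = 1200.0  # max CDS reads/gene when boosting for depth
    utr_bg_rate: float = 0.002  # background reads as a fraction of a gene's reads
    # contamination / adapter
    ncrna_fraction: float = 0.05
    adapter: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("SimSpec.seed is mandatory")
        for name in ("length_mix", "stop_weights"):
            total = sum(getattr(self, name).values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"SimSpec.{name} must sum to 1, got {total}")
        if not np.isclose(sum(self.frame_probs), 1.0):
            raise ValueError("frame_probs must sum to 1")
        for name in ("utr_bg_rate", "ncrna_fraction", "jitter_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"SimSpec.{name} must be in [0, 1]")
        lo, hi = self.efficiency_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("efficiency_range must be within [0, 1]")
        n_special = (
            self.n_readthrough
            + self.n_frameshift_decoys
            + self.n_annotation_collisions
            + self.n_cds_collisions
            + self.plant_short_isr
            + self.plant_short_utr
            + self.plant_no_downstream_stop
        )
        if n_special > self.n_genes:
            raise ValueError("more planted genes than n_genes")


@dataclass
class World:
    """A generated transcriptome with its companion files and truth table."""

    spec: SimSpec
    transcripts: list[TranscriptRecord]
    ncrna: dict[str, str]
    proteome: dict[str, str]
    truth: pd.DataFrame  # one row per transcript
    #: per-gene generation parameters used by the read model
    gene_params: dict[str, dict] = field(default_factory=dict, repr=False)


def _codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return "".join(SENSE_CODONS[i] for i in idx)


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _weighted_choice(rng: np.random.Generator, weights: dict):
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _len_in(rng: np.random.Generator, lo_hi: tuple[int, int], codons: bool) -> int:
    lo, hi = lo_hi
    n = int(rng.integers(lo, hi + 1))
    return (n // 3) * 3 if codons else n


def generate_world(spec: SimSpec) -> World:
    """Build the transcriptome, ncRNA set, proteome and transcript truth table.

    Gene roles are assigned in a fixed order (readthrough, frameshift decoys,
    annotation collisions, CDS collisions, curation plants, plain negatives);
    all randomness flows from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])

    roles = (
        ["readthrough"] * spec.n_readthrough
        + ["decoy"] * spec.n_frameshift_decoys
        + ["annotation_collision"] * spec.n_annotation_collisions
        + ["cds_collision"] * spec.n_cds_collisions
        + ["short_isr"] * spec.plant_short_isr
        + ["short_utr"] * spec.plant_short_utr
        + ["no_downstream_stop"] * spec.plant_no_downstream_stop
    )
    roles += ["negative"] * (spec.n_genes - len(roles))

    signal_roles = {"readthrough", "decoy", "annotation_collision"}
    transcripts: list[TranscriptRecord] = []
    truth_rows = []
    gene_params: dict[str, dict] = {}
    frame_base = np.asarray(spec.frame_probs, dtype=float)

    for gi, role in enumerate(roles):
        gene_id = f"g{gi:04d}"
        tid = f"{gene_id}.1"
        is_signal = role in signal_roles

        cds_range = (
            spec.signal_cds_len_range if is_signal and spec.signal_cds_len_range else spec.cds_len_range
        )
        isr_range = (
            spec.signal_isr_len_range if is_signal and spec.signal_isr_len_range else spec.isr_len_range
        )
        utr3_range = (
            spec.signal_utr3_len_range if is_signal and spec.signal_utr3_len_range else spec.utr3_len_range
        )

        utr5 = _rand_bases(rng, _len_in(rng, spec.utr5_len_range, codons=False))
        n_cds_codons = max(2, _len_in(rng, cds_range, codons=True) // 3)
        if role == "short_isr":
            n_isr_codons = int(rng.integers(1, 15))  # < 45 nt
        else:
            n_isr_codons = max(1, _len_in(rng, isr_range, codons=True) // 3)
        if role == "short_utr":
            utr3_len = int(rng.integers(0, 45))
        else:
            utr3_len = _len_in(rng, utr3_range, codons=False)

        stop_weights = (
            spec.rt_stop_weights
            if role == "readthrough" and spec.rt_stop_weights
            else spec.stop_weights
        )
        stop = _weighted_choice(rng, stop_weights)
        dstop = _weighted_choice(rng, spec.stop_weights)

        cds_body = "ATG" + _codons(rng, n_cds_codons - 1)
        isr = _codons(rng, n_isr_codons)
        utr3 = _rand_bases(rng, utr3_len)
        if role == "no_downstream_stop":
            # sense codons all the way to the end: no in-frame stop downstream
            tail_codons = int(rng.integers(30, 60))
            seq = utr5 + cds_body + stop + _codons(rng, tail_codons)
        else:
            seq = utr5 + cds_body + stop + isr + dstop + utr3

        cds_start = len(utr5)
        cds_stop_start = cds_start + len(cds_body)
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gene_id,
                sequence=seq,
                cds_start=cds_start,
                cds_stop_start=cds_stop_start,
            )
        )

        efficiency = 0.0
        if role == "readthrough" or role == "annotation_collision":
            lo, hi = spec.efficiency_range
            efficiency = float(rng.uniform(lo, hi))
        elif role == "decoy":
            lo, hi = spec.decoy_efficiency_range
            efficiency = float(rng.uniform(lo, hi))

        frame_probs = rng.dirichlet(frame_base * spec.frame_concentration)

        truth_rows.append(
            {
                "transcript_id": tid,
                "gene_id": gene_id,
                "role": role,
                "is_readthrough": role == "readthrough",
                "efficiency": efficiency,
                "frameshift_decoy": role == "decoy",
                "annotation_collision": role == "annotation_collision",
                "cds_collision": role == "cds_collision",
                "stop_codon": stop,
            }
        )
        gene_params[tid] = {
            "role": role,
            "efficiency": efficiency,
            "frame_probs": frame_probs,
        }

    # --- planted CDS collisions: copy a codon-aligned CDS segment of another
    # gene into the plant's ISR (the copied codons are sense codons, so the
    # ISR gains no in-frame stop and curation still sees the same geometry)
    donor_pool = [i for i, r in enumerate(roles) if r == "negative"]
    for i, role in enumerate(roles):
        if role != "cds_collision":
            continue
        donor_i = donor_pool[int(rng.integers(0, len(donor_pool)))]
        donor = transcripts[donor_i]
        plant = transcripts[i]
        n_copy_codons = 9  # 27 nt > 24 nt collision threshold
        d_codons = (donor.cds_stop_start - donor.cds_start) // 3
        d_off = donor.cds_start + 3 * int(rng.integers(1, d_codons - n_copy_codons))
        segment = donor.sequence[d_off : d_off + 3 * n_copy_codons]
        isr_start = plant.cds_stop_start + 3
        isr_len = None
        d = find_inframe_stop(plant.sequence, plant.cds_stop_start)
        isr_len = d - isr_start
        if isr_len < 3 * n_copy_codons:
            continue  # ISR too short to host the copy; leave unplanted
        p_off = isr_start + 3 * int(rng.integers(0, (isr_len - 3 * n_copy_codons) // 3 + 1))
        seq = plant.sequence
        new_seq = seq[:p_off] + segment + seq[p_off + len(segment):]
        transcripts[i] = replace(plant, sequence=new_seq)

    # --- optional second isoforms: same gene through the downstream stop,
    # different rest-of-3'UTR tail
    extra: list[TranscriptRecord] = []
    for i, rec in enumerate(list(transcripts)):
        n_iso = _weighted_choice(rng, spec.isoform_weights)
        if n_iso < 2 or roles[i] in {"no_downstream_stop"}:
            continue
        d = find_inframe_stop(rec.sequence, rec.cds_stop_start)
        if d is None:
            continue
        tail = _rand_bases(rng, _len_in(rng, spec.utr3_len_range, codons=False))
        iso = TranscriptRecord(
            transcript_id=f"{rec.gene_id}.2",
            gene_id=rec.gene_id,
            sequence=rec.sequence[: d + 3] + tail,
            cds_start=rec.cds_start,
            cds_stop_start=rec.cds_stop_start,
        )
        extra.append(iso)
        base = next(r for r in truth_rows if r["transcript_id"] == rec.transcript_id)
        truth_rows.append({**base, "transcript_id": iso.transcript_id})
        gene_params[iso.transcript_id] = dict(gene_params[rec.transcript_id])
    transcripts.extend(extra)

    # --- noncoding RNA set
    ncrna: dict[str, str] = {}
    for ci, cls in enumerate(_NCRNA_CLASSES):
        length = int(rng.integers(120, 1500))
        ncrna[f"{cls}_{ci}"] = _rand_bases(rng, length)

    # --- proteome: every gene's CDS translation; annotation-collision plants
    # additionally donate a 10-aa ISR-peptide window into another entry
    proteome: dict[str, str] = {}
    for rec in transcripts:
        if not rec.transcript_id.endswith(".1"):
            continue
        cds = rec.sequence[rec.cds_start : rec.cds_stop_start]
        proteome[f"P_{rec.gene_id}"] = str(Seq(cds).translate())
    for i, role in enumerate(roles):
        if role != "annotation_collision":
            continue
        rec = transcripts[i]
        d = find_inframe_stop(rec.sequence, rec.cds_stop_start)
        isr_pep = str(Seq(rec.sequence[rec.cds_stop_start + 3 : d]).translate())
        host_i = donor_pool[int(rng.integers(0, len(donor_pool)))]
        host_key = f"P_{transcripts[host_i].gene_id}"
        host = proteome[host_key]
        mid = len(host) // 2
        proteome[host_key] = host[:mid] + isr_pep[:10] + host[mid:]

    truth = pd.DataFrame(truth_rows)
    return World(
        spec=spec,
        transcripts=transcripts,
        ncrna=ncrna,
        proteome=proteome,
        truth=truth,
        gene_params=gene_params,
    )


READ_TRUTH_COLUMNS = ["read_id", "origin", "transcript_id", "pos5", "length"]


def generate_reads(spec: SimSpec, world: World) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit raw reads and the per-read truth table.

    Each raw read is the footprint plus three upstream transcript bases
    (trimmed away by preprocessing) plus the adapter, if one is configured.
    ``pos5`` in the truth table is the footprint 5' end after trimming.
    """
    rng = np.random.default_rng([spec.seed, 2])
    lengths = np.array(sorted(spec.length_mix), dtype=int)
    length_p = np.array([spec.length_mix[int(l)] for l in lengths], dtype=float)
    length_p /= length_p.sum()
    off = spec.p_site_offset

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple] = []
    counter = itertools.count()

    def emit(seq_full: str, origin: str, tid: str, pos5: int, length: int):
        rid = f"r{next(counter):07d}"
        reads.append((rid, seq_full))
        truth_rows.append((rid, origin, tid, pos5, length))

    def sample_reads(rec, n, codon_starts, weights, frame_probs, origin):
        """Place n footprints on decoded codons with the 5'-end geometry."""
        if n <= 0 or not codon_starts:
            return
        w = np.asarray(weights, dtype=float)
        w /= w.sum()
        picks = rng.choice(len(codon_starts), size=n, p=w)
        frames = rng.choice(3, size=n, p=frame_probs)
        lens = lengths[rng.choice(len(lengths), size=n, p=length_p)]
        if spec.jitter_prob > 0:
            jit_mask = rng.random(n) < spec.jitter_prob
            jit = rng.choice([-1, 1], size=n)
            frames = frames  # jitter applies to pos5 directly below
        else:
            jit_mask = np.zeros(n, dtype=bool)
            jit = np.zeros(n, dtype=int)
        L = len(rec.sequence)
        for k in range(n):
            pos5 = codon_starts[picks[k]] - off + int(frames[k])
            if jit_mask[k]:
                pos5 += int(jit[k])
            ln = int(lens[k])
            if pos5 < 3 or pos5 + ln > L:
                continue  # footprint would fall off the transcript
            raw = rec.sequence[pos5 - 3 : pos5 + ln]
            if spec.adapter:
                raw += spec.adapter
            emit(raw, origin, rec.transcript_id, pos5, ln)

    n_mrna_reads = 0
    for rec in world.transcripts:
        if not rec.transcript_id.endswith(".1"):
            continue  # reads are drawn once per gene, on the primary isoform
        params = world.gene_params[rec.transcript_id]
        role = params["role"]
        eff = params["efficiency"]
        frame_probs = params["frame_probs"]

        n_cds_codons = (rec.cds_stop_start - rec.cds_start) // 3
        cds_codon_starts = [rec.cds_start + 3 * c for c in range(n_cds_codons)]
        # terminating ribosomes dwell on the stop codon of every gene
        cds_positions = cds_codon_starts + [rec.cds_stop_start]
        cds_weights = [1.0] * n_cds_codons + [1.0]

        # expression: log-normal, optionally boosted so planted signal genes
        # reach the target ISR depth (capped)
        n_cds = float(
            rng.lognormal(mean=np.log(spec.expression_mean), sigma=spec.expression_sigma)
        )
        d = find_inframe_stop(rec.sequence, rec.cds_stop_start)
        if eff > 0 and d is not None and spec.target_isr_depth:
            n_isr_codons = (d - rec.cds_stop_start - 3) // 3
            w_total = spec.stop_pause_isr + n_isr_codons
            needed = spec.target_isr_depth * (n_cds_codons + 1) / (eff * w_total)
            n_cds = min(max(n_cds, needed), spec.expression_cap)
        n_cds = int(rng.poisson(n_cds))

        sample_reads(rec, n_cds, cds_positions, cds_weights, frame_probs, "CDS")
        n_gene = n_cds

        if eff > 0 and d is not None:
            n_isr_codons = (d - rec.cds_stop_start - 3) // 3
            # decoded positions: the recoded stop (pause) and the ISR codons;
            # the final footprint at the downstream stop is not emitted
            # (termination there releases the ribosome); rate = eff x local
            # CDS rate
            isr_positions = [rec.cds_stop_start] + [
                rec.cds_stop_start + 3 * (c + 1) for c in range(n_isr_codons)
            ]
            isr_weights = [spec.stop_pause_isr] + [1.0] * n_isr_codons
            local_rate = n_cds / (n_cds_codons + 1)
            n_isr = int(rng.poisson(eff * local_rate * sum(isr_weights)))
            isr_frame_probs = (
                np.asarray(frame_probs)[[2, 0, 1]] if role == "decoy" else frame_probs
            )
            sample_reads(rec, n_isr, isr_positions, isr_weights, isr_frame_probs, "ISR")
            n_gene += n_isr

        # uniform, frameless 3'UTR background downstream of the canonical stop
        n_bg = int(rng.poisson(spec.utr_bg_rate * n_gene))
        L = len(rec.sequence)
        lo = rec.cds_stop_start + 3
        for _ in range(n_bg):
            ln = int(lengths[rng.choice(len(lengths), p=length_p)])
            if L - ln <= lo:
                break
            pos5 = int(rng.integers(lo, L - ln + 1))
            if pos5 < 3:
                continue
            raw = rec.sequence[pos5 - 3 : pos5 + ln]
            if spec.adapter:
                raw += spec.adapter
            emit(raw, "UTR_bg", rec.transcript_id, pos5, ln)
        n_mrna_reads += n_gene + n_bg

    # noncoding-RNA contamination
    if spec.ncrna_fraction > 0 and world.ncrna:
        n_contam = int(round(spec.ncrna_fraction * n_mrna_reads / (1 - spec.ncrna_fraction)))
        nc_ids = sorted(world.ncrna)
        for _ in range(n_contam):
            src = nc_ids[int(rng.integers(0, len(nc_ids)))]
            seq = world.ncrna[src]
            ln = int(lengths[rng.choice(len(lengths), p=length_p)]) + 3
            if len(seq) <= ln:
                continue
            start = int(rng.integers(0, len(seq) - ln + 1))
            window = seq[start : start + ln]
            if rng.random() < 0.5:
                window = reverse_complement(window)
            raw = window + (spec.adapter or "")
            emit(raw, "ncRNA", src, -1, ln - 3)

    truth = pd.DataFrame(truth_rows, columns=READ_TRUTH_COLUMNS)
    return reads, truth


def true_alignments(read_truth: pd.DataFrame) -> pd.DataFrame:
    """Alignment table implied by the read truth (fast path for simulations).

    Equivalent to trimming and perfectly aligning the emitted reads when
    every footprint is unique in the transcriptome (``n_loci`` is set to 1).
    """
    df = read_truth[read_truth["origin"] != "ncRNA"].copy()
    df = df[["read_id", "transcript_id", "pos5", "length"]]
    df["n_loci"] = 1
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# file output (everything is plain text; byte-identical under a fixed seed)


def _write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_world(world: World, outdir) -> dict[str, str]:
    """Write transcriptome.fa, cds.tsv, ncrna.fa, proteome.fa, truth_transcripts.tsv."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcriptome": out / "transcriptome.fa",
        "cds": out / "cds.tsv",
        "ncrna": out / "ncrna.fa",
        "proteome": out / "proteome.fa",
        "truth": out / "truth_transcripts.tsv",
    }
    _write_fasta({t.transcript_id: t.sequence for t in world.transcripts}, paths["transcriptome"])
    pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "cds_start": t.cds_start,
                "cds_stop_start": t.cds_stop_start,
            }
            for t in world.transcripts
        ]
    ).to_csv(paths["cds"], sep="\t", index=False)
    _write_fasta(world.ncrna, paths["ncrna"])
    _write_fasta(world.proteome, paths["proteome"])
    world.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def write_reads(reads: list[tuple[str, str]], truth: pd.DataFrame, outdir) -> dict[str, str]:
    from pathlib import Path

    from .reads import write_fastq

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fq = out / "reads.fastq"
    tt = out / "truth_reads.tsv"
    write_fastq(reads, fq)
    truth.to_csv(tt, sep="\t", index=False)
    return {"fastq": str(fq), "read_truth": str(tt)}


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryReport:
    """Confusion summary of a screen run against the planted truth."""

    sensitivity: float
    specificity: float
    gene_sensitivity: float
    gene_specificity: float
    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int
    fn_attribution: dict
    confusion: pd.DataFrame


def evaluate_recovery(result: ScreenResult, truth: pd.DataFrame) -> RecoveryReport:
    """Score a screen result against the transcript truth table.

    Truth positives are the planted readthrough transcripts; decoys,
    annotation collisions and plain negatives all count as negatives.  A
    planted positive removed before screening (curation, no stats) counts as
    a false negative attributed to ``curation``.
    """
    calls = result.transcript_calls
    known = set(truth["transcript_id"])
    unknown = set(calls["transcript_id"]) - known
    if unknown:
        raise ValueError(f"screen result contains transcripts absent from truth: {sorted(unknown)[:5]}")

    called = dict(zip(calls["transcript_id"], calls["called"]))
    tp = fp = fn = tn = 0
    fn_attr: dict[str, int] = {}
    for row in truth.itertuples(index=False):
        pos = bool(row.is_readthrough)
        call = bool(called.get(row.transcript_id, False))
        if pos and call:
            tp += 1
        elif pos and not call:
            fn += 1
            fn_attr[_first_failure(result, row.transcript_id)] = (
                fn_attr.get(_first_failure(result, row.transcript_id), 0) + 1
            )
        elif not pos and call:
            fp += 1
        else:
            tn += 1

    gene_truth = truth.groupby("gene_id")["is_readthrough"].any()
    gene_called = (
        dict(zip(result.gene_calls["gene_id"], result.gene_calls["called"]))
        if not result.gene_calls.empty
        else {}
    )
    gtp = sum(1 for g, p in gene_truth.items() if p and gene_called.get(g, False))
    gfn = sum(1 for g, p in gene_truth.items() if p and not gene_called.get(g, False))
    gfp = sum(1 for g, p in gene_truth.items() if not p and gene_called.get(g, False))
    gtn = sum(1 for g, p in gene_truth.items() if not p and not gene_called.get(g, False))

    confusion = pd.DataFrame(
        [
            {"level": "transcript", "tp": tp, "fp": fp, "fn": fn, "tn": tn},
            {"level": "gene", "tp": gtp, "fp": gfp, "fn": gfn, "tn": gtn},
        ]
    )
    return RecoveryReport(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        gene_sensitivity=gtp / (gtp + gfn) if gtp + gfn else float("nan"),
        gene_specificity=gtn / (gtn + gfp) if gtn + gfp else float("nan"),
        n_tp=tp,
        n_fp=fp,
        n_fn=fn,
        n_tn=tn,
        fn_attribution=fn_attr,
        confusion=confusion,
    )


def _first_failure(result: ScreenResult, tid: str) -> str:
    """Attribute a false negative to the first level it failed (best dataset)."""
    from .screen import LEVELS

    best = -1
    for df in result.per_dataset.values():
        rows = df[df["transcript_id"] == tid]
        if rows.empty:
            continue
        row = rows.iloc[0]
        depth = 0
        for level in LEVELS:
            if row[level]:
                depth += 1
            else:
                break
        best = max(best, depth)
    if best < 0:
        return "curation"
    if best >= len(LEVELS):
        return "support"  # passed everywhere it was seen, lost at the combine step
    return LEVELS[best]


# ---------------------------------------------------------------------------
# canonical scenarios


def benchmark_spec(seed: int) -> SimSpec:
    """The default parameter-recovery benchmark.

    100 genes: 20 readthrough (efficiency 0.1-0.8), 10 frameshift decoys,
    5 annotation-collision plants, 65 negatives.  Signal genes use the
    screen's sensitive geometry (short CDS relative to a long ISR) and their
    expression is raised until the expected ISR depth reaches ~300 reads
    (capped), the regime the fixed count/coverage thresholds were built for.
    """
    return SimSpec(
        seed=seed,
        n_genes=100,
        n_readthrough=20,
        n_frameshift_decoys=10,
        n_annotation_collisions=5,
        signal_cds_len_range=(300, 450),
        signal_isr_len_range=(240, 300),
        signal_utr3_len_range=(350, 400),
        target_isr_depth=250.0,
        expression_cap=900.0,
        expression_mean=400.0,
    )


def tga_bias_spec(seed: int) -> SimSpec:
    """Small world with readthrough planted preferentially on TGA stops."""
    return SimSpec(
        seed=seed,
        n_genes=30,
        n_readthrough=12,
        rt_stop_weights={"TAA": 0.15, "TAG": 0.10, "TGA": 0.75},
        signal_cds_len_range=(300, 450),
        signal_isr_len_range=(240, 300),
        signal_utr3_len_range=(350, 400),
        target_isr_depth=150.0,
        expression_cap=900.0,
        expression_mean=300.0,
        ncrna_fraction=0.0,
    )
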