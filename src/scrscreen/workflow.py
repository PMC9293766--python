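"""End-to-end orchestration: curate -> align -> assign -> screen -> stats.

This is the programmatic surface behind the command-line interface; tests
and scripts drive the same functions.  Each dataset (one FASTQ) is processed
independently — trim, ncRNA depletion, perfect-match alignment, footprint
length selection, region statistics, periodicity QC — and the screen then
combines the per-dataset results into transcript- and gene-level calls.
"""

from __future__ import annotations

import hashlib
import json
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assign import RegionStats, dataset_qc, metagene_profile, region_stats_table, stats_frame
from .reads import (
    PerfectMatchIndex,
    align_perfect,
    filter_ncrna,
    length_histogram,
    read_fastq,
    select_top_lengths,
    trim_reads,
)
from .screen import ProteomeIndex, ScreenConfig, ScreenResult, density_summary, run_screen
from .transcripts import CuratedTranscript, curate_transcriptome, curated_table, load_transcripts


@dataclass
class DatasetResult:
    """Per-dataset pipeline products and bookkeeping."""

    name: str
    alignments: pd.DataFrame
    counts: Counter
    selected_lengths: set[int]
    stats: dict[str, RegionStats]
    periodicity_scores: dict[int, float]
    qc_pass: bool

    @property
    def n_input_reads(self) -> int:
        return (
            self.counts["aligned"]
            + self.counts["unaligned"]
            + self.counts["ncrna_removed"]
            + self.counts["length_dropped"]
            + self.counts["malformed"]
        )


@dataclass
class RunResult:
    curated: list[CuratedTranscript]
    datasets: dict[str, DatasetResult]
    screen: ScreenResult | None
    manifest: dict = field(default_factory=dict)


def curate_from_files(fasta, cds_tsv, cfg: ScreenConfig) -> list[CuratedTranscript]:
    records = load_transcripts(fasta, cds_tsv)
    return curate_transcriptome(
        records, min_region_len=cfg.min_region_len, collision_len=cfg.collision_len
    )


def process_dataset(
    name: str,
    fastq,
    curated: list[CuratedTranscript],
    ncrna: dict[str, str] | None,
    cfg: ScreenConfig,
    adapter: str | None = None,
    trim5: int = 3,
    index: PerfectMatchIndex | None = None,
) -> DatasetResult:
    """Run one FASTQ through trim, ncRNA depletion, alignment and statistics."""
    counts: Counter = Counter()
    usable = [t for t in curated if t.passes_curation]
    stream = read_fastq(fastq, counts=counts)
    stream = trim_reads(stream, adapter=adapter, trim5=trim5, counts=counts)
    if ncrna:
        stream = filter_ncrna(stream, ncrna, counts=counts)
    alignments = align_perfect(stream, usable, counts=counts, index=index)

    hist = length_histogram(alignments)
    lengths = select_top_lengths(hist, k=cfg.top_k_lengths) if hist else set()
    selected = (
        alignments[alignments["length"].isin(lengths)] if lengths else alignments.iloc[0:0]
    )
    _, scores = metagene_profile(selected, usable)
    stats = region_stats_table(alignments, usable, lengths or None)
    return DatasetResult(
        name=name,
        alignments=alignments,
        counts=counts,
        selected_lengths=lengths,
        stats=stats,
        periodicity_scores=scores,
        qc_pass=dataset_qc(scores, cfg.qc_min_score),
    )


def screen_datasets(
    datasets: dict[str, DatasetResult],
    curated: list[CuratedTranscript],
    cfg: ScreenConfig,
    proteome: dict[str, str] | None = None,
    eliminate_ids: set[str] | None = None,
) -> ScreenResult:
    """Apply the four-level screen over all QC-passing datasets."""
    usable = [t for t in curated if t.passes_curation]
    passing = {n: d.stats for n, d in datasets.items() if d.qc_pass}
    if not passing:
        raise ValueError("no dataset passes the periodicity QC")
    pindex = ProteomeIndex(proteome, window=cfg.peptide_min_len) if proteome else None
    return run_screen(
        passing, usable, cfg, proteome=pindex, eliminate_ids=eliminate_ids
    )


def run_pipeline_files(
    fasta,
    cds_tsv,
    fastqs: dict[str, str],
    cfg: ScreenConfig,
    ncrna: dict[str, str] | None = None,
    proteome: dict[str, str] | None = None,
    adapter: str | None = None,
    trim5: int = 3,
) -> RunResult:
    """File-level end-to-end run over one or more FASTQ datasets."""
    t0 = time.time()
    curated = curate_from_files(fasta, cds_tsv, cfg)
    usable = [t for t in curated if t.passes_curation]
    index = PerfectMatchIndex(usable)
    datasets = {
        name: process_dataset(
            name, path, curated, ncrna, cfg, adapter=adapter, index=index
        )
        for name, path in fastqs.items()
    }
    screen = screen_datasets(datasets, curated, cfg, proteome=proteome)
    manifest = build_manifest(
        cfg,
        inputs={"transcriptome": fasta, "cds": cds_tsv, **fastqs},
        curated=curated,
        datasets=datasets,
        screen=screen,
        elapsed=time.time() - t0,
    )
    return RunResult(curated=curated, datasets=datasets, screen=screen, manifest=manifest)


def run_simulated(spec, cfg: ScreenConfig | None = None, fast: bool = True):
    """Generate a synthetic world and screen it; returns (RunResult-like, world).

    With ``fast=True`` the emitted reads are converted directly to their true
    alignments (no FASTQ round-trip, trimming or alignment search) — the fast
    path for replicate studies.  With ``fast=False`` everything goes through
    the file-level pipeline in a temporary directory.
    """
    from .simulate import generate_reads, generate_world, true_alignments, write_reads, write_world

    cfg = cfg or ScreenConfig()
    world = generate_world(spec)
    if not fast:
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            reads, read_truth = generate_reads(spec, world)
            pw = write_world(world, tmp)
            pr = write_reads(reads, read_truth, tmp)
            result = run_pipeline_files(
                pw["transcriptome"], pw["cds"], {"sim": pr["fastq"]}, cfg,
                ncrna=world.ncrna, proteome=world.proteome, adapter=spec.adapter,
            )
        return result, world

    _, read_truth = generate_reads(spec, world)
    alignments = true_alignments(read_truth)
    curated = curate_transcriptome(
        [t for t in world.transcripts],
        min_region_len=cfg.min_region_len,
        collision_len=cfg.collision_len,
    )
    usable = [t for t in curated if t.passes_curation]
    hist = length_histogram(alignments)
    lengths = select_top_lengths(hist, k=cfg.top_k_lengths) if hist else set()
    selected = alignments[alignments["length"].isin(lengths)] if lengths else alignments
    _, scores = metagene_profile(selected, usable)
    stats = region_stats_table(alignments, usable, lengths or None)
    dataset = DatasetResult(
        name="sim",
        alignments=alignments,
        counts=Counter({"aligned": alignments["read_id"].nunique()}),
        selected_lengths=lengths,
        stats=stats,
        periodicity_scores=scores,
        qc_pass=dataset_qc(scores, cfg.qc_min_score),
    )
    screen = screen_datasets({"sim": dataset}, curated, cfg, proteome=world.proteome)
    return RunResult(curated=curated, datasets={"sim": dataset}, screen=screen), world


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(cfg, inputs, curated, datasets, screen, elapsed) -> dict:
    from .screen import config_dict

    return {
        "tool": "scr-screen",
        "version": __version__,
        "config": config_dict(cfg),
        "inputs": {name: {"path": str(p), "sha256": _checksum(p)} for name, p in inputs.items()},
        "elapsed_s": round(elapsed, 3),
        "counts": {
            "transcripts": len(curated),
            "curated_pass": sum(t.passes_curation for t in curated),
            **{
                name: dict(d.counts) | {"n_input_reads": d.n_input_reads}
                for name, d in datasets.items()
            },
        },
        "qc": {name: {"scores": d.periodicity_scores, "pass": d.qc_pass} for name, d in datasets.items()},
        "positives": screen.positive_transcripts if screen else [],
    }


def write_outputs(result: RunResult, outdir) -> dict[str, str]:
    """Write the screen report bundle (TSVs + JSON manifest)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ct = curated_table(result.curated)
    paths["curated"] = str(out / "curated_transcripts.tsv")
    ct.to_csv(paths["curated"], sep="\t", index=False)

    for name, d in result.datasets.items():
        p = out / f"alignments_{name}.tsv"
        d.alignments.to_csv(p, sep="\t", index=False)
        paths[f"alignments_{name}"] = str(p)
        sp = out / f"region_stats_{name}.tsv"
        stats_frame(d.stats).to_csv(sp, sep="\t", index=False)
        paths[f"region_stats_{name}"] = str(sp)

    if result.screen is not None:
        for name, df in result.screen.per_dataset.items():
            p = out / f"screen_{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths[f"screen_{name}"] = str(p)
        paths["transcript_calls"] = str(out / "transcript_calls.tsv")
        result.screen.transcript_calls.to_csv(paths["transcript_calls"], sep="\t", index=False)
        paths["gene_calls"] = str(out / "gene_calls.tsv")
        result.screen.gene_calls.to_csv(paths["gene_calls"], sep="\t", index=False)
        paths["funnel"] = str(out / "funnel.tsv")
        result.screen.funnel.to_csv(paths["funnel"], sep="\t", index=False)
        first = next(iter(result.screen.per_dataset))
        paths["density_summary"] = str(out / "density_summary.tsv")
        density_summary(result.screen, first).to_csv(paths["density_summary"], sep="\t", index=False)

    manifest_path = out / "manifest.json"
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    tmp.rename(manifest_path)  # atomic publish
    paths["manifest"] = str(manifest_path)
    return paths
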