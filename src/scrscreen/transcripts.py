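"""Transcript model and transcriptome curation.

Everything operates in transcript (cDNA) space with 0-based, half-open
coordinates.  A transcript is described by its sense-strand sequence plus the
position of the start codon and of the canonical stop codon.  Curation locates
the first downstream in-frame stop codon, which bounds the interstop codon
region (ISR), and applies the rejection filters:

* no downstream in-frame stop codon,
* ISR shorter than 45 nt, or rest-of-3'UTR shorter than 45 nt,
* ISR sharing an exact sense-strand substring of more than 24 nt with the
  CDS of another gene's transcript (reads could not be placed uniquely),
* ISR with more than 10% ambiguous (N) bases.

Transcripts failing any filter are kept in the output with their rejection
reasons recorded, so that every input record is accounted for.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: curation rejection reasons
FLAG_NO_DOWNSTREAM_STOP = "no_downstream_stop"
FLAG_SHORT_ISR = "short_isr"
FLAG_SHORT_3UTR = "short_3utr"
FLAG_CDS_COLLISION = "cds_collision"
FLAG_AMBIGUOUS_ISR = "ambiguous_isr"


class CurationError(ValueError):
    """Raised on malformed transcript annotations."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with CDS coordinates.

    ``cds_start`` is the 0-based index of the first nt of the start codon;
    ``cds_stop_start`` the 0-based index of the first nt of the canonical
    stop codon.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_stop_start: int

    def validate(self, require_atg: bool = True) -> None:
        seq = self.sequence
        if not (0 <= self.cds_start < self.cds_stop_start):
            raise CurationError(
                f"{self.transcript_id}: invalid CDS coordinates "
                f"({self.cds_start}, {self.cds_stop_start})"
            )
        if (self.cds_stop_start - self.cds_start) % 3 != 0:
            raise CurationError(f"{self.transcript_id}: CDS length not a multiple of 3")
        if self.cds_stop_start + 3 > len(seq):
            raise CurationError(f"{self.transcript_id}: stop codon extends past sequence end")
        stop = seq[self.cds_stop_start : self.cds_stop_start + 3]
        if stop not in STOP_CODONS:
            raise CurationError(f"{self.transcript_id}: canonical stop codon is {stop!r}")
        if require_atg and seq[self.cds_start : self.cds_start + 3] != "ATG":
            raise CurationError(f"{self.transcript_id}: CDS does not begin with ATG")

    @property
    def cds_length(self) -> int:
        """CDS length in nt, excluding the stop codon."""
        return self.cds_stop_start - self.cds_start


@dataclass(frozen=True)
class CuratedTranscript:
    """A transcript with ISR/3'UTR coordinates and curation flags.

    ``isr_start``/``isr_end_exclusive`` bound the ISR (whole codons between
    the canonical stop and the downstream in-frame stop);
    ``rest3utr_start`` is the first nt after the downstream stop.  For
    transcripts without a downstream in-frame stop these are ``None`` and the
    ``no_downstream_stop`` flag is set.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_stop_start: int
    isr_start: int | None = None
    isr_end_exclusive: int | None = None
    rest3utr_start: int | None = None
    curation_flags: frozenset = field(default_factory=frozenset)

    @property
    def cds_length(self) -> int:
        return self.cds_stop_start - self.cds_start

    @property
    def isr_length(self) -> int:
        if self.isr_start is None:
            return 0
        return self.isr_end_exclusive - self.isr_start

    @property
    def rest3utr_length(self) -> int:
        if self.rest3utr_start is None:
            return 0
        return len(self.sequence) - self.rest3utr_start

    @property
    def canonical_stop_codon(self) -> str:
        return self.sequence[self.cds_stop_start : self.cds_stop_start + 3]

    @property
    def passes_curation(self) -> bool:
        return not self.curation_flags


def find_inframe_stop(sequence: str, cds_stop_start: int) -> int | None:
    """Locate the first in-frame stop codon downstream of the canonical stop.

    Scans codon by codon starting at ``cds_stop_start + 3``; a trailing
    partial codon is ignored.  Returns the 0-based index of the first nt of
    the downstream stop, or ``None`` if there is none.
    """
    if cds_stop_start < 0 or cds_stop_start + 3 > len(sequence):
        raise CurationError(f"stop codon index {cds_stop_start} out of range")
    if sequence[cds_stop_start : cds_stop_start + 3] not in STOP_CODONS:
        raise CurationError(
            f"no stop codon at index {cds_stop_start}: "
            f"{sequence[cds_stop_start:cds_stop_start + 3]!r}"
        )
    for i in range(cds_stop_start + 3, len(sequence) - 2, 3):
        if sequence[i : i + 3] in STOP_CODONS:
            return i
    return None


def _cds_kmer_index(records: list[TranscriptRecord], k: int) -> dict[str, set]:
    """Map every k-mer occurring in any CDS (stop codon included) to gene ids."""
    index: dict[str, set] = {}
    for rec in records:
        cds = rec.sequence[rec.cds_start : rec.cds_stop_start + 3]
        for i in range(len(cds) - k + 1):
            kmer = cds[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, set()).add(rec.gene_id)
    return index


def curate_transcriptome(
    records: list[TranscriptRecord],
    min_region_len: int = 45,
    collision_len: int = 24,
    exclude_same_gene: bool = True,
    max_isr_n_frac: float = 0.10,
    require_atg: bool = True,
) -> list[CuratedTranscript]:
    """Apply the curation filters to a transcriptome.

    Every input record appears exactly once in the output, in input order,
    with its rejection reasons (possibly none) recorded.  The CDS-collision
    filter flags a transcript whose ISR shares an exact substring longer than
    ``collision_len`` nt (i.e. >=25 nt by default) with the CDS of another
    transcript; with ``exclude_same_gene`` (default) CDSs of the same gene do
    not count, so that alternative-3'UTR isoforms do not self-collide.
    """
    seen: set[str] = set()
    for rec in records:
        if rec.transcript_id in seen:
            raise CurationError(f"duplicate transcript_id {rec.transcript_id!r}")
        seen.add(rec.transcript_id)
        rec.validate(require_atg=require_atg)

    k = collision_len + 1
    cds_index = _cds_kmer_index(records, k)

    out: list[CuratedTranscript] = []
    for rec in records:
        flags: set[str] = set()
        dstop = find_inframe_stop(rec.sequence, rec.cds_stop_start)
        if dstop is None:
            out.append(
                CuratedTranscript(
                    transcript_id=rec.transcript_id,
                    gene_id=rec.gene_id,
                    sequence=rec.sequence,
                    cds_start=rec.cds_start,
                    cds_stop_start=rec.cds_stop_start,
                    curation_flags=frozenset({FLAG_NO_DOWNSTREAM_STOP}),
                )
            )
            continue

        isr_start = rec.cds_stop_start + 3
        isr_seq = rec.sequence[isr_start:dstop]
        rest_start = dstop + 3
        rest_len = len(rec.sequence) - rest_start

        if len(isr_seq) < min_region_len:
            flags.add(FLAG_SHORT_ISR)
        if rest_len < min_region_len:
            flags.add(FLAG_SHORT_3UTR)
        if isr_seq and isr_seq.count("N") / len(isr_seq) > max_isr_n_frac:
            flags.add(FLAG_AMBIGUOUS_ISR)

        for i in range(len(isr_seq) - k + 1):
            kmer = isr_seq[i : i + k]
            if "N" in kmer:
                continue
            genes = cds_index.get(kmer)
            if genes and (genes - {rec.gene_id} if exclude_same_gene else genes):
                flags.add(FLAG_CDS_COLLISION)
                break

        out.append(
            CuratedTranscript(
                transcript_id=rec.transcript_id,
                gene_id=rec.gene_id,
                sequence=rec.sequence,
                cds_start=rec.cds_start,
                cds_stop_start=rec.cds_stop_start,
                isr_start=isr_start,
                isr_end_exclusive=dstop,
                rest3utr_start=rest_start,
                curation_flags=frozenset(flags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_transcript_fasta(path) -> dict[str, str]:
    """Read a transcriptome FASTA into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_cds_table(path) -> pd.DataFrame:
    """Read the CDS sidecar TSV (transcript_id, gene_id, cds_start, cds_stop_start)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    required = {"transcript_id", "gene_id", "cds_start", "cds_stop_start"}
    missing = required - set(df.columns)
    if missing:
        raise CurationError(f"CDS table missing columns: {sorted(missing)}")
    return df


def load_transcripts(fasta_path, cds_tsv_path) -> list[TranscriptRecord]:
    """Combine a FASTA and its CDS sidecar TSV into transcript records."""
    seqs = read_transcript_fasta(fasta_path)
    table = read_cds_table(cds_tsv_path)
    records = []
    for row in table.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise CurationError(f"{row.transcript_id}: in CDS table but not in FASTA")
        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                sequence=seqs[row.transcript_id],
                cds_start=int(row.cds_start),
                cds_stop_start=int(row.cds_stop_start),
            )
        )
    return records


def curated_table(curated: list[CuratedTranscript]) -> pd.DataFrame:
    """Tabulate curation results (one row per input transcript)."""
    rows = []
    for t in curated:
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "stop_codon": t.canonical_stop_codon,
                "cds_start": t.cds_start,
                "cds_stop_start": t.cds_stop_start,
                "isr_start": t.isr_start if t.isr_start is not None else -1,
                "isr_length": t.isr_length,
                "rest3utr_length": t.rest3utr_length,
                "flags": ",".join(sorted(t.curation_flags)),
                "passes": t.passes_curation,
            }
        )
    return pd.DataFrame(rows)


def cds_table_from_gff3(path) -> pd.DataFrame:
    """Convenience: derive the CDS sidecar table from a transcript-space GFF3.

    Expects CDS features whose seqid is the transcript id, with the gene id in
    a ``gene_id`` or ``Parent`` attribute.  Coordinates are converted from
    GFF3 1-based inclusive to 0-based.  Genome-coordinate (spliced) GFF3 is
    out of scope.
    """
    rows = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "CDS":
                continue
            seqid, start, end = parts[0], int(parts[3]), int(parts[4])
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("gene_id") or attrs.get("Parent") or seqid
            cur = rows.setdefault(seqid, [seqid, gene, start - 1, end])
            cur[2] = min(cur[2], start - 1)
            cur[3] = max(cur[3], end)
    out = pd.DataFrame(
        rows.values(), columns=["transcript_id", "gene_id", "cds_start", "cds_end"]
    )
    # GFF3 CDS includes the stop codon; the canonical stop starts 3 nt before the end
    out["cds_stop_start"] = out["cds_end"] - 3
    return out[["transcript_id", "gene_id", "cds_start", "cds_stop_start"]]
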