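"""Read preprocessing and perfect-match transcriptome alignment.

Footprints are trimmed (adapter, then a fixed 5' trim), depleted of reads
matching noncoding RNA, and placed on the curated transcriptome by exact
substring search.  The screen discards any alignment with a mismatch, so a
k-mer-seeded perfect-match search is a faithful replacement for a general
aligner: every reported placement is an exact sense-strand substring match,
and every such match is reported.

Bookkeeping is explicit: every input read ends up in exactly one of
``aligned``, ``unaligned``, ``ncrna_removed``, ``length_dropped`` or
``malformed``, so pipelines can assert read conservation.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .transcripts import CuratedTranscript

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path, counts: Counter | None = None) -> Iterator[Read]:
    """Stream a FASTQ file (gz-transparent); malformed records are skipped and counted."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if (
                not header.startswith("@")
                or not plus.startswith("+")
                or not seq
                or len(qual) != len(seq)
            ):
                if counts is not None:
                    counts["malformed"] += 1
                continue
            yield Read(header[1:].split()[0], seq.upper())


def write_fastq(reads: Iterable[tuple[str, str]], path) -> int:
    """Write (id, sequence) pairs as FASTQ with uniform quality; returns count."""
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def trim_reads(
    reads: Iterable[Read],
    adapter: str | None = None,
    trim5: int = 3,
    min_len: int = 18,
    counts: Counter | None = None,
) -> Iterator[Read]:
    """Adapter-truncate, 5'-trim, and length-filter reads.

    If an adapter is given, the read is truncated at the leftmost exact
    occurrence of the adapter's first 10 nt (the full adapter if shorter).
    Then ``trim5`` nt are removed from the 5' end; the 5'-most bases of
    ribosome-profiling reads are of low quality and are dropped uniformly.
    Reads shorter than ``min_len`` after trimming are dropped and counted.
    """
    if trim5 < 0:
        raise ValueError("trim5 must be >= 0")
    probe = adapter[:10] if adapter else None
    for read in reads:
        seq = read.sequence
        if probe:
            hit = seq.find(probe)
            if hit >= 0:
                seq = seq[:hit]
        seq = seq[trim5:]
        if len(seq) < min_len:
            if counts is not None:
                counts["length_dropped"] += 1
            continue
        yield Read(read.read_id, seq)


def filter_ncrna(
    reads: Iterable[Read],
    ncrna: dict[str, str] | list[str],
    counts: Counter | None = None,
) -> Iterator[Read]:
    """Remove reads occurring exactly within any noncoding RNA (either strand).

    ``ncrna`` maps class labels (e.g. ``rRNA``) to sequences, or is a plain
    list; per-class removal counts are recorded when labels are given.
    """
    if isinstance(ncrna, dict):
        items = list(ncrna.items())
    else:
        items = [("ncRNA", s) for s in ncrna]
    if not items:
        for read in reads:
            yield read
        return
    # one concatenated haystack per strand; '#' separators prevent junction hits
    labels, seqs = zip(*items)
    fwd = "#".join(seqs)
    rev = "#".join(reverse_complement(s) for s in seqs)
    for read in reads:
        if read.sequence in fwd or read.sequence in rev:
            if counts is not None:
                counts["ncrna_removed"] += 1
                for label, seq in items:
                    if read.sequence in seq or read.sequence in reverse_complement(seq):
                        counts[f"ncrna_removed:{label}"] += 1
                        break
            continue
        yield read


class PerfectMatchIndex:
    """k-mer-seeded exact-match index over a set of transcripts.

    Seeds on the first ``k`` nt of a read and verifies the full read against
    the transcript, so the result set equals a brute-force substring search
    for any read of length >= k.
    """

    def __init__(self, transcripts: list[CuratedTranscript], k: int = 18):
        self.k = k
        self.transcripts = transcripts
        self._seqs = [t.sequence for t in transcripts]
        self._ids = [t.transcript_id for t in transcripts]
        index: dict[str, list[tuple[int, int]]] = {}
        for ti, seq in enumerate(self._seqs):
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((ti, i))
        self._index = index

    def placements(self, seq: str) -> list[tuple[str, int]]:
        """All (transcript_id, pos5) perfect placements of ``seq``."""
        if len(seq) < self.k:
            return []
        hits = []
        n = len(seq)
        for ti, pos in self._index.get(seq[: self.k], ()):
            if self._seqs[ti][pos : pos + n] == seq:
                hits.append((self._ids[ti], pos))
        return hits


ALIGNMENT_COLUMNS = ["read_id", "transcript_id", "pos5", "length", "n_loci"]


def align_perfect(
    reads: Iterable[Read],
    transcripts: list[CuratedTranscript],
    kmer: int = 18,
    counts: Counter | None = None,
    index: PerfectMatchIndex | None = None,
) -> pd.DataFrame:
    """Place reads on transcripts by exact substring match (zero mismatches).

    Returns one row per placement; ``n_loci`` is the number of placements of
    that read across the whole transcriptome.  Reads with no placement are
    counted as ``unaligned``.
    """
    if index is None:
        index = PerfectMatchIndex(transcripts, k=kmer)
    rows = []
    for read in reads:
        hits = index.placements(read.sequence)
        if not hits:
            if counts is not None:
                counts["unaligned"] += 1
            continue
        if counts is not None:
            counts["aligned"] += 1
        n_loci = len(hits)
        for tid, pos in hits:
            rows.append((read.read_id, tid, pos, len(read.sequence), n_loci))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def length_histogram(alignments: pd.DataFrame) -> Counter:
    """Aligned-read length distribution (each read counted once, multi-locus included)."""
    if alignments.empty:
        return Counter()
    per_read = alignments.drop_duplicates("read_id")
    return Counter(dict(per_read["length"].value_counts()))


def select_top_lengths(hist: Counter, k: int = 3) -> set[int]:
    """The k most abundant read lengths; ties broken toward the shorter length."""
    if not hist:
        raise ValueError("empty length histogram")
    ranked = sorted(hist.items(), key=lambda kv: (-kv[1], kv[0]))
    return {length for length, _ in ranked[:k]}


def alignments_from_sam(path, transcripts: list[CuratedTranscript]) -> pd.DataFrame:
    """Import transcript-space alignments from SAM, keeping zero-mismatch hits only.

    Escape hatch for externally produced alignments; the NM tag (fallback:
    sequence re-verification) enforces the zero-mismatch rule.
    """
    import pysam

    seqs = {t.transcript_id: t.sequence for t in transcripts}
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_reverse:
                continue
            tid = rec.reference_name
            if tid not in seqs:
                continue
            seq = rec.query_sequence or ""
            if rec.has_tag("NM"):
                if rec.get_tag("NM") != 0:
                    continue
            if seqs[tid][rec.reference_start : rec.reference_start + len(seq)] != seq:
                continue
            rows.append((rec.query_name, tid, rec.reference_start, len(seq), 1))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    if not df.empty:
        df["n_loci"] = df.groupby("read_id")["read_id"].transform("size")
    return df


def verify_alignments(
    alignments: pd.DataFrame,
    transcripts: list[CuratedTranscript],
    sample: int = 1000,
    seed: int = 0,
) -> None:
    """Assert sequence identity for a random sample of alignments (paranoia pass)."""
    import numpy as np

    if alignments.empty:
        return
    seqs = {t.transcript_id: t.sequence for t in transcripts}
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(alignments), size=min(sample, len(alignments)), replace=False)
    sub = alignments.iloc[idx]
    for row in sub.itertuples(index=False):
        frag = seqs[row.transcript_id][row.pos5 : row.pos5 + row.length]
        if len(frag) != row.length:
            raise AssertionError(f"alignment past transcript end: {row}")
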