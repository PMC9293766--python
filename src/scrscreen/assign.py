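"""Region/frame assignment of aligned footprints and per-region statistics.

A footprint is assigned to a region by its 5'-end position alone, using
fixed windows that keep a deliberate 9-position gap between regions so that
no read is ambiguous (the ~12 nt 5'-end-to-P-site offset of 80S footprints
motivates the bounds):

* CDS window:   ``[cds_start - 12,  cds_stop_start - 22]``
* ISR window:   ``[cds_stop_start - 12,  downstream_stop - 22]``
* 3'UTR window: ``[downstream_stop - 12,  transcript end]``

All bounds are inclusive on the 5'-end position.  Reads falling in the gaps
are reported as unassigned, never silently dropped.  Densities are computed
over the biological region lengths (CDS, ISR, rest-of-3'UTR), not over the
window lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transcripts import CuratedTranscript

REGIONS = ("CDS", "ISR", "UTR")

#: 5'-end window offsets: lower bound is 12 nt upstream of the region's first
#: codon, upper bound is the 22nd nt upstream of the region's closing stop.
UPSTREAM_MARGIN = 12
DOWNSTREAM_MARGIN = 22


@dataclass(frozen=True)
class RegionWindows:
    """Inclusive 5'-end windows for one curated transcript."""

    cds: tuple[int, int]
    isr: tuple[int, int]
    utr: tuple[int, int]

    @classmethod
    def for_transcript(cls, t: CuratedTranscript) -> "RegionWindows":
        if t.isr_start is None:
            raise ValueError(f"{t.transcript_id}: not curated (no downstream stop)")
        return cls(
            cds=(t.cds_start - UPSTREAM_MARGIN, t.cds_stop_start - DOWNSTREAM_MARGIN),
            isr=(t.cds_stop_start - UPSTREAM_MARGIN, t.isr_end_exclusive - DOWNSTREAM_MARGIN),
            utr=(t.isr_end_exclusive - UPSTREAM_MARGIN, len(t.sequence) - 1),
        )


def assign_region(pos5: int, t: CuratedTranscript) -> str | None:
    """Region label for a footprint 5'-end position, or ``None`` if unassigned."""
    w = RegionWindows.for_transcript(t)
    if w.cds[0] <= pos5 <= w.cds[1]:
        return "CDS"
    if w.isr[0] <= pos5 <= w.isr[1]:
        return "ISR"
    if w.utr[0] <= pos5 <= w.utr[1]:
        return "UTR"
    return None


def assign_frame(pos5: int, t: CuratedTranscript) -> int:
    """Reading frame of a 5'-end position relative to the start codon."""
    return (pos5 - t.cds_start) % 3


@dataclass
class RegionStats:
    """Per-region read statistics for one transcript (selected lengths only)."""

    transcript_id: str
    n_reads: dict[str, int]
    density: dict[str, float]
    coverage: dict[str, float]
    frame_fractions: dict[str, np.ndarray | None]
    stop_spanning: int
    n_unassigned: int
    n_total: int

    def frame_vector(self, region: str) -> np.ndarray | None:
        return self.frame_fractions[region]


def _region_intervals(t: CuratedTranscript) -> dict[str, tuple[int, int]]:
    """Half-open nt intervals of the biological regions (density/coverage denominators)."""
    return {
        "CDS": (t.cds_start, t.cds_stop_start),
        "ISR": (t.isr_start, t.isr_end_exclusive),
        "UTR": (t.rest3utr_start, len(t.sequence)),
    }


def region_stats(
    alignments: pd.DataFrame,
    transcript: CuratedTranscript,
    lengths: set[int] | None = None,
) -> RegionStats:
    """Compute counts, densities, coverages, frame fractions and the
    stop-spanning count for one transcript.

    Only alignments of the selected footprint lengths are used.  Coverage of
    a region is the fraction of its nucleotides under at least one footprint
    of a read assigned (by the 5'-end window rule) to that region, footprints
    clipped to the region.
    """
    t = transcript
    intervals = _region_intervals(t)
    for region, (lo, hi) in intervals.items():
        if hi - lo <= 0:
            raise ValueError(f"{t.transcript_id}: empty {region} region")

    aln = alignments
    if not aln.empty:
        aln = aln[aln["transcript_id"] == t.transcript_id]
        if lengths is not None:
            aln = aln[aln["length"].isin(lengths)]
    n_total = len(aln)

    pos5 = aln["pos5"].to_numpy(dtype=np.int64) if n_total else np.empty(0, dtype=np.int64)
    lens = aln["length"].to_numpy(dtype=np.int64) if n_total else np.empty(0, dtype=np.int64)

    w = RegionWindows.for_transcript(t)
    bounds = {"CDS": w.cds, "ISR": w.isr, "UTR": w.utr}

    n_reads: dict[str, int] = {}
    density: dict[str, float] = {}
    coverage: dict[str, float] = {}
    frames: dict[str, np.ndarray | None] = {}
    assigned_any = np.zeros(n_total, dtype=bool)

    for region in REGIONS:
        lo, hi = bounds[region]
        mask = (pos5 >= lo) & (pos5 <= hi)
        assigned_any |= mask
        n = int(mask.sum())
        n_reads[region] = n
        rlo, rhi = intervals[region]
        rlen = rhi - rlo
        density[region] = n / rlen
        # per-nucleotide occupancy mask, footprints clipped to the region
        occupied = np.zeros(rlen, dtype=bool)
        for p, ln in zip(pos5[mask], lens[mask]):
            a = max(p, rlo) - rlo
            b = min(p + ln, rhi) - rlo
            if b > a:
                occupied[a:b] = True
        coverage[region] = float(occupied.mean())
        if n:
            fr = (pos5[mask] - t.cds_start) % 3
            frames[region] = np.bincount(fr, minlength=3) / n
        else:
            frames[region] = None

    stop_end = t.cds_stop_start + 3
    spanning = int(((pos5 <= t.cds_stop_start) & (pos5 + lens >= stop_end)).sum())

    return RegionStats(
        transcript_id=t.transcript_id,
        n_reads=n_reads,
        density=density,
        coverage=coverage,
        frame_fractions=frames,
        stop_spanning=spanning,
        n_unassigned=int(n_total - assigned_any.sum()),
        n_total=n_total,
    )


def region_stats_table(
    alignments: pd.DataFrame,
    transcripts: list[CuratedTranscript],
    lengths: set[int] | None = None,
) -> dict[str, RegionStats]:
    """Per-transcript RegionStats over curation-passing transcripts."""
    by_tid = (
        dict(tuple(alignments.groupby("transcript_id", sort=False)))
        if not alignments.empty
        else {}
    )
    empty = alignments.iloc[0:0]
    out = {}
    for t in transcripts:
        if not t.passes_curation:
            continue
        out[t.transcript_id] = region_stats(by_tid.get(t.transcript_id, empty), t, lengths)
    return out


def stats_frame(stats: dict[str, RegionStats]) -> pd.DataFrame:
    """Flatten per-transcript RegionStats into one row per transcript."""
    rows = []
    for tid, s in stats.items():
        row = {"transcript_id": tid, "stop_spanning": s.stop_spanning,
               "n_unassigned": s.n_unassigned}
        for region in REGIONS:
            row[f"n_{region.lower()}"] = s.n_reads[region]
            row[f"density_{region.lower()}"] = s.density[region]
            row[f"coverage_{region.lower()}"] = s.coverage[region]
            fr = s.frame_fractions[region]
            for i in range(3):
                row[f"frame{i}_{region.lower()}"] = float(fr[i]) if fr is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def stats_from_frame(df: pd.DataFrame) -> dict[str, RegionStats]:
    """Rebuild per-transcript RegionStats from a ``stats_frame`` table."""
    out = {}
    for row in df.itertuples(index=False):
        frames = {}
        for region in REGIONS:
            r = region.lower()
            vec = np.array([getattr(row, f"frame{i}_{r}") for i in range(3)])
            frames[region] = None if np.isnan(vec).any() else vec
        out[row.transcript_id] = RegionStats(
            transcript_id=row.transcript_id,
            n_reads={reg: int(getattr(row, f"n_{reg.lower()}")) for reg in REGIONS},
            density={reg: float(getattr(row, f"density_{reg.lower()}")) for reg in REGIONS},
            coverage={reg: float(getattr(row, f"coverage_{reg.lower()}")) for reg in REGIONS},
            frame_fractions=frames,
            stop_spanning=int(row.stop_spanning),
            n_unassigned=int(row.n_unassigned),
            n_total=sum(int(getattr(row, f"n_{reg.lower()}")) for reg in REGIONS)
            + int(row.n_unassigned),
        )
    return out


def metagene_profile(
    alignments: pd.DataFrame,
    transcripts: list[CuratedTranscript],
    window: int = 62,
    anchor: str = "start",
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Aggregate 5'-end positions around the start (or stop) codon, per length.

    Offsets run over ``[-window//2, window - window//2)`` with position 0 the
    first nt of the anchor codon.  Returns the per-length fraction profile
    (long format: length, offset, frame, fraction) and a periodicity score
    per length: the fraction of CDS-assigned 5' ends in that length's modal
    frame, over the whole CDS.
    """
    lo = -(window // 2)
    hi = window + lo  # exclusive
    tmap = {t.transcript_id: t for t in transcripts if t.passes_curation}

    recs = []
    frame_counts: dict[int, np.ndarray] = {}
    for row in alignments.itertuples(index=False):
        t = tmap.get(row.transcript_id)
        if t is None:
            continue
        anchor_pos = t.cds_start if anchor == "start" else t.cds_stop_start
        off = row.pos5 - anchor_pos
        if lo <= off < hi:
            recs.append((row.length, off, (row.pos5 - t.cds_start) % 3))
        if assign_region(row.pos5, t) == "CDS":
            counts = frame_counts.setdefault(row.length, np.zeros(3, dtype=np.int64))
            counts[(row.pos5 - t.cds_start) % 3] += 1

    prof = pd.DataFrame(recs, columns=["length", "offset", "frame"])
    if prof.empty:
        profile = pd.DataFrame(columns=["length", "offset", "frame", "fraction"])
    else:
        counts = prof.groupby(["length", "offset", "frame"]).size().rename("count").reset_index()
        totals = counts.groupby("length")["count"].transform("sum")
        counts["fraction"] = counts["count"] / totals
        profile = counts[["length", "offset", "frame", "fraction"]]

    scores = {
        int(length): float(c.max() / c.sum())
        for length, c in frame_counts.items()
        if c.sum() > 0
    }
    return profile, scores


def dataset_qc(scores: dict[int, float], min_score: float = 0.55) -> bool:
    """A dataset shows usable three-nucleotide periodicity if its best
    footprint length concentrates at least ``min_score`` of CDS 5' ends in
    one frame."""
    return bool(scores) and max(scores.values()) >= min_score
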