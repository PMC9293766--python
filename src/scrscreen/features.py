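"""Sequence-level statistics on screen positives.

Stop-codon usage of positives against the transcriptome background (leaky
TGA stops are expected to be over-represented among readthrough targets),
and a position frequency matrix with per-position information content for
the nucleotide context flanking the canonical stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .transcripts import STOP_CODONS, CuratedTranscript

_STOPS = ("TAA", "TAG", "TGA")
_BASES = ("A", "C", "G", "T")


def stop_usage(
    positives: list[CuratedTranscript],
    background: list[CuratedTranscript],
) -> pd.DataFrame:
    """Observed vs expected stop-codon usage among screen positives.

    Expected counts are the number of positives times each stop codon's
    frequency among all (background) curated transcripts; ``fold`` is
    observed/expected.  A chi-square goodness-of-fit statistic (2 df) is
    attached to the frame's ``attrs``.
    """
    if not positives:
        raise ValueError("no positive transcripts")
    pos_ids = {t.transcript_id for t in positives}
    bg_ids = {t.transcript_id for t in background}
    if not pos_ids <= bg_ids:
        raise ValueError("positives must be a subset of the background set")

    obs = {s: 0 for s in _STOPS}
    for t in positives:
        obs[t.canonical_stop_codon] += 1
    bg = {s: 0 for s in _STOPS}
    for t in background:
        bg[t.canonical_stop_codon] += 1
    n_bg = sum(bg.values())
    n_pos = len(positives)

    rows = []
    for s in _STOPS:
        freq = bg[s] / n_bg
        expected = n_pos * freq
        rows.append(
            {
                "stop_codon": s,
                "observed": obs[s],
                "background_freq": freq,
                "expected": expected,
                "fold": obs[s] / expected if expected > 0 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    valid = table["expected"] > 0
    chi2, p = sstats.chisquare(table.loc[valid, "observed"], table.loc[valid, "expected"])
    table.attrs["chi2"] = float(chi2)
    table.attrs["chi2_p"] = float(p)
    return table


@dataclass
class ContextPFM:
    """Position frequency matrix around the canonical stop codon.

    ``freq`` has one row per base (A/C/G/T) and one column per position
    (negative = upstream of the stop, positive = downstream; the stop triplet
    itself is excluded unless requested).  ``info`` is the per-position
    information content in bits, IC = 2 - H (Shannon entropy, log2).
    """

    freq: pd.DataFrame
    info: pd.Series
    n_used: int
    n_excluded: int


def context_pfm(
    transcripts: list[CuratedTranscript],
    up: int = 6,
    down: int = 6,
    include_stop: bool = False,
    small_sample_correction: bool = False,
) -> ContextPFM:
    """PFM and information content of the stop-codon context.

    Windows cover positions -up..-1 before the stop and +1..+down after it
    (counted from the stop triplet); transcripts too short for the window
    are excluded and counted.  The optional small-sample correction
    subtracts the Basharin bias term 3/(2 ln2 n) from the information
    content, matching common logo software.
    """
    # positions are offsets from the first nt of the stop codon: the triplet
    # occupies 0..2, so "+1 after the stop" is offset 3
    positions: list[int] = list(range(-up, 0))
    if include_stop:
        positions += [0, 1, 2]
    positions += list(range(3, down + 3))

    counts = {p: {b: 0 for b in _BASES} for p in positions}
    n_used = n_excluded = 0
    for t in transcripts:
        stop = t.cds_stop_start
        if stop - up < 0 or stop + 3 + down > len(t.sequence):
            n_excluded += 1
            continue
        window = {p: t.sequence[stop + p] for p in positions}
        if any(b not in _BASES for b in window.values()):
            n_excluded += 1
            continue
        n_used += 1
        for p, base in window.items():
            counts[p][base] += 1

    if n_used == 0:
        raise ValueError("no transcripts long enough for the context window")

    freq = pd.DataFrame(
        {p: [counts[p][b] / n_used for b in _BASES] for p in positions},
        index=list(_BASES),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = freq * np.log2(freq.where(freq > 0, 1.0))
    entropy = -plogp.sum(axis=0)
    info = 2.0 - entropy
    if small_sample_correction:
        info = info - 3.0 / (2.0 * np.log(2) * n_used)
    info = info.clip(lower=0.0)
    return ContextPFM(freq=freq, info=info, n_used=n_used, n_excluded=n_excluded)
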