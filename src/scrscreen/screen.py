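"""The four-level stop codon readthrough screen.

Per dataset, a curated transcript passes when:

1. **Density** — ISR read density is at least ``density_ratio_min`` (default
   4) times the density in the rest of the 3'UTR, and does not exceed the CDS
   density (an ISR hotter than its own CDS is not consistent with
   readthrough).
2. **Coverage** — at least 30 reads map to the ISR, more than half of the ISR
   and less than a quarter of the rest-3'UTR is covered by footprints, and at
   least one footprint spans the canonical stop codon.
3. **Periodicity** — the ISR and CDS frame-fraction vectors are each within
   two standard deviations of a reference distribution (built from
   high-coverage CDSs) in at least one frame.  Ribosomal frameshifting
   products fail here: their ISR frames are rotated away from the reference.
4. **Annotation collision** — the ISR-encoded peptide must not occur exactly
   (window of >= 8 aa) in the supplied proteome; a hit means the "ISR" is in
   fact annotated coding sequence elsewhere, and the candidate is eliminated.

All quantities are computed for every level regardless of earlier failures,
so reports can show near-misses; the funnel (survivors per level) applies the
levels cumulatively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .assign import RegionStats
from .transcripts import CuratedTranscript


@dataclass
class ScreenConfig:
    """Numeric thresholds of the screen (defaults as published)."""

    density_ratio_min: float = 4.0
    isr_min_reads: int = 30
    isr_coverage_min: float = 0.5  # strict >
    utr_coverage_max: float = 0.25  # strict <
    require_stop_spanning: bool = True
    sd_multiplier: float = 2.0
    ref_min_cds_reads: int = 200
    top_k_lengths: int = 3
    min_region_len: int = 45
    collision_len: int = 24
    peptide_min_len: int = 8
    min_support: int = 1  # datasets a transcript must pass to be called
    qc_min_score: float = 0.55
    require_cds_periodicity: bool = True
    reference_scope: str = "transcript"  # or "codon"

    def validate(self) -> None:
        positive = {
            "density_ratio_min": self.density_ratio_min,
            "isr_min_reads": self.isr_min_reads,
            "isr_coverage_min": self.isr_coverage_min,
            "utr_coverage_max": self.utr_coverage_max,
            "sd_multiplier": self.sd_multiplier,
            "ref_min_cds_reads": self.ref_min_cds_reads,
            "top_k_lengths": self.top_k_lengths,
            "min_region_len": self.min_region_len,
            "collision_len": self.collision_len,
            "peptide_min_len": self.peptide_min_len,
            "min_support": self.min_support,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"ScreenConfig.{name} must be positive, got {value}")
        if self.reference_scope not in ("transcript", "codon"):
            raise ValueError(f"unknown reference_scope {self.reference_scope!r}")


@dataclass
class FrameReference:
    """Mean and SD of CDS frame-fraction vectors: the periodicity null."""

    mu: np.ndarray
    sigma: np.ndarray
    n_transcripts: int


def build_frame_reference(
    stats: dict[str, RegionStats],
    cfg: ScreenConfig,
    alignments: pd.DataFrame | None = None,
    transcripts: list[CuratedTranscript] | None = None,
) -> FrameReference:
    """Reference frame distribution over high-coverage CDSs.

    Default scope (``transcript``): each transcript with at least
    ``ref_min_cds_reads`` CDS reads contributes one frame-fraction vector;
    mu/sigma are the per-frame mean and population SD over those vectors.

    Alternative scope (``codon``): the vectors are per-codon frame fractions
    pooled over the qualifying CDSs (requires ``alignments`` and
    ``transcripts``).
    """
    if cfg.reference_scope == "codon":
        if alignments is None or transcripts is None:
            raise ValueError("codon-scope reference needs alignments and transcripts")
        vectors = _per_codon_vectors(stats, alignments, transcripts, cfg)
    else:
        vectors = [
            s.frame_fractions["CDS"]
            for s in stats.values()
            if s.n_reads["CDS"] >= cfg.ref_min_cds_reads
            and s.frame_fractions["CDS"] is not None
        ]
    if len(vectors) < 2:
        raise ValueError(
            "fewer than 2 transcripts qualify for the frame reference; "
            "deeper data (or a lower ref_min_cds_reads) is required"
        )
    mat = np.vstack(vectors)
    return FrameReference(mu=mat.mean(axis=0), sigma=mat.std(axis=0), n_transcripts=len(vectors))


def _per_codon_vectors(stats, alignments, transcripts, cfg):
    qualifying = {
        tid for tid, s in stats.items() if s.n_reads["CDS"] >= cfg.ref_min_cds_reads
    }
    tmap = {t.transcript_id: t for t in transcripts}
    vectors = []
    for tid, grp in alignments.groupby("transcript_id", sort=False):
        if tid not in qualifying:
            continue
        t = tmap[tid]
        pos5 = grp["pos5"].to_numpy()
        rel = pos5 - t.cds_start
        in_cds = (rel >= -12) & (pos5 <= t.cds_stop_start - 22)
        rel = rel[in_cds]
        codon = rel // 3
        frame = rel % 3
        for c in np.unique(codon):
            fr = frame[codon == c]
            vectors.append(np.bincount(fr, minlength=3) / len(fr))
    return vectors


def level1_density(stats: RegionStats, cfg: ScreenConfig) -> tuple[bool, dict]:
    """Density selection: ISR <= CDS and ISR >= ratio_min x rest-3'UTR."""
    isr, cds, utr = stats.density["ISR"], stats.density["CDS"], stats.density["UTR"]
    ratio = np.inf if utr == 0 else isr / utr
    ok = isr > 0 and isr <= cds and ratio >= cfg.density_ratio_min
    return bool(ok), {
        "density_isr": isr,
        "density_cds": cds,
        "density_utr": utr,
        "density_ratio": ratio,
    }


def level2_coverage(stats: RegionStats, cfg: ScreenConfig) -> tuple[bool, dict]:
    """Coverage selection: read count, ISR/3'UTR coverage, stop-spanning read."""
    n_isr = stats.n_reads["ISR"]
    cov_isr = stats.coverage["ISR"]
    cov_utr = stats.coverage["UTR"]
    span = stats.stop_spanning
    ok = (
        n_isr >= cfg.isr_min_reads
        and cov_isr > cfg.isr_coverage_min
        and cov_utr < cfg.utr_coverage_max
        and (span >= 1 or not cfg.require_stop_spanning)
    )
    return bool(ok), {
        "n_isr": n_isr,
        "coverage_isr": cov_isr,
        "coverage_utr": cov_utr,
        "stop_spanning": span,
    }


def _within_reference(fracs: np.ndarray, ref: FrameReference, k: float) -> bool:
    """True if at least one frame of ``fracs`` is within k sigma of the reference.

    A frame with zero reference SD counts only on exact equality with its mean.
    """
    dev = np.abs(fracs - ref.mu)
    zero = ref.sigma == 0
    ok = np.where(zero, dev == 0, dev <= k * ref.sigma)
    return bool(ok.any())


def level3_periodicity(
    isr_fracs: np.ndarray | None,
    cds_fracs: np.ndarray | None,
    ref: FrameReference,
    cfg: ScreenConfig,
) -> bool:
    """Periodicity selection against the reference frame distribution."""
    if isr_fracs is None:
        return False
    ok = _within_reference(np.asarray(isr_fracs, dtype=float), ref, cfg.sd_multiplier)
    if cfg.require_cds_periodicity:
        if cds_fracs is None:
            return False
        ok = ok and _within_reference(np.asarray(cds_fracs, dtype=float), ref, cfg.sd_multiplier)
    return ok


class ProteomeIndex:
    """Exact peptide-window index over a proteome (annotation-collision check)."""

    def __init__(self, proteins: dict[str, str] | list[str], window: int = 8):
        if isinstance(proteins, dict):
            proteins = list(proteins.values())
        self.window = window
        self._kmers: set[str] = set()
        for seq in proteins:
            seq = seq.upper()
            for i in range(len(seq) - window + 1):
                self._kmers.add(seq[i : i + window])

    def collides(self, peptide: str) -> bool:
        w = self.window
        peptide = peptide.upper()
        return any(peptide[i : i + w] in self._kmers for i in range(len(peptide) - w + 1))


def translate_isr(t: CuratedTranscript) -> str:
    """Peptide encoded by the ISR (codons after the canonical stop)."""
    isr = t.sequence[t.isr_start : t.isr_end_exclusive]
    peptide = str(Seq(isr).translate())
    assert "*" not in peptide, f"{t.transcript_id}: internal stop in ISR translation"
    return peptide


def level4_annotation_collision(
    transcript: CuratedTranscript,
    proteome: ProteomeIndex | None,
    cfg: ScreenConfig,
) -> tuple[bool, dict]:
    """Eliminate candidates whose ISR peptide occurs exactly in the proteome.

    A window of at least ``peptide_min_len`` aa shared with any proteome
    entry indicates the "ISR" is annotated coding sequence elsewhere.  With
    no proteome supplied the level passes for every transcript (with a
    warning): the check cannot be performed.
    """
    if proteome is None:
        warnings.warn(
            "no proteome supplied: level-4 annotation-collision check skipped",
            stacklevel=2,
        )
        return True, {"isr_peptide_hit": False}
    peptide = translate_isr(transcript)
    hit = proteome.collides(peptide)
    return (not hit), {"isr_peptide_hit": hit}


LEVELS = ("level1", "level2", "level3", "level4")


def screen_dataset(
    stats: dict[str, RegionStats],
    transcripts: list[CuratedTranscript],
    ref: FrameReference,
    cfg: ScreenConfig,
    proteome: ProteomeIndex | None = None,
    eliminate_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Apply the four levels to every curated transcript of one dataset.

    ``eliminate_ids`` optionally injects an externally produced level-4 hit
    list (e.g. from BLAST) instead of the built-in peptide-window search.
    """
    tmap = {t.transcript_id: t for t in transcripts}
    rows = []
    for tid, s in stats.items():
        t = tmap[tid]
        l1, q1 = level1_density(s, cfg)
        l2, q2 = level2_coverage(s, cfg)
        l3 = level3_periodicity(s.frame_fractions["ISR"], s.frame_fractions["CDS"], ref, cfg)
        if eliminate_ids is not None:
            hit = tid in eliminate_ids
            l4, q4 = (not hit), {"isr_peptide_hit": hit}
        else:
            l4, q4 = level4_annotation_collision(t, proteome, cfg)
        fr_isr = s.frame_fractions["ISR"]
        row = {
            "transcript_id": tid,
            "gene_id": t.gene_id,
            "level1": l1,
            "level2": l2,
            "level3": l3,
            "level4": l4,
            "passes": l1 and l2 and l3 and l4,
            **q1,
            **q2,
            **q4,
        }
        for i in range(3):
            row[f"frame{i}_isr"] = float(fr_isr[i]) if fr_isr is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Screen output across datasets."""

    per_dataset: dict[str, pd.DataFrame]
    transcript_calls: pd.DataFrame  # transcript_id, gene_id, n_support, called
    gene_calls: pd.DataFrame  # gene_id, called
    funnel: pd.DataFrame  # dataset x cumulative survivors per level
    config: ScreenConfig = field(repr=False, default=None)

    @property
    def positive_transcripts(self) -> list[str]:
        df = self.transcript_calls
        return df.loc[df["called"], "transcript_id"].tolist()


def funnel_table(per_dataset: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cumulative survivor counts per level and dataset (the screening funnel)."""
    rows = []
    for name, df in per_dataset.items():
        surv = df
        row = {"dataset": name, "candidates": len(df)}
        for level in LEVELS:
            surv = surv[surv[level]]
            row[level] = len(surv)
        rows.append(row)
    return pd.DataFrame(rows)


def run_screen(
    datasets: dict[str, dict[str, RegionStats]],
    transcripts: list[CuratedTranscript],
    cfg: ScreenConfig,
    proteome: ProteomeIndex | None = None,
    references: dict[str, FrameReference] | None = None,
    eliminate_ids: set[str] | None = None,
) -> ScreenResult:
    """Run the full screen over one or more datasets and roll up calls.

    A transcript is called positive when it passes all four levels in at
    least ``cfg.min_support`` datasets; a gene is positive when any of its
    transcripts is.
    """
    cfg.validate()
    if not datasets:
        raise ValueError("no datasets supplied")
    per_dataset = {}
    for name, stats in datasets.items():
        ref = references[name] if references else build_frame_reference(stats, cfg)
        per_dataset[name] = screen_dataset(
            stats, transcripts, ref, cfg, proteome=proteome, eliminate_ids=eliminate_ids
        )

    support = {}
    gene_of = {}
    for df in per_dataset.values():
        for row in df.itertuples(index=False):
            gene_of[row.transcript_id] = row.gene_id
            if row.passes:
                support[row.transcript_id] = support.get(row.transcript_id, 0) + 1
    calls = pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "gene_id": gene_of[tid],
                "n_support": support.get(tid, 0),
                "called": support.get(tid, 0) >= cfg.min_support,
            }
            for tid in gene_of
        ]
    )
    genes = (
        calls.groupby("gene_id")["called"].any().rename("called").reset_index()
        if not calls.empty
        else pd.DataFrame(columns=["gene_id", "called"])
    )
    return ScreenResult(
        per_dataset=per_dataset,
        transcript_calls=calls,
        gene_calls=genes,
        funnel=funnel_table(per_dataset),
        config=cfg,
    )


def density_summary(result: ScreenResult, dataset: str) -> pd.DataFrame:
    """Mean ISR and rest-3'UTR densities for called positives vs all transcripts."""
    df = result.per_dataset[dataset]
    called = set(result.positive_transcripts)
    pos = df[df["transcript_id"].isin(called)]
    rows = [
        {
            "group": "positives",
            "n": len(pos),
            "mean_density_isr": pos["density_isr"].mean() if len(pos) else np.nan,
            "mean_density_utr": pos["density_utr"].mean() if len(pos) else np.nan,
        },
        {
            "group": "all",
            "n": len(df),
            "mean_density_isr": df["density_isr"].mean(),
            "mean_density_utr": df["density_utr"].mean(),
        },
    ]
    return pd.DataFrame(rows)


def config_dict(cfg: ScreenConfig) -> dict:
    return asdict(cfg)
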