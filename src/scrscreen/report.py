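"""Report generation from a completed run directory.

Every number in the report bundle is recomputed from the run's TSV outputs
(screen report, alignments, curated table); no report-only statistics.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .features import context_pfm, stop_usage
from .transcripts import CuratedTranscript, load_transcripts, curate_transcriptome


def _screen_tables(run_dir: Path) -> dict[str, pd.DataFrame]:
    return {
        p.stem.removeprefix("screen_"): pd.read_csv(p, sep="\t")
        for p in sorted(run_dir.glob("screen_*.tsv"))
    }


def make_report(run_dir, world_dir=None) -> dict[str, str]:
    """Assemble the report bundle for a completed run.

    Writes the funnel recount, per-positive-gene 5'-end profiles and frame
    fractions, and — when the world's FASTA/TSV inputs are reachable — the
    stop-usage and stop-context tables of the positives.
    """
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise FileNotFoundError(f"run directory not found: {run_dir}")
    out = run_dir / "report"
    out.mkdir(exist_ok=True)
    paths: dict[str, str] = {}

    calls = pd.read_csv(run_dir / "transcript_calls.tsv", sep="\t")
    positives = set(calls.loc[calls["called"], "transcript_id"])
    screens = _screen_tables(run_dir)

    # funnel recounted from the per-level booleans of the screen report
    rows = []
    for name, df in screens.items():
        surv = df
        row = {"dataset": name, "candidates": len(df)}
        for level in ("level1", "level2", "level3", "level4"):
            surv = surv[surv[level]]
            row[level] = len(surv)
        rows.append(row)
    funnel = pd.DataFrame(rows)
    paths["funnel"] = str(out / "funnel_recount.tsv")
    funnel.to_csv(paths["funnel"], sep="\t", index=False)

    # per-positive frame fractions and densities (one panel per gene)
    panels = []
    for name, df in screens.items():
        sub = df[df["transcript_id"].isin(positives)].copy()
        sub.insert(0, "dataset", name)
        panels.append(sub)
    panel = pd.concat(panels) if panels else pd.DataFrame()
    paths["positive_panels"] = str(out / "positive_panels.tsv")
    panel.to_csv(paths["positive_panels"], sep="\t", index=False)

    # density comparison (positives vs all), as in the screen's summary
    rows = []
    for name, df in screens.items():
        pos = df[df["transcript_id"].isin(positives)]
        rows.append(
            {
                "dataset": name,
                "n_positives": len(pos),
                "mean_density_isr_positives": pos["density_isr"].mean() if len(pos) else float("nan"),
                "mean_density_isr_all": df["density_isr"].mean(),
                "mean_density_utr_positives": pos["density_utr"].mean() if len(pos) else float("nan"),
                "mean_density_utr_all": df["density_utr"].mean(),
            }
        )
    paths["density_comparison"] = str(out / "density_comparison.tsv")
    pd.DataFrame(rows).to_csv(paths["density_comparison"], sep="\t", index=False)

    if world_dir is not None:
        world_dir = Path(world_dir)
        records = load_transcripts(world_dir / "transcriptome.fa", world_dir / "cds.tsv")
        curated = [t for t in curate_transcriptome(records) if t.passes_curation]
        pos_t = [t for t in curated if t.transcript_id in positives]
        if pos_t:
            usage = stop_usage(pos_t, curated)
            paths["stop_usage"] = str(out / "stop_usage.tsv")
            usage.to_csv(paths["stop_usage"], sep="\t", index=False)
            pfm = context_pfm(pos_t)
            paths["context_pfm"] = str(out / "context_pfm.tsv")
            pfm.freq.to_csv(paths["context_pfm"], sep="\t")
            paths["context_ic"] = str(out / "context_ic.tsv")
            pfm.info.rename("information_bits").to_csv(paths["context_ic"], sep="\t")
    return paths
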