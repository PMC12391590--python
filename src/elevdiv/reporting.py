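"""Aggregation of stage outputs into one summary table.

The summary is a pure function of the stage tables: one row per
metric × trait set × band carrying the observed value, SES and the
significance call; one row per fitted metric × trait set trend (with the
mean R² across all fitted relationships repeated for convenience); and the
guild × band richness profile.  Missing cells (metrics undefined in
species-poor bands) stay in the table as explicit NaNs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["summarize", "mean_r2", "write_summary"]


def mean_r2(trends: pd.DataFrame) -> float:
    """Mean R² across fitted relationships, each under its selected model."""
    if trends.empty:
        return float("nan")
    return float(np.round(trends["r2"].mean(), 2))


def summarize(result) -> pd.DataFrame:
    """Merge SES cells, trend fits and guild profiles into one tidy frame.

    The frame carries a ``section`` column (``ses`` / ``trend`` /
    ``guild_richness``) so it can be written as a single TSV and filtered
    back apart; it is recomputable from the stage TSVs alone.
    """
    for attr in ("ses", "trends", "guild_richness"):
        if getattr(result, attr, None) is None:
            raise ValueError(f"missing stage output: {attr}")

    ses = result.ses.copy()
    ses.insert(0, "section", "ses")

    trends = result.trends.copy()
    trends.insert(0, "section", "trend")
    trends["mean_r2"] = mean_r2(result.trends)

    guilds = result.guild_richness.copy()
    if not guilds.empty:
        guilds.insert(0, "section", "guild_richness")

    out = pd.concat([ses, trends, guilds], ignore_index=True)
    return out


def write_summary(summary: pd.DataFrame, outdir: str | Path) -> None:
    """Write ``summary.tsv`` and a JSON mirror of the same content."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    records = json.loads(summary.to_json(orient="records"))
    (outdir / "summary.json").write_text(json.dumps(records, indent=1))
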