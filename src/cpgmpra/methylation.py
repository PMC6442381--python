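"""Bisulfite methylation summaries at promoter level.

Input is a per-CpG call table (promoter, cpg_position, n_methylated,
n_total) as produced by standard bisulfite quantification.  The
promoter methylation level is the unweighted mean of per-CpG
methylation fractions over covered CpGs — each CpG contributes
equally regardless of its read depth, so deep coverage at one site
cannot dominate the promoter summary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

__all__ = [
    "cpg_methylation",
    "promoter_methylation",
    "summarize_methylation",
    "read_calls",
]

logger = logging.getLogger(__name__)

_COLUMNS = ["promoter", "cpg_position", "n_methylated", "n_total"]


def cpg_methylation(n_methylated: int, n_total: int) -> float:
    """Methylation fraction of a single CpG: n_methylated / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_methylated <= n_total:
        raise ValueError("need 0 <= n_methylated <= n_total")
    return n_methylated / n_total


def promoter_methylation(
    calls: pd.DataFrame, min_coverage: int = 1
) -> float | None:
    """Unweighted mean of per-CpG fractions for one promoter.

    CpGs with coverage below ``min_coverage`` are excluded (logged);
    returns None when no CpG is covered.
    """
    covered = calls[calls.n_total >= max(min_coverage, 1)]
    n_excluded = len(calls) - len(covered)
    if n_excluded:
        logger.info("excluded %d CpG(s) below coverage %d", n_excluded, min_coverage)
    if covered.empty:
        logger.info("promoter has no covered CpGs")
        return None
    return float((covered.n_methylated / covered.n_total).mean())


def summarize_methylation(
    calls: pd.DataFrame, min_coverage: int = 1
) -> pd.DataFrame:
    """Per-promoter summary table (promoter, n_cpgs, mean_methylation)."""
    missing = set(_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"calls table missing columns {sorted(missing)}")
    rows = []
    for prom, grp in calls.groupby("promoter", sort=True):
        level = promoter_methylation(grp, min_coverage)
        if level is None:
            continue
        rows.append(
            {
                "promoter": prom,
                "n_cpgs": int((grp.n_total >= max(min_coverage, 1)).sum()),
                "mean_methylation": level,
            }
        )
    return pd.DataFrame(rows, columns=["promoter", "n_cpgs", "mean_methylation"])


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
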