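"""Barcode counts to promoter activities.

Reporter activity of a construct is read out as the enrichment of its
barcodes in the RNA pool over the DNA (integrated reporter) pool.  Per
replicate:

1. DNA and RNA libraries are scaled to each other by normalizing the
   larger to the smaller total count;
2. barcodes with scaled DNA count of at most ``min_dna_reads`` (default
   20, strict "more than") are dropped — the DNA count is the
   denominator and must be well measured;
3. a DNA-passing barcode missing from RNA is taken as transcriptionally
   silent: its RNA count is 0, not missing;
4. barcode enrichment is n_r / n_d + alpha, with the pseudocount
   alpha = 0.05 chosen as the smallest value that roughly stabilizes
   the variance of lowly transcribed barcodes (a diagnostic profile
   across candidate alphas is provided to reproduce that choice);
5. the promoter's log2 activity is the mean of log2 enrichments of its
   (purity-filtered) barcodes, requiring at least
   ``min_barcodes_per_promoter`` barcodes (default 3; drop to 1 for
   low-coverage libraries).

Replicates are aggregated as unweighted mean with sample SD.  The
pseudocount floors every activity at log2(alpha) ~ -4.32; a promoter
with zero RNA across all barcodes sits exactly on that floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantParams",
    "scale_to_smaller",
    "filter_dna",
    "barcode_enrichment",
    "promoter_activity",
    "quantify_replicate",
    "aggregate_replicates",
    "relative_activity",
    "condition_fold_change",
    "alpha_variance_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    alpha: float = 0.05
    min_dna_reads: float = 20.0
    min_barcodes_per_promoter: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.min_dna_reads < 0:
            raise ValueError("min_dna_reads must be >= 0")
        if self.min_barcodes_per_promoter < 1:
            raise ValueError("min_barcodes_per_promoter must be >= 1")


def scale_to_smaller(
    dna_counts: pd.Series, rna_counts: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Scale the larger library down to the smaller library's total.

    Returns (dna, rna) with equal totals; the smaller library is
    untouched, so per-barcode ratios within each library are preserved.
    """
    td, tr = float(dna_counts.sum()), float(rna_counts.sum())
    if td <= 0 or tr <= 0:
        raise ValueError("both libraries must have positive total counts")
    if td > tr:
        return dna_counts * (tr / td), rna_counts.astype(float)
    return dna_counts.astype(float), rna_counts * (td / tr)


def filter_dna(scaled_dna: pd.Series, params: QuantParams = QuantParams()) -> pd.Index:
    """Barcodes sufficiently represented on DNA: scaled count strictly > threshold."""
    return scaled_dna.index[scaled_dna > params.min_dna_reads]


def barcode_enrichment(n_r: float, n_d: float, alpha: float = 0.05) -> float:
    """RNA/DNA enrichment with pseudocount: n_r / n_d + alpha.

    n_d must be positive (guaranteed upstream by the DNA filter); a
    barcode absent from RNA enters with n_r = 0 and lands on the alpha
    floor.
    """
    if n_d <= 0:
        raise ValueError("n_d must be positive; apply the DNA filter first")
    return n_r / n_d + alpha


def promoter_activity(
    enrichments: pd.DataFrame,
    params: QuantParams = QuantParams(),
) -> pd.DataFrame:
    """Per-promoter log2 activity from barcode enrichments.

    ``enrichments`` has columns (promoter, barcode, enrichment).
    Activity is the mean of log2(enrichment) over the promoter's
    barcodes; promoters with fewer than ``min_barcodes_per_promoter``
    barcodes are dropped (logged).
    """
    rows = []
    for prom, grp in enrichments.groupby("promoter", sort=True):
        if len(grp) < params.min_barcodes_per_promoter:
            logger.info(
                "dropping promoter %s: %d barcode(s) < required %d",
                prom, len(grp), params.min_barcodes_per_promoter,
            )
            continue
        rows.append(
            {
                "promoter": prom,
                "n_barcodes_used": len(grp),
                "log2_activity": float(np.mean(np.log2(grp.enrichment))),
            }
        )
    return pd.DataFrame(rows, columns=["promoter", "n_barcodes_used", "log2_activity"])


def quantify_replicate(
    counts: pd.DataFrame,
    barcode_map: dict[str, str],
    params: QuantParams = QuantParams(),
) -> pd.DataFrame:
    """Full quantification of one replicate.

    ``counts`` has columns (barcode, sample, count) with sample in
    {DNA, RNA}; ``barcode_map`` maps purity-filtered barcodes to their
    promoter.  Applies scaling, the DNA filter, zero-RNA imputation and
    the enrichment model, returning per-promoter activities.
    """
    dna = counts[counts["sample"] == "DNA"].set_index("barcode")["count"]
    rna = counts[counts["sample"] == "RNA"].set_index("barcode")["count"]
    if rna.sum() > 0:
        dna, rna = scale_to_smaller(dna, rna)
    else:
        # fully silent RNA library: nothing to scale, every barcode
        # lands on the pseudocount floor
        dna = dna.astype(float)
    kept = filter_dna(dna, params)
    kept = kept[kept.isin(list(barcode_map))]
    rna_kept = rna.reindex(kept).fillna(0.0)  # DNA-passing, RNA-absent -> silent
    enr = pd.DataFrame(
        {
            "promoter": [barcode_map[b] for b in kept],
            "barcode": kept,
            "enrichment": rna_kept.to_numpy() / dna.loc[kept].to_numpy()
            + params.alpha,
        }
    )
    return promoter_activity(enr, params)


def aggregate_replicates(replicates: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean and sample SD of log2 activity across replicates.

    SD uses n-1 and is NaN for promoters seen in a single replicate.
    Only promoters present in at least one replicate appear.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    long = pd.concat(
        [df.assign(replicate=name) for name, df in replicates.items()],
        ignore_index=True,
    )
    agg = long.groupby("promoter", sort=True)["log2_activity"].agg(
        mean_log2_activity="mean", sd_log2_activity=lambda s: s.std(ddof=1),
        n_replicates="size",
    )
    return agg.reset_index()


def relative_activity(
    per_replicate: dict[str, pd.DataFrame], reference_promoter: str
) -> pd.DataFrame:
    """log2 activity relative to a reference construct (e.g. the WT).

    The reference's log2 activity is subtracted per replicate, then
    replicates are aggregated; the reference must be quantified in
    every replicate.
    """
    shifted = {}
    for name, df in per_replicate.items():
        ref = df.loc[df.promoter == reference_promoter, "log2_activity"]
        if ref.empty:
            raise ValueError(
                f"reference promoter {reference_promoter!r} missing in "
                f"replicate {name!r}"
            )
        shifted[name] = df.assign(log2_activity=df.log2_activity - float(ref.iloc[0]))
    return aggregate_replicates(shifted)


def condition_fold_change(
    activities_a: pd.DataFrame, activities_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-promoter log2 fold change A - B of aggregated activities.

    Inputs are aggregate tables (promoter, mean_log2_activity, ...);
    promoters missing in either condition are dropped with logging.
    """
    a = activities_a.set_index("promoter")["mean_log2_activity"]
    b = activities_b.set_index("promoter")["mean_log2_activity"]
    common = a.index.intersection(b.index)
    dropped = a.index.symmetric_difference(b.index)
    if len(dropped):
        logger.info("dropping %d promoter(s) missing in one condition", len(dropped))
    return pd.DataFrame(
        {"promoter": common, "log2_fold_change": (a[common] - b[common]).to_numpy()}
    )


def alpha_variance_profile(
    counts: pd.DataFrame,
    barcode_map: dict[str, str],
    alphas: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5),
    params: QuantParams = QuantParams(),
) -> pd.DataFrame:
    """Variance-stabilization diagnostic across candidate pseudocounts.

    For each candidate alpha, quantifies the replicate and reports the
    variance of barcode-level log2 enrichments within promoters (mean of
    per-promoter variances).  Users pick the smallest alpha at which the
    variance roughly stabilizes — the procedure behind the 0.05 default.
    """
    dna = counts[counts["sample"] == "DNA"].set_index("barcode")["count"]
    rna = counts[counts["sample"] == "RNA"].set_index("barcode")["count"]
    dna, rna = scale_to_smaller(dna, rna)
    kept = filter_dna(dna, params)
    kept = kept[kept.isin(barcode_map.keys())]
    ratio = rna.reindex(kept).fillna(0.0).to_numpy() / dna.loc[kept].to_numpy()
    prom = pd.Series([barcode_map[b] for b in kept], index=kept)
    rows = []
    for a in alphas:
        log2e = pd.Series(np.log2(ratio + a), index=kept)
        within = log2e.groupby(prom).var(ddof=1)
        rows.append({"alpha": a, "mean_within_promoter_variance": within.mean()})
    return pd.DataFrame(rows)
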