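"""TF-binding prediction from motif score and regional CpG density.

Genome-scale ChIP enrichment is summarized over non-overlapping 600-nt
tiling windows; a window is "bound" when its log2 enrichment over input
exceeds 2.5.  Two sequence features predict binding:

* the best motif log-odds score in the window — sum over motif
  positions of log2(p_i(base) / 0.25), maximized over offsets and both
  strands (uniform background, log2 scale; a score >= 12 is the
  conventional "contains a motif" call);
* the window's normalized CpG density (OE).

The two are combined additively on the logit scale,

    P(bound) = sigmoid(a + b * motif_score + c * oe),

fitted by maximum likelihood.  Precision-recall curves over 100
equally spaced cutoffs from min to max of a score compare each single
feature against the combined model; for factors whose motifs
concentrate in CpG islands, the combination outperforms either feature
alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .seqstats import normalized_cpg_density

__all__ = [
    "PWM",
    "GenomicWindow",
    "LogisticModel",
    "PRCurve",
    "read_pwm",
    "logodds_scan",
    "tile_windows",
    "call_bound",
    "subset_stats",
    "fit_logistic",
    "pr_curve",
    "pr_area",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position probabilities over ACGT.

    Cells are floored at a small pseudo-probability and renormalized on
    construction so log-odds scores are always finite.
    """

    name: str
    matrix: np.ndarray  # (width, 4), rows sum to 1
    pseudo: float = 1e-3

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if (m < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        m = m + self.pseudo
        m = m / m.sum(axis=1, keepdims=True)
        object.__setattr__(self, "matrix", m)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")  # pragma: no cover

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def logodds(self) -> np.ndarray:
        """(width, 4) log2 odds against the uniform 0.25 background."""
        return np.log2(self.matrix / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())


def read_pwm(path: str | Path) -> PWM:
    """Read a PWM from text: a ``>name`` header then one A C G T row per position."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("PWM file must start with a '>name' header")
    name = lines[0][1:].strip()
    rows = [[float(x) for x in ln.split()] for ln in lines[1:]]
    return PWM(name=name, matrix=np.array(rows))


def _encode_indices(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.intp)


def _scan_one_strand(seq: str, lo: np.ndarray) -> float:
    w = lo.shape[0]
    if len(seq) < w:
        return -np.inf
    idx = _encode_indices(seq)
    # windowed gather: score[o] = sum_i lo[i, idx[o+i]]
    offsets = np.arange(len(seq) - w + 1)
    windows = idx[offsets[:, None] + np.arange(w)[None, :]]
    scores = lo[np.arange(w)[None, :], windows].sum(axis=1)
    return float(scores.max())


def logodds_scan(sequence: str, pwm: PWM) -> float:
    """Best log2 log-odds score over all offsets and both strands.

    Returns -inf when the window is shorter than the motif (no site
    fits).  The reverse strand is scored on the reverse complement.
    """
    seq = sequence.upper()
    lo = pwm.logodds
    fwd = _scan_one_strand(seq, lo)
    rev = _scan_one_strand(seq.translate(_COMPLEMENT)[::-1], lo)
    return max(fwd, rev)


@dataclass
class GenomicWindow:
    """A tiling window with its binding-relevant summaries."""

    id: str
    oe: float
    chip_log2_enrichment: float = np.nan
    best_motif_score: float = -np.inf
    bound: bool = False
    sequence: str | None = None
    start: int | None = None
    end: int | None = None


def tile_windows(
    sequence: str,
    window_size: int = 600,
    pwm: PWM | None = None,
    id_prefix: str = "w",
) -> list[GenomicWindow]:
    """Cut a span into non-overlapping consecutive windows.

    The trailing remainder shorter than ``window_size`` is dropped.
    Each window gets its OE and, if a PWM is supplied, its best motif
    score.
    """
    n = len(sequence) // window_size
    out = []
    for t in range(n):
        s, e = t * window_size, (t + 1) * window_size
        sub = sequence[s:e]
        out.append(
            GenomicWindow(
                id=f"{id_prefix}{t}",
                oe=normalized_cpg_density(sub),
                best_motif_score=logodds_scan(sub, pwm) if pwm else -np.inf,
                sequence=sub,
                start=s,
                end=e,
            )
        )
    return out


def call_bound(
    window: GenomicWindow, enrichment_threshold: float = 2.5
) -> bool:
    """Bound iff ChIP log2 enrichment over input strictly exceeds the threshold."""
    if np.isnan(window.chip_log2_enrichment):
        raise ValueError(f"window {window.id} has no enrichment value")
    return bool(window.chip_log2_enrichment > enrichment_threshold)


def _windows_frame(windows) -> pd.DataFrame:
    if isinstance(windows, pd.DataFrame):
        return windows
    return pd.DataFrame(
        {
            "id": [w.id for w in windows],
            "oe": [w.oe for w in windows],
            "motif_score": [w.best_motif_score for w in windows],
            "bound": [w.bound for w in windows],
        }
    )


def subset_stats(
    windows,
    motif_threshold: float = 12.0,
    oe_threshold: float = 0.6,
) -> pd.DataFrame:
    """Percent bound and recall for the subsets {all, motif, OE, motif+OE}.

    percent_bound = bound windows in subset / subset size;
    recall = bound windows in subset / all bound windows.  An empty
    subset reports NaN percent_bound.  "motif" means best score >= the
    threshold, "OE" means window OE >= the threshold; the combined
    subset is exactly their intersection.
    """
    df = _windows_frame(windows)
    n_bound_total = int(df.bound.sum())
    masks = {
        "all": np.ones(len(df), dtype=bool),
        "motif": (df.motif_score >= motif_threshold).to_numpy(),
        "oe": (df.oe >= oe_threshold).to_numpy(),
        "motif+oe": (
            (df.motif_score >= motif_threshold) & (df.oe >= oe_threshold)
        ).to_numpy(),
    }
    rows = []
    for name, mask in masks.items():
        n, nb = int(mask.sum()), int(df.bound[mask].sum())
        rows.append(
            {
                "subset": name,
                "n_windows": n,
                "percent_bound": 100.0 * nb / n if n else np.nan,
                "recall": nb / n_bound_total if n_bound_total else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LogisticModel:
    """Additive logistic binding predictor on (motif score, OE)."""

    intercept: float
    coef_motif: float
    coef_oe: float
    fitted: bool = False
    separation_fallback: bool = False
    conf_int: np.ndarray | None = field(default=None, repr=False)

    def predict_proba(self, motif_score, oe) -> np.ndarray:
        z = (
            self.intercept
            + self.coef_motif * np.asarray(motif_score, dtype=float)
            + self.coef_oe * np.asarray(oe, dtype=float)
        )
        return 1.0 / (1.0 + np.exp(-z))


def fit_logistic(windows) -> LogisticModel:
    """Maximum-likelihood fit of bound ~ intercept + motif_score + OE.

    The problem is convex, so the fit is deterministic given the data.
    On (quasi-)complete separation the MLE diverges; a warning is
    emitted and a lightly L2-regularized fit is returned instead, with
    ``separation_fallback`` set.
    """
    df = _windows_frame(windows)
    y = df.bound.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both bound and unbound windows to fit")
    X = sm.add_constant(df[["motif_score", "oe"]].to_numpy(dtype=float))
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = model.fit(disp=0)
        if not res.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("did not converge")
        params, ci, fallback = res.params, res.conf_int(), False
    except Exception:
        warnings.warn(
            "perfect separation or non-convergence; using L2-regularized fit",
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0, maxiter=500)
        params, ci, fallback = res.params, None, True
    return LogisticModel(
        intercept=float(params[0]),
        coef_motif=float(params[1]),
        coef_oe=float(params[2]),
        fitted=True,
        separation_fallback=fallback,
        conf_int=np.asarray(ci) if ci is not None else None,
    )


@dataclass
class PRCurve:
    """Precision/recall over equally spaced score cutoffs."""

    cutoffs: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    score_name: str = ""


def pr_curve(windows, score: str = "oe", n_cutoffs: int = 100) -> PRCurve:
    """Precision-recall curve for one score over tiled windows.

    ``score`` is a column of the window table ("oe", "motif_score",
    "probability", ...).  Cutoffs are ``n_cutoffs`` equally spaced
    values from min(score) to max(score).  At cutoff t, with windows
    scoring >= t forming the predicted-positive set:

        precision = bound windows >= t / windows >= t
        recall    = bound windows >= t / all bound windows

    At the minimum cutoff every window is included, so recall is 1 and
    precision equals the overall bound fraction.
    """
    df = _windows_frame(windows) if not isinstance(windows, pd.DataFrame) else windows
    s = df[score].to_numpy(dtype=float)
    y = df["bound"].to_numpy(dtype=bool)
    n_bound = int(y.sum())
    if n_bound == 0:
        raise ValueError("no bound windows: PR curve undefined")
    cutoffs = np.linspace(s.min(), s.max(), n_cutoffs)
    # counts above cutoff via sorting, O((n + k) log n)
    order = np.argsort(s)
    s_sorted = s[order]
    bound_sorted = y[order]
    cum_bound_from = np.concatenate(
        [np.cumsum(bound_sorted[::-1])[::-1], [0]]
    )  # bound among s_sorted[i:]
    idx = np.searchsorted(s_sorted, cutoffs, side="left")
    n_above = len(s) - idx
    b_above = cum_bound_from[idx]
    with np.errstate(invalid="ignore"):
        precision = np.where(n_above > 0, b_above / np.maximum(n_above, 1), np.nan)
    recall = b_above / n_bound
    return PRCurve(
        cutoffs=cutoffs,
        precision=precision,
        recall=recall.astype(float),
        score_name=score,
    )


def pr_area(curve: PRCurve) -> float:
    """Area under the PR curve by trapezoid over recall (NaN precision dropped)."""
    ok = ~np.isnan(curve.precision)
    r, p = curve.recall[ok], curve.precision[ok]
    order = np.argsort(r)
    return float(np.trapezoid(p[order], r[order]))
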