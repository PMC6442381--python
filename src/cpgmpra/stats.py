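"""Rank-correlation statistics with permutation significance.

The dependence of reporter activity on normalized CpG density is
summarized per replicate by Spearman's rho (Pearson correlation of
mid-ranks, so ties get average ranks), reported as mean ± SD across
replicates.  Significance comes from permutation tests that make no
distributional assumption:

* approximate — y is permuted ``n_perm`` times and the two-sided
  p-value is (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm); the +1
  correction counts the observed statistic among the permutations, so
  p can never be 0 and the test is valid at any n_perm;
* exact — all n! permutations are enumerated (practical for n up to
  ~9) and p is the raw proportion including the identity permutation,
  so again p > 0 always.

Both act on y only; permuting one margin suffices for the
exchangeability null.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PermutationResult",
    "spearman_rho",
    "perm_test_approx",
    "perm_test_exact",
    "replicate_correlations",
]


@dataclass(frozen=True)
class PermutationResult:
    rho_observed: float
    n_permutations: int
    p_value: float
    mode: str  # "approximate" | "exact"
    seed: int | None = None
    alternative: str = "two_sided"


def _std_ranks(v: np.ndarray) -> np.ndarray:
    """Mid-ranks centred and scaled to unit norm, so rho = r_x @ r_y."""
    r = rankdata(v, method="average")
    r = r - r.mean()
    norm = math.sqrt(float(r @ r))
    if norm == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return r / norm


def _check(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return x, y


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on mid-ranks)."""
    x, y = _check(x, y)
    return float(_std_ranks(x) @ _std_ranks(y))


def _p_from_null(
    rho_obs: float, rho_null: np.ndarray, alternative: str, plus_one: bool
) -> float:
    if alternative == "two_sided":
        hits = np.abs(rho_null) >= abs(rho_obs) - 1e-12
    elif alternative == "greater":
        hits = rho_null >= rho_obs - 1e-12
    elif alternative == "less":
        hits = rho_null <= rho_obs + 1e-12
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    k = int(hits.sum())
    if plus_one:
        return (1 + k) / (1 + len(rho_null))
    return k / len(rho_null)


def perm_test_approx(
    x,
    y,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "two_sided",
) -> PermutationResult:
    """Monte-Carlo permutation test for Spearman's rho.

    Requires an explicit ``seed`` for reproducibility.  n_perm must be
    at least 100 for a meaningful tail estimate.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("seed is required for the approximate test")
    x, y = _check(x, y)
    rx, ry = _std_ranks(x), _std_ranks(y)
    rho_obs = float(rx @ ry)
    rng = np.random.default_rng(seed)
    # permuting standardized ranks of y == re-ranking permuted y
    perm = rng.permuted(
        np.broadcast_to(ry, (n_perm, len(ry))).copy(), axis=1
    )
    rho_null = perm @ rx
    p = _p_from_null(rho_obs, rho_null, alternative, plus_one=True)
    return PermutationResult(rho_obs, n_perm, p, "approximate", seed, alternative)


def perm_test_exact(
    x,
    y,
    alternative: str = "two_sided",
    max_n: int = 9,
) -> PermutationResult:
    """Exhaustive permutation test enumerating all n! reorderings of y.

    Feasible up to n = ``max_n`` (default 9, i.e. 362,880 permutations);
    larger samples are directed to the approximate test.
    """
    x, y = _check(x, y)
    n = len(x)
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds the exhaustive bound {max_n}; use perm_test_approx"
        )
    rx, ry = _std_ranks(x), _std_ranks(y)
    rho_obs = float(rx @ ry)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rho_null = ry[perms] @ rx
    p = _p_from_null(rho_obs, rho_null, alternative, plus_one=False)
    return PermutationResult(
        rho_obs, len(perms), p, "exact", None, alternative
    )


def replicate_correlations(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Per-replicate rho with pooled permutation significance.

    rho is computed per replicate and reported as mean ± sample SD; the
    p-value pools the per-replicate permutation null distributions and
    compares them against the mean observed |rho| (each replicate
    permuted independently from the given seed).
    """
    rhos, nulls = [], []
    for i, (name, (x, y)) in enumerate(sorted(pairs.items())):
        x, y = _check(x, y)
        rx, ry = _std_ranks(x), _std_ranks(y)
        rhos.append(float(rx @ ry))
        rng = np.random.default_rng((seed, i))
        perm = rng.permuted(np.broadcast_to(ry, (n_perm, len(ry))).copy(), axis=1)
        nulls.append(perm @ rx)
    rho_mean = float(np.mean(rhos))
    null_mean = np.mean(nulls, axis=0)  # mean rho across replicates per permutation
    p = _p_from_null(rho_mean, null_mean, "two_sided", plus_one=True)
    return {
        "rho_per_replicate": dict(zip(sorted(pairs), rhos)),
        "rho_mean": rho_mean,
        "rho_sd": float(np.std(rhos, ddof=1)) if len(rhos) > 1 else float("nan"),
        "p_value": p,
        "n_permutations": n_perm,
    }
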