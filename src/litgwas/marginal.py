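"""Univariate (marginal) baselines: Marginal (SQ) and Marginal (SQ/CP).

Each SQ/CP column is regressed on the adjusted SNP separately; the minimum
p-value across columns is Bonferroni-thresholded at alpha / K, where K is
the number of principal components of the column set explaining 95% of its
variation (an effective number of tests that accounts for the strong
correlation among squared residuals and cross products).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .sqcp import SqCpMatrix

__all__ = ["MarginalResult", "marginal_test", "effective_tests_K"]


@dataclass
class MarginalResult:
    pvalues: np.ndarray
    columns: list[str]
    min_p: float
    K: int
    alpha: float
    alpha_prime: float
    significant: bool
    best_column: str


def _column_values(Z: Union[SqCpMatrix, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    if isinstance(Z, SqCpMatrix):
        vals = Z.values if Z.centered else Z.values - Z.values.mean(axis=0)
        return vals, list(Z.column_kinds)
    vals = np.asarray(Z, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    vals = vals - vals.mean(axis=0)
    return vals, [f"col{j + 1}" for j in range(vals.shape[1])]


def effective_tests_K(
    Z: Union[SqCpMatrix, np.ndarray], threshold: float = 0.95
) -> int:
    """Smallest number of PCs of (column-standardized) Z whose cumulative
    variance fraction reaches ``threshold``.

    PCA is on the correlation scale so K does not depend on column units;
    constant columns carry no variance direction and are excluded.
    """
    vals, _ = _column_values(Z)
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("Z has no non-constant column")
    S = vals[:, keep] / sd[keep]
    corr = (S.T @ S) / (S.shape[0] - 1)
    evals = np.linalg.eigvalsh(corr)[::-1]
    evals = np.clip(evals, 0.0, None)
    frac = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def marginal_pvalues(Zc: np.ndarray, x: np.ndarray,
                     exact_t: bool = False) -> np.ndarray:
    """Two-sided per-column p-values from simple regression on x (hot path).

    Columns and x must be centered.  Uses the normal-approximation score
    test n*r^2 ~ chi2(1) by default; ``exact_t`` switches to the exact
    t-reference for small n.  Constant columns get p = 1.
    """
    n = Zc.shape[0]
    ssx = float(x @ x)
    ssz = np.einsum("ij,ij->j", Zc, Zc)
    num = x @ Zc
    p = np.ones(Zc.shape[1])
    ok = ssz > 0
    if not ok.all():
        warnings.warn("constant Z column(s); their p-values set to 1")
    r2 = np.zeros_like(ssz)
    r2[ok] = num[ok] ** 2 / (ssx * ssz[ok])
    r2 = np.clip(r2, 0.0, 1.0)
    if exact_t:
        with np.errstate(divide="ignore"):
            tstat = np.sqrt(r2[ok] * (n - 2) / np.clip(1 - r2[ok], 1e-300, None))
        p[ok] = 2.0 * stats.t.sf(tstat, df=n - 2)
    else:
        p[ok] = stats.chi2.sf(n * r2[ok], df=1)
    return p


def marginal_test(
    Z: Union[SqCpMatrix, np.ndarray],
    x_adj: np.ndarray,
    alpha: float = 5e-8,
    *,
    exact_t: bool = False,
    K: Optional[int] = None,
) -> MarginalResult:
    """Minimum-p marginal procedure over the columns of Z.

    Pass the SQ-only matrix for Marginal (SQ) or the full SQ/CP matrix for
    Marginal (SQ/CP); each procedure corrects for its own column set.  ``K``
    may be precomputed once per dataset (its value barely depends on the
    single SNP being adjusted for).
    """
    vals, names = _column_values(Z)
    x = np.asarray(x_adj, dtype=float).ravel()
    x = x - x.mean()
    if not np.any(x != 0.0):
        raise ValueError("monomorphic or fully-explained SNP")
    p = marginal_pvalues(vals, x, exact_t=exact_t)
    if K is None:
        K = effective_tests_K(Z)
    best = int(np.argmin(p))
    alpha_prime = alpha / K
    return MarginalResult(
        pvalues=p,
        columns=names,
        min_p=float(p[best]),
        K=int(K),
        alpha=float(alpha),
        alpha_prime=float(alpha_prime),
        significant=bool(p[best] < alpha_prime),
        best_column=names[best],
    )
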