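"""Lean per-SNP testing path shared by the scan driver and the simulators.

`analyze_snp` takes traits already residualized on the covariate design H
(column-centered) and a structure-adjusted, mean-zero genotype, removes the
SNP's additive effect by the Frisch-Waugh-Lovell identity (one rank-1
update instead of refitting the full design), rebuilds the SQ/CP features,
and runs wLIT / uLIT / aLIT plus both marginal procedures.  Everything is
computed from the d x d Gram matrix of Z, so per-SNP cost is O(n * d^2)
with d = r + r(r-1)/2 and memory never O(n^2).

For the linear kernels, with v_K = x/||x||, lam_K = x'x and the kernel
eigenpairs (lam_i, v_i) of Z Z', the projections proj_i = x'v_i satisfy

    n * T_wlit = sum_i proj_i^2            (null weights lam_K*lam_i/n)
    n * T_ulit = sum_i proj_i^2 / (lam_i * x'x)   (null chi2(d1)/n)

so a single length-d vector x'Z W carries both statistics.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy import stats

from .kdc import P_FLOOR, cauchy_combine, weighted_chisq_sf
from .sqcp import sqcp_values

__all__ = ["analyze_snp"]


def analyze_snp(
    E0: np.ndarray,
    x_adj: np.ndarray,
    h0: Union[float, np.ndarray, None] = None,
    *,
    include_cp: bool = True,
    studentized: bool = True,
    rank_tol: float = 1e-10,
    gc_lambda: Optional[tuple[float, float]] = None,
    K_sq: Optional[int] = None,
    K_sqcp: Optional[int] = None,
) -> dict:
    """Run the full single-SNP test battery.

    Parameters
    ----------
    E0
        n x r traits residualized on the covariate design H (centered).
    x_adj
        Structure-adjusted genotype, mean zero.
    h0
        Leverage of the H design (scalar 1/n for intercept-only, or a
        length-n vector); used for internal studentization of the joint
        H + SNP design.  ``None`` skips studentization.
    include_cp
        False restricts both LIT and the marginal battery to squared
        residuals only (the cheaper variance-only mode).
    gc_lambda
        Optional (lambda_wlit, lambda_ulit) genomic-control factors applied
        to the wLIT/uLIT p-values before the Cauchy combination.
    K_sq, K_sqcp
        Effective test counts for the Bonferroni baselines.  Z's covariance
        barely depends on which single SNP was adjusted for, so callers
        testing many SNPs of one dataset compute these once and pass them
        in; left None they are recomputed from this SNP's Gram matrix.

    Returns a dict with the LIT statistics/p-values, the marginal minimum
    p-values and effective test counts K for the SQ and SQ/CP column sets,
    and the ranks used.
    """
    x = np.asarray(x_adj, dtype=float).ravel()
    n, r = E0.shape
    ssx = float(x @ x)
    if ssx <= 0.0:
        raise ValueError("monomorphic or fully-explained SNP")

    # FWL: remove the SNP's additive effect from the H-residualized traits
    b = (x @ E0) / ssx
    E = E0 - x[:, None] * b
    if studentized and h0 is not None:
        h = np.asarray(h0) + x * x / ssx
        E = E / np.sqrt(1.0 - h)[:, None]
        E = E - E.mean(axis=0)

    use_cp = include_cp and r >= 2
    Z = sqcp_values(E, include_cp=use_cp, center=True)
    d = Z.shape[1]
    gram = Z.T @ Z
    evals, evecs = np.linalg.eigh(gram)  # ascending
    top = evals[-1]
    if top <= 0.0:
        raise ValueError("degenerate SQ/CP matrix")
    keep = evals > rank_tol * top
    evals = evals[keep]
    d1 = int(evals.size)

    xZ = x @ Z
    # v_L,i = Z w_i / sqrt(lam_i)  =>  x'v_L,i = (x'Z w_i) / sqrt(lam_i)
    proj = xZ @ evecs[:, keep]
    s = proj * proj / evals  # s_i = (x . v_L,i)^2

    q_w = float(s @ evals)  # = n * T_wlit
    weights_w = ssx * evals / n
    t_wlit = q_w / n
    p_wlit = weighted_chisq_sf(q_w, weights_w)

    q_u = float(s.sum()) / ssx  # = n * T_ulit
    t_ulit = q_u / n
    p_ulit = float(np.clip(stats.chi2.sf(n * q_u, df=d1), P_FLOOR, 1.0))

    if gc_lambda is not None:
        from .adjustments import gc_adjust

        p_wlit = float(gc_adjust(np.array([p_wlit]), gc_lambda[0])[0])
        p_ulit = float(gc_adjust(np.array([p_ulit]), gc_lambda[1])[0])
    p_alit = cauchy_combine([p_wlit, p_ulit])

    # marginal battery: score test of each Z column on x
    diag = np.diag(gram)
    ok = diag > 0
    r2 = np.zeros(d)
    r2[ok] = xZ[ok] ** 2 / (ssx * diag[ok])
    p_cols = np.ones(d)
    p_cols[ok] = stats.chi2.sf(n * np.clip(r2[ok], 0.0, 1.0), df=1)

    if K_sqcp is None:
        K_sqcp = _effective_tests_from_gram(gram)
    minp_sqcp = float(p_cols.min())
    if use_cp:
        if K_sq is None:
            K_sq = _effective_tests_from_gram(gram[:r, :r])
        minp_sq = float(p_cols[:r].min())
    else:
        K_sq, minp_sq = K_sqcp, minp_sqcp

    return {
        "t_wlit": t_wlit, "t_ulit": t_ulit,
        "p_wlit": p_wlit, "p_ulit": p_ulit, "p_alit": p_alit,
        "d1": d1, "d2": 1, "n": n,
        "p_columns": p_cols,
        "minp_sq": minp_sq, "K_sq": K_sq,
        "minp_sqcp": minp_sqcp, "K_sqcp": K_sqcp,
    }


def _effective_tests_from_gram(gram: np.ndarray,
                               threshold: float = 0.95) -> int:
    """Number of PCs explaining `threshold` of variance, correlation scale."""
    diag = np.diag(gram)
    ok = diag > 0
    sub = gram[np.ix_(ok, ok)]
    dd = np.sqrt(np.diag(sub))
    corr = sub / np.outer(dd, dd)
    evals = np.clip(np.linalg.eigvalsh(corr)[::-1], 0.0, None)
    frac = np.cumsum(evals) / evals.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)
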