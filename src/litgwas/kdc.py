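"""Step 3 of LIT: the kernel-based independence test and p-value machinery.

The test statistic is the Hilbert-Schmidt independence criterion between the
SQ/CP similarity matrix L = Z Z' and the genotype similarity matrix
K = X X' (linear kernels):

    T = (1/n) tr(K L).

Under the null of no latent interaction, n*T is asymptotically a weighted sum
of independent chi-square(1) variables with weights lambda_K,i * lambda_L,j / n
over all eigenvalue pairs of the two kernel matrices.  Because the feature
dimensions d1 = r + r(r-1)/2 and d2 (1 for a single SNP) are tiny compared to
n, everything is computed from thin SVD factors without ever forming an
n x n matrix:

    T = (1/n) tr(D_K R D_L R'),   R = V_K' V_L.

Weighting eigenvectors by eigenvalues is the traditional statistic (wLIT);
weighting them equally, T = (1/n) tr(R R'), is equivalent to using projection
kernels (uLIT), whose null is an ordinary chi-square with d1*d2 degrees of
freedom.  The two p-values are combined by the Cauchy combination test
(aLIT), which hedges against either weighting being suboptimal for the
(unknown) pleiotropic architecture.

Tail probabilities of the weighted chi-square sum are computed by numerical
inversion of the characteristic function (Davies/Imhof), with a
Lugannani-Rice saddlepoint fallback for the deep tail where the oscillatory
integral loses accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .sqcp import SqCpMatrix

__all__ = [
    "KernelSpec",
    "SpectralFactors",
    "LitResult",
    "spectral_factorize",
    "wlit_statistic",
    "ulit_statistic",
    "weighted_chisq_sf",
    "cauchy_combine",
    "lit_single_snp",
    "region_test",
]

P_FLOOR = 1e-300  # avoid log-scale infinities in output tables


@dataclass
class KernelSpec:
    """Kernel choice and numerical-rank cutoff for the spectral factors."""

    kind: str = "linear"  # "linear" | "projection"
    rank_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "projection"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if not (0.0 < self.rank_tol < 1.0):
            raise ValueError("rank_tol must be in (0, 1)")


@dataclass
class SpectralFactors:
    """Eigenvalues/eigenvectors of an implicit kernel M M' (never formed)."""

    eigenvalues: np.ndarray  # nonincreasing, positive
    eigenvectors: np.ndarray  # n x d, orthonormal columns
    d: int

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class LitResult:
    """Per-SNP (or per-region) LIT output."""

    snp_id: str
    t_wlit: float
    t_ulit: float
    p_wlit: float
    p_ulit: float
    p_alit: float
    d1: int
    d2: int
    n_used: int
    p_wlit_perm: Optional[float] = None
    p_ulit_perm: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def spectral_factorize(
    M: np.ndarray, spec: Optional[KernelSpec] = None
) -> SpectralFactors:
    """Spectral factors of the linear kernel M M' from the d x d Gram matrix.

    Kernel eigenvalues are the squared singular values of M; memory stays
    O(n*d).  Eigenvalues below ``rank_tol`` times the largest are dropped
    (this is what makes duplicated SQ/CP columns harmless).  For a
    ``projection`` kernel the retained eigenvalues are replaced by ones.
    """
    if spec is None:
        spec = KernelSpec()
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    gram = M.T @ M
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0.0:
        raise ValueError("cannot factorize an all-zero feature matrix")
    keep = evals > spec.rank_tol * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    V = (M @ evecs) / np.sqrt(evals)
    if spec.kind == "projection":
        evals = np.ones_like(evals)
    return SpectralFactors(eigenvalues=evals, eigenvectors=V, d=int(evals.size))


def _cross_rotation(X_factors: SpectralFactors,
                    Z_factors: SpectralFactors) -> np.ndarray:
    if X_factors.d == 0:
        raise ValueError("monomorphic or fully-explained SNP")
    if X_factors.n != Z_factors.n:
        raise ValueError("factor sets are not on identical samples")
    return X_factors.eigenvectors.T @ Z_factors.eigenvectors  # d2 x d1


def wlit_statistic(
    Z_factors: SpectralFactors, X_factors: SpectralFactors, n: int
) -> tuple[float, np.ndarray]:
    """Eigenvalue-weighted statistic T = (1/n) tr(D_K R D_L R').

    Returns (T, null_weights) where null_weights = {lam_K,i*lam_L,j/n} are
    the coefficients of the asymptotic weighted-chi-square(1) null of n*T.
    """
    R = _cross_rotation(X_factors, Z_factors)
    lam_k = X_factors.eigenvalues
    lam_l = Z_factors.eigenvalues
    T = float(np.einsum("i,ij,j,ij->", lam_k, R, lam_l, R)) / n
    weights = np.outer(lam_k, lam_l).ravel() / n
    return T, weights


def ulit_statistic(
    Z_factors: SpectralFactors, X_factors: SpectralFactors, n: int
) -> tuple[float, np.ndarray]:
    """Equal-weight statistic T = (1/n) ||R||_F^2 (projection kernels).

    null_weights are d1*d2 copies of 1/n, i.e. n*T ~ chi2(d1*d2)/n under H0.
    """
    R = _cross_rotation(X_factors, Z_factors)
    T = float(np.sum(R * R)) / n
    weights = np.full(R.size, 1.0 / n)
    return T, weights


# ---------------------------------------------------------------------------
# weighted chi-square tail probability (Davies/Imhof + saddlepoint fallback)
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)


def _imhof_sf(q: float, w: np.ndarray, tol: float = 1e-10) -> float:
    """Upper tail P(sum w_i chi2_1 > q) by Imhof's inversion integral.

    The integrand sin(theta(u)) / (u * rho(u)) oscillates with asymptotic
    frequency q/2 under a polynomially decaying envelope 1/(u * rho(u)).
    The integral is truncated at U where the alternating-series bound
    (envelope times a half-wavelength) drops below ``tol``, and evaluated
    by composite Gauss-Legendre with about one oscillation per panel,
    fully vectorized over nodes.
    """

    def log_env(U: float) -> float:
        return -np.log(U) - 0.25 * float(np.sum(np.log1p((w * U) ** 2)))

    # truncation point: 2 * envelope(U) / q <= tol
    U = 1.0 / w.max()
    log_tol = np.log(tol * q / 2.0)
    for _ in range(200):
        if log_env(U) <= log_tol:
            break
        U *= 1.5
    freq = 0.5 * float(w.sum()) + 0.5 * q  # max |theta'(u)|
    n_panels = int(np.ceil(U * freq / (2.0 * np.pi))) + 8
    n_panels = min(n_panels, 400_000)
    edges = np.linspace(0.0, U, n_panels + 1)
    half = 0.5 * (edges[1] - edges[0])
    mids = 0.5 * (edges[:-1] + edges[1:])
    total = 0.0
    chunk = max(1, 65536 // _GL_NODES.size)
    for s in range(0, n_panels, chunk):
        u = (mids[s:s + chunk, None] + half * _GL_NODES[None, :]).ravel()
        theta = 0.5 * np.arctan(np.outer(u, w)).sum(axis=1) - 0.5 * q * u
        log_rho = 0.25 * np.log1p(np.outer(u, w) ** 2).sum(axis=1)
        vals = np.sin(theta) * np.exp(-log_rho) / u
        total += half * float(
            (vals.reshape(-1, _GL_NODES.size) @ _GL_WEIGHTS).sum()
        )
    return 0.5 + total / np.pi


def _saddlepoint_sf(q: float, w: np.ndarray) -> float:
    """Lugannani-Rice (Kuonen) saddlepoint approximation to the upper tail."""
    mean = w.sum()
    if q <= mean:
        return 0.5  # only reached defensively; caller uses this in the tail
    zmax = 1.0 / (2.0 * w.max())

    def kprime(z: float) -> float:
        return float(np.sum(w / (1.0 - 2.0 * z * w))) - q

    zhat = optimize.brentq(kprime, 0.0, zmax * (1.0 - 1e-12), xtol=1e-14)
    K = -0.5 * float(np.sum(np.log1p(-2.0 * zhat * w)))
    K2 = float(np.sum(2.0 * w**2 / (1.0 - 2.0 * zhat * w) ** 2))
    rr = np.sqrt(2.0 * (zhat * q - K))
    vv = zhat * np.sqrt(K2)
    if rr == 0.0:
        return 0.5
    return float(stats.norm.sf(rr + np.log(vv / rr) / rr))


def weighted_chisq_sf(q: float, weights: Sequence[float]) -> float:
    """P(sum_i w_i chi2_1,i > q) for positive weights w.

    Equal weights use the exact chi-square closed form.  Otherwise Imhof's
    characteristic-function inversion is attempted at absolute accuracy
    ~1e-9; when the inversion is unreliable (deep tail, reported error large,
    or a non-positive result) the saddlepoint approximation is used.  The
    result is clipped to (1e-300, 1].
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("need at least one weight")
    if np.any(w < 0):
        raise ValueError("negative weight in the chi-square mixture")
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("need at least one positive weight")
    if q <= 0.0:
        return 1.0
    if np.allclose(w, w[0], rtol=1e-12, atol=0.0):
        p = float(stats.chi2.sf(q / w[0], df=w.size))
        return float(np.clip(p, P_FLOOR, 1.0))

    # deep tail: characteristic-function inversion loses absolute accuracy
    # below ~1e-9, where the saddlepoint approximation is the better tool
    if q > w.sum():
        p_sp = _saddlepoint_sf(q, w)
        if p_sp < 1e-9:
            return float(np.clip(p_sp, P_FLOOR, 1.0))
    p = _imhof_sf(q, w)
    if not np.isfinite(p) or p <= 1e-9 or p > 1.0:
        p = _saddlepoint_sf(q, w) if q > w.sum() else np.clip(p, 0.0, 1.0)
    return float(np.clip(p, P_FLOOR, 1.0))


def cauchy_combine(pvalues: Sequence[float]) -> float:
    """Cauchy combination test (CCT) of p-values.

    T' = mean_c tan((0.5 - p_c) * pi); the combined p-value is the standard
    Cauchy upper-tail of T'.  Valid under arbitrary dependence at small
    significance levels.  Tiny p use the asymptote tan((0.5-p)pi) ~ 1/(p pi),
    which keeps deep-tail inputs (p ~ 1e-46) exact instead of clipping them;
    a huge T' maps back through p ~ 1/(pi T').  Inputs are clipped only at
    the floating-point edges (1e-300, 1 - 1e-15).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cauchy_combine needs at least one p-value")
    if np.any(~np.isfinite(p)):
        raise ValueError("non-finite p-value")
    p = np.clip(p, P_FLOOR, 1.0 - 1e-15)
    t = np.where(p < 1e-10, 1.0 / (p * np.pi), np.tan((0.5 - p) * np.pi))
    T = float(t.mean())
    if T > 1e15:
        combined = 1.0 / (np.pi * T)
    else:
        combined = float(stats.cauchy.sf(T))
    return float(np.clip(combined, P_FLOOR, 1.0))


# ---------------------------------------------------------------------------
# single-SNP and region tests
# ---------------------------------------------------------------------------

def _as_feature_matrix(Z: Union[SqCpMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(Z, SqCpMatrix):
        vals = Z.values
        if not Z.centered:
            vals = vals - vals.mean(axis=0)
        return vals
    vals = np.asarray(Z, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    return vals - vals.mean(axis=0)


def _permutation_pvalues(
    Zf: SpectralFactors,
    x: np.ndarray,
    t_wlit: float,
    t_ulit: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation p-values for a single-SNP test (d2 = 1), vectorized.

    With x centered and lam_K = ||x||^2, both statistics depend on x only
    through c = x' V_L: T_w = (1/n) sum_i lam_L,i c_i^2 and
    T_u = (1/n) c'c / ||x||^2.  Permuting x therefore reduces to a single
    (n_perm x n) @ (n x d1) product.
    """
    n = x.shape[0]
    perms = np.empty((n_perm, n), dtype=np.intp)
    for b in range(n_perm):
        perms[b] = rng.permutation(n)
    C = x[perms] @ Zf.eigenvectors  # n_perm x d1
    ssx = float(x @ x)
    tw = (C * C) @ Zf.eigenvalues / n
    tu = (C * C).sum(axis=1) / ssx / n
    p_w = (1 + np.sum(tw >= t_wlit * (1.0 - 1e-12))) / (n_perm + 1)
    p_u = (1 + np.sum(tu >= t_ulit * (1.0 - 1e-12))) / (n_perm + 1)
    return float(p_w), float(p_u)


def lit_single_snp(
    Z: Union[SqCpMatrix, np.ndarray],
    x_adj: np.ndarray,
    *,
    spec: Optional[KernelSpec] = None,
    snp_id: str = "snp",
    min_n: int = 30,
    permutations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> LitResult:
    """Run wLIT, uLIT and their Cauchy aggregate (aLIT) for one SNP.

    ``Z`` holds the centered SQ/CP features (additive SNP effect already
    removed from the residuals); ``x_adj`` is the structure-adjusted,
    mean-zero genotype.  Optional ``permutations`` adds permutation p-values
    for small samples where the asymptotic null may be unreliable.
    """
    if spec is None:
        spec = KernelSpec()
    Zc = _as_feature_matrix(Z)
    x = np.asarray(x_adj, dtype=float).ravel()
    n = x.shape[0]
    if Zc.shape[0] != n:
        raise ValueError("Z and genotype have different sample counts")
    if n < min_n:
        raise ValueError(f"n={n} below the minimum sample count {min_n}")
    x = x - x.mean()
    if not np.any(x != 0.0):
        raise ValueError("monomorphic or fully-explained SNP")

    Zf = spectral_factorize(Zc, spec=KernelSpec("linear", spec.rank_tol))
    Xf = spectral_factorize(x[:, None], spec=KernelSpec("linear", spec.rank_tol))

    t_w, w_weights = wlit_statistic(Zf, Xf, n)
    t_u, _ = ulit_statistic(Zf, Xf, n)
    p_w = weighted_chisq_sf(n * t_w, w_weights)
    p_u = float(np.clip(stats.chi2.sf(n * n * t_u, df=Zf.d * Xf.d),
                        P_FLOOR, 1.0))
    p_a = cauchy_combine([p_w, p_u])

    res = LitResult(
        snp_id=snp_id, t_wlit=t_w, t_ulit=t_u,
        p_wlit=p_w, p_ulit=p_u, p_alit=p_a,
        d1=Zf.d, d2=Xf.d, n_used=n,
    )
    if permutations > 0:
        if rng is None:
            rng = np.random.default_rng()
        # rescale the observed statistics to the permutation parametrization
        ssx = float(x @ x)
        c = (x @ Zf.eigenvectors) / np.sqrt(ssx)
        tw_obs = ssx * float((c * c) @ Zf.eigenvalues) / n
        tu_obs = float(c @ c) / n
        res.p_wlit_perm, res.p_ulit_perm = _permutation_pvalues(
            Zf, x, tw_obs, tu_obs, permutations, rng
        )
    return res


def region_test(
    Z: Union[SqCpMatrix, np.ndarray],
    x_multi: np.ndarray,
    *,
    spec: Optional[KernelSpec] = None,
    region_id: str = "region",
    min_n: int = 30,
) -> LitResult:
    """Region-based LIT over m0 SNPs tested jointly.

    The genotype kernel is built from all m0 structure-adjusted SNP columns;
    d2 is the numerical rank of that matrix (collinear SNPs reduce the rank
    with a warning rather than an error).  With m0 = 1 this reduces exactly
    to :func:`lit_single_snp`.
    """
    if spec is None:
        spec = KernelSpec()
    Zc = _as_feature_matrix(Z)
    X = np.asarray(x_multi, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m0 = X.shape
    if Zc.shape[0] != n:
        raise ValueError("Z and genotype matrix have different sample counts")
    if n < min_n:
        raise ValueError(f"n={n} below the minimum sample count {min_n}")
    X = X - X.mean(axis=0)
    if not np.any(X != 0.0):
        raise ValueError("monomorphic or fully-explained SNP")

    Zf = spectral_factorize(Zc, spec=KernelSpec("linear", spec.rank_tol))
    Xf = spectral_factorize(X, spec=KernelSpec("linear", spec.rank_tol))
    flags: list[str] = []
    if Xf.d < m0:
        warnings.warn(
            f"{region_id}: genotype matrix rank {Xf.d} < {m0} columns "
            "(collinear SNPs); continuing with the reduced rank"
        )
        flags.append("rank_reduced")

    t_w, w_weights = wlit_statistic(Zf, Xf, n)
    t_u, _ = ulit_statistic(Zf, Xf, n)
    p_w = weighted_chisq_sf(n * t_w, w_weights)
    p_u = float(np.clip(stats.chi2.sf(n * n * t_u, df=Zf.d * Xf.d),
                        P_FLOOR, 1.0))
    p_a = cauchy_combine([p_w, p_u])
    return LitResult(
        snp_id=region_id, t_wlit=t_w, t_ulit=t_u,
        p_wlit=p_w, p_ulit=p_u, p_alit=p_a,
        d1=Zf.d, d2=Xf.d, n_used=n, flags=flags,
    )
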