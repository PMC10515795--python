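"""Step 2 of LIT: individual-specific trait variance/covariance estimates.

A latent interaction at a SNP makes the residual trait variance (and the
covariance between pairs of traits) a function of genotype.  Conditional on
genotype X, with trait model Y_k = beta_k X + phi_k M + gamma_k M X + eps_k
and a latent standardized environment M,

    Var(Y_k | X)        = a_k + b_k X + c_k X^2,
    Cov(Y_k, Y_k' | X)  = a~ + b~ X + c~ X^2,

with a = phi^2 + sigma^2, b = 2 phi gamma, c = gamma^2 and the analogous
cross-trait coefficients.  Squared residuals (SQ) estimate the first
quantity per individual; pairwise residual cross products (CP) estimate the
second.  This module assembles the n x (r + r(r-1)/2) matrix Z = [Z_SQ Z_CP]
used by the kernel test, and exposes the population coefficients for
simulator validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .preprocess import ResidualMatrix

__all__ = ["SqCpMatrix", "compute_sqcp", "itv_itc_coefficients"]


@dataclass
class SqCpMatrix:
    """Matrix of squared residuals and residual cross products.

    Columns are ordered SQ(1..r) then CP pairs lexicographically:
    (1,2), (1,3), ..., (r-1,r).
    """

    values: np.ndarray
    column_kinds: list[str] = field(default_factory=list)
    centered: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.column_kinds)


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _pair_indices(r: int) -> tuple[np.ndarray, np.ndarray]:
    if r not in _TRIU_CACHE:
        _TRIU_CACHE[r] = np.triu_indices(r, k=1)
    return _TRIU_CACHE[r]


def sqcp_values(E: np.ndarray, include_cp: bool = True,
                center: bool = True) -> np.ndarray:
    """Raw SQ/CP array from a residual array; hot-path helper (no labels)."""
    n, r = E.shape
    if include_cp:
        i, j = _pair_indices(r)
        Z = np.empty((n, r + i.size), dtype=E.dtype)
        np.multiply(E, E, out=Z[:, :r])
        np.multiply(E[:, i], E[:, j], out=Z[:, r:])
    else:
        Z = E * E
    if center:
        Z -= Z.mean(axis=0)
    return Z


def compute_sqcp(
    residuals: Union[ResidualMatrix, np.ndarray],
    include_cp: bool = True,
    center: bool = True,
) -> SqCpMatrix:
    """Build Z = [Z_SQ Z_CP] from trait residuals.

    ``include_cp=False`` keeps only the squared residuals (the cheaper
    variance-only mode).  ``center=True`` mean-centers every column, which the
    kernel-test null expression assumes.
    """
    if isinstance(residuals, ResidualMatrix):
        E = residuals.values
        names = residuals.trait_names or [
            f"trait{k + 1}" for k in range(E.shape[1])
        ]
    else:
        E = np.asarray(residuals, dtype=float)
        if E.ndim == 1:
            E = E[:, None]
        names = [f"trait{k + 1}" for k in range(E.shape[1])]
    r = E.shape[1]
    if r < 1:
        raise ValueError("need at least one trait")
    if include_cp and r < 2:
        raise ValueError("cross products require at least 2 traits (r >= 2)")

    kinds = [f"SQ:{names[k]}" for k in range(r)]
    if include_cp:
        i, j = np.triu_indices(r, k=1)
        kinds += [f"CP:{names[a]}*{names[b]}" for a, b in zip(i, j)]
    Z = sqcp_values(E, include_cp=include_cp, center=center)
    return SqCpMatrix(values=Z, column_kinds=kinds, centered=center)


def itv_itc_coefficients(
    phi_k: float,
    gamma_k: float,
    sigma_k: float,
    phi_k2: float | None = None,
    gamma_k2: float | None = None,
) -> dict[str, float]:
    """Population ITV/ITC coefficients implied by the single-SNP trait model.

    Returns a, b, c for trait k, and the cross-trait a~, b~, c~ when the
    second trait's (phi, gamma) are supplied.  Used as the closed-form
    reference the simulator's moment-recovery checks compare against.
    """
    if sigma_k < 0:
        raise ValueError("sigma_k must be non-negative")
    out = {
        "a": phi_k**2 + sigma_k**2,
        "b": 2.0 * phi_k * gamma_k,
        "c": gamma_k**2,
    }
    if phi_k2 is not None and gamma_k2 is not None:
        out.update(
            a_cross=phi_k * phi_k2,
            b_cross=phi_k * gamma_k2 + phi_k2 * gamma_k,
            c_cross=gamma_k * gamma_k2,
        )
    return out
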