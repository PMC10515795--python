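"""Step 1 of the LIT pipeline: trait standardization and residualization.

Before any variance/covariance signal can be attributed to a latent
interaction, the *mean* effects of the tested SNP, measured covariates and
population-structure axes must be removed from the traits, and structure must
be removed from the genotype.  This module provides those operations together
with the light container types they exchange.

All regressions include an implicit intercept.  Residualization is ordinary
least squares; leverages (hat-matrix diagonal) are carried along so squared
residuals can be unbiased by internal studentization, e_j / sqrt(1 - h_jj).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TraitMatrix",
    "CovariateMatrix",
    "GenotypeVector",
    "ResidualMatrix",
    "standardize_traits",
    "residualize",
    "adjust_genotype",
    "studentize",
]


@dataclass
class TraitMatrix:
    """n x r matrix of (standardized) phenotypes with sample/trait labels."""

    values: np.ndarray
    sample_ids: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trait values must be a 2-D array")
        self.sample_ids = np.asarray(self.sample_ids)
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match trait rows")
        if len(self.trait_names) != self.values.shape[1]:
            raise ValueError("trait_names length does not match trait columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def r(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateMatrix:
    """n x l design of measured covariates plus structure axes (no intercept)."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if not self.names:
            self.names = [f"covar{i + 1}" for i in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("covariate names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GenotypeVector:
    """Dosages (minor-allele counts in [0, 2]) for one biallelic SNP."""

    dosages: np.ndarray
    snp_id: str = "snp"
    chrom: str = "0"
    pos: int = 0
    ref: str = "A"
    alt: str = "B"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError(f"dosages of {self.snp_id} outside [0, 2]")

    @property
    def maf(self) -> float:
        finite = self.dosages[np.isfinite(self.dosages)]
        freq = float(finite.mean()) / 2.0
        return min(freq, 1.0 - freq)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the observed mean."""
        x = self.dosages.copy()
        miss = ~np.isfinite(x)
        if miss.any():
            x[miss] = x[~miss].mean()
        return x


@dataclass
class ResidualMatrix:
    """OLS residuals per trait plus the leverage of the joint design."""

    values: np.ndarray
    hat_diag: np.ndarray
    dof: int
    trait_names: list[str] = field(default_factory=list)
    studentized: bool = False

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def r(self) -> int:
        return self.values.shape[1]


def standardize_traits(
    raw: np.ndarray,
    groups: Optional[Sequence] = None,
    *,
    trait_names: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence] = None,
    outlier_sd: Optional[float] = None,
) -> TraitMatrix:
    """Standardize each trait to mean 0, sd 1 (sample sd, ddof=1).

    When ``groups`` is given (e.g. sex), standardization is performed within
    each group so that between-group mean differences are removed.  When
    ``outlier_sd`` is set, samples with any trait more than ``outlier_sd``
    standard deviations *above* the (group) mean are dropped before
    standardizing; the conventional cutoff for anthropometric traits is 4.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    n, r = raw.shape
    if trait_names is None:
        trait_names = [f"trait{k + 1}" for k in range(r)]
    trait_names = list(trait_names)
    if sample_ids is None:
        sample_ids = np.arange(n)
    sample_ids = np.asarray(sample_ids)

    if groups is None:
        group_labels = np.zeros(n, dtype=int)
    else:
        group_labels = np.asarray(groups)
        if len(group_labels) != n:
            raise ValueError("groups length does not match number of samples")

    keep = np.ones(n, dtype=bool)
    if outlier_sd is not None:
        for g in np.unique(group_labels):
            idx = group_labels == g
            block = raw[idx]
            mu = block.mean(axis=0)
            sd = block.std(axis=0, ddof=1)
            high = (block - mu) > outlier_sd * sd
            keep[np.flatnonzero(idx)[high.any(axis=1)]] = False

    raw = raw[keep]
    group_labels = group_labels[keep]
    sample_ids = sample_ids[keep]

    out = np.empty_like(raw)
    for g in np.unique(group_labels):
        idx = group_labels == g
        if idx.sum() < 2:
            raise ValueError(f"standardization group {g!r} has fewer than 2 samples")
        block = raw[idx]
        sd = block.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"constant trait column(s) {[trait_names[b] for b in bad]} "
                f"in group {g!r}"
            )
        out[idx] = (block - block.mean(axis=0)) / sd
    return TraitMatrix(out, sample_ids, trait_names)


def _genotype_design(dosages: np.ndarray, dominance: bool) -> np.ndarray:
    """Additive (1-column) or 2-df genotypic (two indicator) coding."""
    if dominance:
        return np.column_stack([(dosages == 1).astype(float),
                                (dosages == 2).astype(float)])
    return dosages[:, None].astype(float)


def _build_design(
    n: int,
    covariates: Optional[CovariateMatrix],
    genotype: Optional[GenotypeVector],
    dominance: bool,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    if covariates is not None:
        if covariates.n != n:
            raise ValueError("covariate rows do not match trait rows")
        cols.append(covariates.values)
        names.extend(covariates.names)
    if genotype is not None:
        x = genotype.mean_imputed()
        if len(x) != n:
            raise ValueError("genotype length does not match trait rows")
        g = _genotype_design(x, dominance)
        cols.append(g)
        if dominance:
            names.extend([f"{genotype.snp_id}:het", f"{genotype.snp_id}:hom"])
        else:
            names.append(genotype.snp_id)
    return np.concatenate(cols, axis=1), names


def _qr_residualize(design: np.ndarray, names: list[str],
                    Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Residuals, hat diagonal and rank via a (pivoted-checked) thin QR."""
    import scipy.linalg

    q, rmat, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rmat))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < design.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        raise ValueError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(dropped)
        )
    coef = q.T @ Y
    resid = Y - q @ coef
    hat = np.einsum("ij,ij->i", q, q)
    return resid, hat, rank


def residualize(
    traits: TraitMatrix,
    covariates: Optional[CovariateMatrix] = None,
    genotype: Optional[GenotypeVector] = None,
    *,
    dominance: bool = False,
    studentized: bool = False,
) -> ResidualMatrix:
    """Regress the additive (or 2-df genotypic) SNP effect, covariates and
    structure axes out of every trait.

    With ``dominance=True`` the genotype enters as two indicator columns
    (het, hom-alt) which absorbs any pure genotype-level mean function.
    """
    Y = traits.values
    design, names = _build_design(traits.n, covariates, genotype, dominance)
    resid, hat, rank = _qr_residualize(design, names, Y)
    out = ResidualMatrix(
        values=resid,
        hat_diag=hat,
        dof=traits.n - rank,
        trait_names=list(traits.trait_names),
    )
    if studentized:
        out = studentize(out)
    return out


def adjust_genotype(
    genotype: GenotypeVector,
    covariates: Optional[CovariateMatrix] = None,
) -> np.ndarray:
    """Mean-center the dosage and remove population-structure mean effects.

    Returns the adjusted genotype vector X-tilde (mean ~ 0), the genotype-side
    feature used by every downstream kernel test.
    """
    x = genotype.mean_imputed()
    n = len(x)
    if covariates is None:
        return x - x.mean()
    design, names = _build_design(n, covariates, None, False)
    resid, _, _ = _qr_residualize(design, names, x[:, None])
    return resid[:, 0]


def studentize(residuals: ResidualMatrix, tol: float = 1e-8) -> ResidualMatrix:
    """Internally studentize residuals: e_j / sqrt(1 - h_jj), then re-center.

    Squared studentized residuals are unbiased for the conditional trait
    variance, which is what the SQ/CP construction estimates.
    """
    h = residuals.hat_diag
    if np.any(h >= 1.0 - tol):
        bad = int(np.argmax(h))
        raise ValueError(
            f"sample {bad} has leverage {h[bad]:.6f} >= 1; its residual is "
            "identically zero and cannot be studentized"
        )
    vals = residuals.values / np.sqrt(1.0 - h)[:, None]
    vals = vals - vals.mean(axis=0)
    return ResidualMatrix(
        values=vals,
        hat_diag=h,
        dof=residuals.dof,
        trait_names=residuals.trait_names,
        studentized=True,
    )
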