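"""Robustness layer: genomic control, LD retest, dominance retest, IAF.

Latent-interaction tests are vulnerable to three artifacts:

* residual confounding/polygenicity inflating the test statistics — handled
  by genomic-control (GC) adjustment of the wLIT/uLIT p-values before their
  Cauchy combination;
* a neighboring SNP in LD whose *additive* effect is imperfectly removed,
  manufacturing heteroskedasticity at the lead SNP — handled by detecting
  additive cross-trait signal at LD neighbors (the same kernel statistic
  applied to the trait matrix itself, GAMuT-style) and regressing the
  significant neighbors out of the traits before retesting;
* dominance or trait-scale misspecification masquerading as interaction —
  handled by removing a 2-df genotypic fit from every trait and retesting.

An optional individual-specific-allele-frequency (IAF) genotype
standardization corrects structure-driven *variance* effects for modest n;
it fits a binomial GLM of allele counts on the structure axes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .kdc import KernelSpec, LitResult, lit_single_snp, region_test
from .preprocess import (
    CovariateMatrix,
    GenotypeVector,
    TraitMatrix,
    adjust_genotype,
    residualize,
)
from .sqcp import compute_sqcp

__all__ = [
    "InflationReport",
    "genomic_inflation",
    "gc_adjust",
    "additive_cross_trait_test",
    "ld_adjust_and_retest",
    "dominance_retest",
    "iaf_standardize",
]

CHI2_1_MEDIAN = 0.4549364231195728  # median of the 1-df chi-square


@dataclass
class InflationReport:
    """Genomic inflation factors per LIT implementation."""

    lambda_gc: dict[str, float]
    n_snps_used: int
    maf_bin_lambdas: Optional[dict[str, list]] = field(default=None)

    def to_json(self) -> str:
        payload = {
            "lambda_gc": self.lambda_gc,
            "n_snps_used": self.n_snps_used,
        }
        if self.maf_bin_lambdas is not None:
            payload["maf_bin_lambdas"] = self.maf_bin_lambdas
        return json.dumps(payload, indent=2)


def genomic_inflation(pvalues: Sequence[float]) -> float:
    """Genomic inflation factor: median association chi-square / 0.4549.

    The p-values should come from an LD-thinned set with genome-wide
    significant SNPs removed, so the median reflects the null bulk.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        warnings.warn(
            f"only {p.size} p-values; the genomic inflation factor "
            "will be noisy"
        )
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def inflation_report(
    pvalues_by_method: dict[str, Sequence[float]],
    mafs: Optional[np.ndarray] = None,
    maf_bins: Optional[Sequence[float]] = None,
) -> InflationReport:
    """Lambda per method, optionally stratified by MAF bin."""
    lam = {m: genomic_inflation(p) for m, p in pvalues_by_method.items()}
    n_used = len(next(iter(pvalues_by_method.values())))
    bins = None
    if mafs is not None and maf_bins is not None:
        mafs = np.asarray(mafs)
        bins = {}
        idx = np.digitize(mafs, maf_bins)
        for m, p in pvalues_by_method.items():
            p = np.asarray(p)
            bins[m] = [
                genomic_inflation(p[idx == b]) if (idx == b).sum() >= 100
                else float("nan")
                for b in range(1, len(maf_bins))
            ]
    return InflationReport(lambda_gc=lam, n_snps_used=n_used,
                           maf_bin_lambdas=bins)


def gc_adjust(pvalues: np.ndarray, lambda_gc: float) -> np.ndarray:
    """Deflate p-values by the genomic inflation factor on the chi-square
    scale: p_adj = SF_chi2(Q_chi2(1-p) / lambda).

    Monotone in p; lambda <= 1 leaves the p-values unchanged (deflation
    only, the standard GC convention).
    """
    p = np.asarray(pvalues, dtype=float)
    if lambda_gc <= 1.0:
        return p.copy()
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return stats.chi2.sf(chi / lambda_gc, df=1)


def additive_cross_trait_test(
    traits_resid: np.ndarray | TraitMatrix,
    x_adj: np.ndarray,
    *,
    spec: Optional[KernelSpec] = None,
    snp_id: str = "snp",
) -> LitResult:
    """Kernel test for *additive* cross-trait association at a SNP.

    The trait-side kernel is built from the traits themselves (residualized
    on covariates/structure but NOT on the tested SNP), so the statistic
    picks up shared mean effects — the multivariate additive test used to
    flag LD neighbors that must be regressed out before a variance test.
    With a single trait it reduces to the marginal additive regression.
    """
    Yr = traits_resid.values if isinstance(traits_resid, TraitMatrix) else \
        np.asarray(traits_resid, dtype=float)
    if Yr.ndim == 1:
        Yr = Yr[:, None]
    Yc = Yr - Yr.mean(axis=0)
    return lit_single_snp(Yc, x_adj, spec=spec, snp_id=snp_id)


def _lit_from_residuals(E: np.ndarray, x_adj: np.ndarray,
                        snp_id: str) -> LitResult:
    Z = compute_sqcp(E, include_cp=E.shape[1] >= 2, center=True)
    return lit_single_snp(Z, x_adj, snp_id=snp_id)


def ld_adjust_and_retest(
    traits: TraitMatrix,
    covariates: Optional[CovariateMatrix],
    lead: GenotypeVector,
    neighbors: Sequence[GenotypeVector],
    *,
    r_threshold: float = 0.1,
    alpha: float = 5e-8,
    studentized: bool = True,
) -> tuple[LitResult, dict]:
    """Regress out LD neighbors with additive effects, then rerun LIT.

    Neighbors (typically all SNPs within 1 Mb of the lead) are screened on
    |correlation| > ``r_threshold`` with the lead SNP and a significant
    additive cross-trait test (p < alpha); the selected SNPs are regressed
    out of the traits jointly before the lead SNP is retested.  With no
    selected neighbor the plain single-SNP result is returned with an
    ``unadjusted`` flag.
    """
    x_lead = lead.mean_imputed()
    x_adj = adjust_genotype(lead, covariates)
    base_resid = residualize(traits, covariates, studentized=False)
    selected = []
    for nb in neighbors:
        xn = nb.mean_imputed()
        r = np.corrcoef(x_lead, xn)[0, 1]
        if abs(r) <= r_threshold:
            continue
        xn_adj = adjust_genotype(nb, covariates)
        res = additive_cross_trait_test(base_resid.values, xn_adj,
                                        snp_id=nb.snp_id)
        if res.p_alit < alpha:
            selected.append(nb)
    info = {
        "n_neighbors": len(neighbors),
        "n_selected": len(selected),
        "selected_ids": [nb.snp_id for nb in selected],
    }
    if not selected:
        resid = residualize(traits, covariates, genotype=lead,
                            studentized=studentized)
        out = _lit_from_residuals(resid.values, x_adj, lead.snp_id)
        out.flags.append("unadjusted")
        return out, info

    nb_mat = np.column_stack([nb.mean_imputed() for nb in selected])
    cov_vals = [covariates.values] if covariates is not None else []
    cov_names = list(covariates.names) if covariates is not None else []
    extended = CovariateMatrix(
        np.column_stack(cov_vals + [nb_mat]),
        names=cov_names + [nb.snp_id for nb in selected],
    )
    resid = residualize(traits, extended, genotype=lead,
                        studentized=studentized)
    out = _lit_from_residuals(resid.values, x_adj, lead.snp_id)
    out.flags.append("ld_adjusted")
    return out, info


def dominance_retest(
    traits: TraitMatrix,
    covariates: Optional[CovariateMatrix],
    genotype: GenotypeVector,
    *,
    studentized: bool = True,
) -> LitResult:
    """Remove a 2-df genotypic (dominance/scale) fit per trait, rerun LIT.

    The two genotype indicator columns absorb any pure genotype-level mean
    function, so a signal that survives cannot be explained by dominance or
    by a monotone trait-scale misspecification acting through the mean.
    """
    levels = np.unique(genotype.mean_imputed().round())
    if levels.size < 2:
        raise ValueError(
            f"{genotype.snp_id} has fewer than 2 genotype levels"
        )
    resid = residualize(traits, covariates, genotype=genotype,
                        dominance=True, studentized=studentized)
    x_adj = adjust_genotype(genotype, covariates)
    out = _lit_from_residuals(resid.values, x_adj, genotype.snp_id)
    out.flags.append("dominance_adjusted")
    return out


def iaf_standardize(
    genotype: GenotypeVector,
    structure_axes: Optional[np.ndarray] = None,
    *,
    eps: float = 1e-4,
    max_n: int = 100_000,
) -> np.ndarray:
    """Standardize a genotype by individual-specific allele frequencies.

    pi_j is fit by a binomial GLM (logit link) of the allele count (out of
    2 trials) on the structure axes; the standardized genotype is
    (X_j - 2 pi_j) / sqrt(2 pi_j (1 - pi_j)).  Without axes this is the
    usual (X - 2 p) / sqrt(2 p (1 - p)).  Intended for modest sample sizes;
    the GLM per SNP is too costly genome-wide at biobank scale.
    """
    x = genotype.mean_imputed()
    n = len(x)
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds the IAF ceiling ({max_n}); use mean-effect "
            "structure adjustment plus genomic control instead"
        )
    p_hat = x.mean() / 2.0
    if p_hat <= 0.0 or p_hat >= 1.0:
        raise ValueError(f"{genotype.snp_id} is monomorphic")
    if structure_axes is None:
        pi = np.full(n, p_hat)
    else:
        import statsmodels.api as sm

        A = np.asarray(structure_axes, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        design = sm.add_constant(A)
        counts = np.column_stack([x, 2.0 - x])
        model = sm.GLM(counts, design, family=sm.families.Binomial())
        pi = np.asarray(model.fit().predict(design))
    if np.any((pi <= eps) | (pi >= 1 - eps)):
        warnings.warn(
            f"{genotype.snp_id}: fitted allele frequencies clipped to "
            f"[{eps}, {1 - eps}]"
        )
        pi = np.clip(pi, eps, 1 - eps)
    return (x - 2.0 * pi) / np.sqrt(2.0 * pi * (1.0 - pi))
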