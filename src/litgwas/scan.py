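"""Genome-scan driver: QC, chunked per-SNP testing, deterministic output.

The scan residualizes the traits on the covariate design H once, then for
each SNP removes its additive effect from those residuals via the
Frisch-Waugh-Lovell identity (exactly equivalent to refitting the full
design per SNP), rebuilds the SQ/CP features and runs LIT plus the marginal
procedures.  SNPs are dispatched in chunks, optionally across joblib
workers; results are emitted in input order regardless of scheduling, so
the output table is identical for any worker count or chunk size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import analyze_snp
from .plink import PlinkReader, read_plink
from .preprocess import CovariateMatrix, standardize_traits, _qr_residualize

__all__ = ["ScanConfig", "hwe_exact_p", "qc_filter", "scan", "load_phenotypes"]


@dataclass
class ScanConfig:
    """Configuration of a genome scan."""

    genotype_prefix: str = ""
    phenotype_file: str = ""
    trait_cols: list[str] = field(default_factory=list)
    covariate_cols: list[str] = field(default_factory=list)
    structure_cols: list[str] = field(default_factory=list)
    group_col: Optional[str] = None
    min_maf: float = 0.05
    max_missing: float = 0.05
    hwe_p: float = 1e-5
    alpha: float = 5e-8
    sq_only: bool = False
    studentized: bool = True
    outlier_sd: Optional[float] = 4.0
    gc_adjust: bool = False
    chunk_size: int = 1_000
    workers: int = 1
    seed: int = 0
    output_prefix: str = "litgwas"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0.0 <= self.max_missing <= 1.0):
            raise ValueError("max_missing must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "ScanConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, Wigginton-style).

    Sums the probabilities of all heterozygote counts (given the allele
    counts) no more likely than the observed one, using the stable
    recurrence on P(het = k).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # heterozygote counts share the parity of the rare-allele count
    het_vals = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(het_vals.size)
    # start from the midpoint and apply the ratio recurrence both ways
    mid_idx = np.argmin(np.abs(het_vals - rare * (2 * n - rare) / (2 * n)))
    probs[mid_idx] = 1.0
    for i in range(mid_idx, probs.size - 1):
        het = het_vals[i]
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # P(het+2)/P(het) = 4*hom_r*hom_c / ((het+2)*(het+1))
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
    for i in range(mid_idx, 0, -1):
        het = het_vals[i]
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # P(het-2)/P(het) = het*(het-1) / (4*(hom_r+1)*(hom_c+1))
        probs[i - 1] = probs[i] * het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    obs = np.searchsorted(het_vals, n_het)
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def qc_filter(reader: PlinkReader, config: ScanConfig,
              sample_mask: Optional[np.ndarray] = None
              ) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply MAF / missingness / HWE filters; returns kept indices + report."""
    rows = []
    keep = []
    for i, dose in reader.iter_snps():
        if sample_mask is not None:
            dose = dose[sample_mask]
        miss = np.mean(~np.isfinite(dose))
        obs = dose[np.isfinite(dose)]
        if obs.size == 0:
            rows.append((reader.bim.snp_id[i], np.nan, 1.0, np.nan, "all_missing"))
            continue
        freq = obs.mean() / 2.0
        maf = min(freq, 1 - freq)
        n_hom1 = int((obs == 2).sum())
        n_het = int((obs == 1).sum())
        n_hom2 = int((obs == 0).sum())
        hwe = hwe_exact_p(n_het, n_hom1, n_hom2) if maf > 0 else np.nan
        reason = ""
        if maf <= config.min_maf:
            reason = "maf"
        elif miss >= config.max_missing:
            reason = "missingness"
        elif np.isfinite(hwe) and hwe <= config.hwe_p:
            reason = "hwe"
        rows.append((reader.bim.snp_id[i], maf, miss, hwe, reason))
        if not reason:
            keep.append(i)
    report = pd.DataFrame(rows, columns=["snp_id", "maf", "missingness",
                                         "hwe_p", "dropped_for"])
    return np.asarray(keep, dtype=int), report


def load_phenotypes(path: str) -> pd.DataFrame:
    """Delimited phenotype/covariate table; first column(s) are sample IDs.

    Accepts either a single ID column or a PLINK-style FID/IID pair (the
    IID is used for alignment).  Separator is sniffed between tab and comma.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    cols = [c.lower() for c in df.columns]
    if cols[:2] == ["fid", "iid"]:
        df = df.rename(columns={df.columns[1]: "IID"}).drop(columns=df.columns[0])
    else:
        df = df.rename(columns={df.columns[0]: "IID"})
    df["IID"] = df["IID"].astype(str)
    return df


def _prepare(config: ScanConfig):
    """Load, align, QC and residualize; returns everything the scan needs."""
    reader = read_plink(config.genotype_prefix)
    pheno = load_phenotypes(config.phenotype_file)
    need = list(config.trait_cols) + list(config.covariate_cols) + \
        list(config.structure_cols) + ([config.group_col] if config.group_col else [])
    pheno = pheno.dropna(subset=[c for c in need if c in pheno.columns])

    fam_iids = reader.fam.iid.astype(str)
    common = pd.Index(fam_iids).intersection(pd.Index(pheno.IID))
    if len(common) == 0:
        raise ValueError("no samples shared between .fam and phenotype file")
    pheno = pheno.set_index("IID").loc[fam_iids[fam_iids.isin(common)]]
    sample_mask = fam_iids.isin(common).to_numpy()

    traits = standardize_traits(
        pheno[config.trait_cols].to_numpy(float),
        groups=pheno[config.group_col].to_numpy() if config.group_col else None,
        trait_names=list(config.trait_cols),
        sample_ids=pheno.index.to_numpy(),
        outlier_sd=config.outlier_sd,
    )
    # outlier removal may drop samples; rebuild the mask accordingly
    kept_ids = pd.Index(traits.sample_ids.astype(str))
    sample_mask = fam_iids.isin(kept_ids).to_numpy()
    pheno = pheno.loc[kept_ids]

    cov_cols = list(config.covariate_cols) + list(config.structure_cols)
    n = traits.n
    if cov_cols:
        H = CovariateMatrix(pheno[cov_cols].to_numpy(float), names=cov_cols)
        design = np.column_stack([np.ones(n), H.values])
        E0, h0, _ = _qr_residualize(design, ["intercept"] + cov_cols,
                                    traits.values)
    else:
        H = None
        E0 = traits.values - traits.values.mean(axis=0)
        h0 = np.full(n, 1.0 / n)

    if config.structure_cols:
        S = pheno[config.structure_cols].to_numpy(float)
        s_design = np.column_stack([np.ones(n), S])
    else:
        s_design = np.ones((n, 1))
    # genotype-side projector: x_adj = x - s_design (s_design^+ x)
    s_q, _ = np.linalg.qr(s_design)

    # effective test counts, once per dataset from the H-residualized Z
    from .pipeline import _effective_tests_from_gram
    from .sqcp import sqcp_values

    Zbase = sqcp_values(E0, include_cp=not config.sq_only, center=True)
    gram = Zbase.T @ Zbase
    K_sqcp = _effective_tests_from_gram(gram)
    r = E0.shape[1]
    K_sq = _effective_tests_from_gram(gram[:r, :r]) if not config.sq_only \
        else K_sqcp

    keep_idx, qc_report = qc_filter(reader, config, sample_mask)
    return reader, sample_mask, E0, h0, s_q, (K_sq, K_sqcp), keep_idx, qc_report


def _scan_chunk(reader, indices, sample_mask, E0, h0, s_q, Ks,
                config) -> list[dict]:
    rows = []
    for i in indices:
        dose = reader.snp_dosages(i)[sample_mask]
        miss = ~np.isfinite(dose)
        if miss.any():
            dose = dose.copy()
            dose[miss] = dose[~miss].mean()
        x_adj = dose - s_q @ (s_q.T @ dose)
        bim = reader.bim.iloc[i]
        try:
            res = analyze_snp(E0, x_adj, h0,
                              include_cp=not config.sq_only,
                              studentized=config.studentized,
                              K_sq=Ks[0], K_sqcp=Ks[1])
        except ValueError as exc:
            warnings.warn(f"{bim.snp_id}: {exc}; skipped")
            continue
        freq = dose.mean() / 2.0
        rows.append({
            "snp_id": bim.snp_id, "chrom": bim.chrom, "pos": bim.pos,
            "maf": min(freq, 1 - freq), "n": E0.shape[0],
            "d1": res["d1"], "d2": res["d2"],
            "T_wlit": res["t_wlit"], "p_wlit": res["p_wlit"],
            "T_ulit": res["t_ulit"], "p_ulit": res["p_ulit"],
            "p_alit": res["p_alit"],
            "minp_sq": res["minp_sq"], "K_sq": res["K_sq"],
            "minp_sqcp": res["minp_sqcp"], "K_sqcp": res["K_sqcp"],
        })
    return rows


def scan(config: ScanConfig, write: bool = True) -> pd.DataFrame:
    """Run the genome scan described by ``config``.

    Returns the per-SNP results table (and writes
    ``<output_prefix>.results.tsv`` plus a QC report unless ``write`` is
    False).  Output is deterministic and independent of ``workers`` /
    ``chunk_size``.
    """
    reader, sample_mask, E0, h0, s_q, Ks, keep_idx, qc_report = \
        _prepare(config)
    if keep_idx.size == 0:
        warnings.warn("no SNPs pass QC; returning an empty table")
        result = pd.DataFrame()
    else:
        n_chunks = max(1, math.ceil(keep_idx.size / config.chunk_size))
        chunks = np.array_split(keep_idx, n_chunks)
        if config.workers > 1:
            from joblib import Parallel, delayed

            parts = Parallel(n_jobs=config.workers)(
                delayed(_scan_chunk)(reader, ch, sample_mask, E0, h0, s_q,
                                     Ks, config)
                for ch in chunks
            )
        else:
            parts = [_scan_chunk(reader, ch, sample_mask, E0, h0, s_q, Ks,
                                 config)
                     for ch in chunks]
        result = pd.DataFrame([row for part in parts for row in part])

    if write:
        out = config.output_prefix
        result.to_csv(out + ".results.tsv", sep="\t", index=False,
                      float_format="%.6e")
        qc_report.to_csv(out + ".qc.tsv", sep="\t", index=False)
    return result
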