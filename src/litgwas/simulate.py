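"""Polygenic GxE trait simulator and the power / type-I-error experiments.

The generative model produces r correlated traits for n unrelated
individuals from m biallelic SNPs:

    Y_jk = alpha_k + b1_k X_j1 + phi_k M_j + gamma_k M_j X_j1
           + (background polygenic score over SNPs 2..m) + W_j + eps_jk

where M is the latent interacting environment and W a second, shared
non-interacting environment.  Every component is standardized to mean 0,
sd 1 (the GxE product M*X is formed *before* standardization) and then
scaled by the square root of its target percent-variance-explained (PVE):

    risk SNP            0.2%
    interacting env     U(0.5%, 2.0%)   per trait
    GxE interaction     U(0.1%, 0.15%)  per trait (interacting traits only)
    shared env W        15%
    background genetics 10% / 35% / 60%
    noise               the remainder

The shared environment and the background score use one realization (one
beta vector) common to all traits, so the baseline inter-trait correlation
(excluding the risk SNP, M and GxE) is exactly 15% + background PVE, i.e.
0.25, 0.50 or 0.75.  Pleiotropy modes set the sign pattern of the GxE
effects across traits; the additive and environmental effect directions are
identical across traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import analyze_snp

__all__ = [
    "SimConfig",
    "SimDataset",
    "scale_component",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_dataset",
    "simulate_null_batch",
    "power_experiment",
    "type_i_error_experiment",
]

PLEIOTROPY_MODES = ("positive", "mixed", "positive_opposed", "mixed_opposed")
ERROR_DISTS = ("normal", "chisq5", "t3")


@dataclass
class SimConfig:
    """Full specification of one simulated study condition."""

    n: int = 300_000
    r: int = 10
    m: int = 100
    maf_interacting: float = 0.25
    maf_range: tuple[float, float] = (0.1, 0.4)
    baseline_corr: float = 0.25
    pve_env_noninteracting: float = 0.15
    pve_risk_snp: float = 0.002
    pve_interacting_env_range: tuple[float, float] = (0.005, 0.02)
    pve_gxe_range: tuple[float, float] = (0.001, 0.0015)
    tau: float = 1.0
    pleiotropy_mode: str = "positive"
    error_dist: str = "normal"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.error_dist not in ERROR_DISTS:
            raise ValueError(f"unknown error_dist {self.error_dist!r}")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if self.pve_additive_background < 0:
            raise ValueError(
                "baseline_corr must be >= pve_env_noninteracting "
                "(background PVE would be negative)"
            )
        worst = (
            self.pve_risk_snp
            + self.pve_interacting_env_range[1]
            + self.pve_gxe_range[1]
            + self.pve_env_noninteracting
            + self.pve_additive_background
        )
        if worst >= 1.0:
            raise ValueError(f"PVE budget sums to {worst:.3f} >= 1")

    @property
    def pve_additive_background(self) -> float:
        """Background-genetics PVE implied by the baseline correlation."""
        return self.baseline_corr - self.pve_env_noninteracting

    @property
    def n_interacting(self) -> int:
        return int(round(self.tau * self.r))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimDataset:
    """One realization of the generative model plus its ground truth."""

    genotypes: np.ndarray  # n x m int8 counts in {0,1,2}
    mafs: np.ndarray
    traits: np.ndarray  # n x r
    config: SimConfig
    truth: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.traits.shape[0]

    @property
    def r(self) -> int:
        return self.traits.shape[1]


def scale_component(x: np.ndarray) -> np.ndarray:
    """Standardize a component to mean 0, sd 1 (sample sd); idempotent."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("cannot standardize a constant component")
    return (x - x.mean()) / sd


def _binomial2(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    """n x len(p) Binomial(2, p_t) draws as int8, chunked over SNPs."""
    m = p.size
    out = np.empty((n, m), dtype=np.int8)
    p32 = p.astype(np.float32)
    chunk = max(1, int(2**26 // max(n, 1)))  # ~256 MB of float32 per chunk
    for s in range(0, m, chunk):
        e = min(m, s + chunk)
        block = p32[s:e]
        g = (rng.random((n, e - s), dtype=np.float32) < block).astype(np.int8)
        g += rng.random((n, e - s), dtype=np.float32) < block
        out[:, s:e] = g
    return out


def simulate_genotypes(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype matrix X ~ Binomial(2, maf_t) and the MAF vector.

    SNP 1 (the SNP with an interacting partner) has MAF fixed at
    ``maf_interacting``; SNPs 2..m draw their MAF from ``maf_range``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mafs = np.empty(config.m)
    mafs[0] = config.maf_interacting
    mafs[1:] = rng.uniform(*config.maf_range, size=config.m - 1)
    G = _binomial2(rng, mafs, config.n)
    return G, mafs


def _background_score(G: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Polygenic score over SNPs 2..m, chunked to avoid a big float copy."""
    n = G.shape[0]
    score = np.zeros(n)
    chunk = 512
    for s in range(1, G.shape[1], chunk):
        e = min(G.shape[1], s + chunk)
        score += G[:, s:e].astype(np.float32) @ beta[s - 1:e - 1].astype(np.float32)
    return score


def _draw_errors(rng: np.random.Generator, n: int, r: int,
                 dist: str) -> np.ndarray:
    if dist == "normal":
        return rng.standard_normal((n, r))
    if dist == "chisq5":
        return rng.chisquare(5, size=(n, r))
    if dist == "t3":
        return rng.standard_t(3, size=(n, r))
    raise ValueError(dist)


def _gxe_signs(rng: np.random.Generator, mode: str,
               n_int: int) -> tuple[np.ndarray, np.ndarray]:
    """(gamma signs for interacting traits, phi sign multiplier per trait).

    The environment effect direction is the same in every trait (+1) except
    in mixed_opposed, where each interacting trait's phi sign is set
    opposite its gamma sign so the interaction opposes the environment.
    """
    if mode == "positive":
        g = np.ones(n_int)
        phi_mult = None
    elif mode == "positive_opposed":
        g = -np.ones(n_int)
        phi_mult = None
    elif mode == "mixed":
        g = rng.choice([-1.0, 1.0], size=n_int)
        phi_mult = None
    elif mode == "mixed_opposed":
        g = rng.choice([-1.0, 1.0], size=n_int)
        phi_mult = -g
    else:
        raise ValueError(mode)
    return g, phi_mult


def simulate_traits(
    genotypes: np.ndarray,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    mafs: Optional[np.ndarray] = None,
) -> SimDataset:
    """Draw the trait matrix given genotypes; returns the full SimDataset.

    The ``truth`` dict stores every standardized shared component and the
    per-trait loadings (sqrt PVE with sign), which is sufficient to
    recompute each component's realized PVE.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G = genotypes
    n, m = G.shape
    r = config.r
    n_int = config.n_interacting

    x1 = G[:, 0].astype(float)
    M = rng.standard_normal(n)
    W = rng.standard_normal(n)
    beta_bg = rng.normal(0.0, 0.01, size=m - 1)
    # raw draws for phi/gamma set nothing but signs; magnitudes come from
    # the PVE budget below
    risk_std = scale_component(x1)
    env_std = scale_component(M)
    gxe_std = scale_component(M * x1)  # product formed before standardization
    bg_std = scale_component(_background_score(G, beta_bg))
    w_std = scale_component(W)

    pve_env = rng.uniform(*config.pve_interacting_env_range, size=r)
    pve_gxe = np.zeros(r)
    gamma_sign = np.zeros(r)
    phi_sign = np.ones(r)
    if n_int > 0:
        pve_gxe[:n_int] = rng.uniform(*config.pve_gxe_range, size=n_int)
        g_signs, phi_mult = _gxe_signs(rng, config.pleiotropy_mode, n_int)
        gamma_sign[:n_int] = g_signs
        if phi_mult is not None:
            phi_sign[:n_int] = phi_mult

    l_risk = np.full(r, np.sqrt(config.pve_risk_snp))
    l_env = phi_sign * np.sqrt(pve_env)
    l_gxe = gamma_sign * np.sqrt(pve_gxe)
    l_bg = np.full(r, np.sqrt(config.pve_additive_background))
    l_w = np.full(r, np.sqrt(config.pve_env_noninteracting))
    pve_noise = 1.0 - (
        config.pve_risk_snp + pve_env + pve_gxe
        + config.pve_env_noninteracting + config.pve_additive_background
    )
    if np.any(pve_noise < 0):
        raise ValueError("PVE budget exceeds 1 for at least one trait")
    l_noise = np.sqrt(pve_noise)

    eps = _draw_errors(rng, n, r, config.error_dist)
    eps -= eps.mean(axis=0)
    eps /= eps.std(axis=0, ddof=1)

    alphas = rng.normal(0.0, 5.0, size=r)
    Y = (
        alphas
        + np.outer(risk_std, l_risk)
        + np.outer(env_std, l_env)
        + np.outer(bg_std, l_bg)
        + np.outer(w_std, l_w)
        + eps * l_noise
    )
    if n_int > 0:
        Y += np.outer(gxe_std, l_gxe)

    truth = {
        "alphas": alphas,
        "pve_env": pve_env,
        "pve_gxe": pve_gxe,
        "gamma_sign": gamma_sign,
        "phi_sign": phi_sign,
        "loadings": {
            "risk": l_risk, "env": l_env, "gxe": l_gxe,
            "background": l_bg, "shared_env": l_w, "noise": l_noise,
        },
        "components": {
            "risk": risk_std, "env": env_std, "gxe": gxe_std,
            "background": bg_std, "shared_env": w_std,
        },
        "beta_background": beta_bg,
        "interacting_snp": 0,
        "interacting_traits": np.arange(n_int),
    }
    if mafs is None:
        mafs = G.mean(axis=0) / 2.0
    return SimDataset(genotypes=G, mafs=np.asarray(mafs), traits=Y,
                      config=config, truth=truth)


def simulate_dataset(config: SimConfig,
                     rng: Optional[np.random.Generator] = None) -> SimDataset:
    """Convenience: genotypes + traits from one config and one rng."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G, mafs = simulate_genotypes(config, rng)
    return simulate_traits(G, config, rng, mafs=mafs)


def simulate_null_batch(
    config: SimConfig,
    n_datasets: int = 50,
    snps_per_dataset: int = 10_000,
    seed: Optional[int] = None,
) -> Iterator[SimDataset]:
    """Stream null datasets (no GxE anywhere) for type-I-error studies.

    Traits keep their additive and environmental components; only the
    interaction is absent (tau = 0).  Non-normal errors are centered and
    scaled to unit variance inside the trait construction.
    """
    base = config.to_dict()
    base.update(tau=0.0, m=snps_per_dataset, seed=None)
    cfg = SimConfig(**base)
    seeds = np.random.SeedSequence(seed if seed is not None else config.seed)
    for child in seeds.spawn(n_datasets):
        rng = np.random.default_rng(child)
        yield simulate_dataset(cfg, rng)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

METHODS = ("alit", "wlit", "ulit", "marginal_sq", "marginal_sqcp")


def _rep_pvalues(config: SimConfig, rng: np.random.Generator) -> dict:
    """One replicate: simulate a dataset, test the interacting SNP."""
    ds = simulate_dataset(config, rng)
    Y = ds.traits
    Ystd = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    x = ds.genotypes[:, 0].astype(float)
    return analyze_snp(Ystd, x - x.mean(), h0=1.0 / ds.n)


def power_experiment(
    configs: Sequence[SimConfig] | SimConfig,
    n_reps: int = 500,
    alpha: float = 5e-8,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Empirical power of every method at the interacting SNP.

    For each config cell, ``n_reps`` datasets are simulated and the tests
    run at SNP 1 only; power is the fraction of p-values (or, for the
    marginal procedures, Bonferroni decisions at alpha / K) below alpha.
    Returns one row per cell with powers and binomial standard errors.
    """
    if isinstance(configs, SimConfig):
        configs = [configs]
    rows = []
    top = np.random.SeedSequence(seed)
    for cfg, cell_seq in zip(configs, top.spawn(len(configs))):
        hits = {meth: 0 for meth in METHODS}
        for child in cell_seq.spawn(n_reps):
            res = _rep_pvalues(cfg, np.random.default_rng(child))
            hits["alit"] += res["p_alit"] < alpha
            hits["wlit"] += res["p_wlit"] < alpha
            hits["ulit"] += res["p_ulit"] < alpha
            hits["marginal_sq"] += res["minp_sq"] < alpha / res["K_sq"]
            hits["marginal_sqcp"] += res["minp_sqcp"] < alpha / res["K_sqcp"]
        row = {
            "n": cfg.n, "r": cfg.r, "tau": cfg.tau,
            "baseline_corr": cfg.baseline_corr,
            "pleiotropy_mode": cfg.pleiotropy_mode,
            "alpha": alpha, "n_reps": n_reps,
        }
        for meth in METHODS:
            p_hat = hits[meth] / n_reps
            row[f"power_{meth}"] = p_hat
            row[f"se_{meth}"] = np.sqrt(p_hat * (1 - p_hat) / n_reps)
        rows.append(row)
    return pd.DataFrame(rows)


def type_i_error_experiment(
    config: SimConfig,
    n_datasets: int = 50,
    snps_per_dataset: int = 10_000,
    alpha: float = 1e-3,
    seed: Optional[int] = None,
    collect_pvalues: bool = False,
) -> dict:
    """Empirical type-I error of each method over null datasets.

    Every SNP in every null dataset is tested (its own additive effect is
    removed first, exactly as in a scan), and the rejection fraction at
    ``alpha`` is reported with an exact 95% binomial (Clopper-Pearson)
    interval for the null expectation.
    """
    counts = {meth: 0 for meth in METHODS}
    pvals = {meth: [] for meth in METHODS} if collect_pvalues else None
    total = 0
    for ds in simulate_null_batch(config, n_datasets, snps_per_dataset, seed):
        Y = ds.traits
        Ystd = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
        n = ds.n
        K_sq = K_sqcp = None  # computed at the first SNP, reused after
        for t in range(ds.genotypes.shape[1]):
            x = ds.genotypes[:, t].astype(float)
            xc = x - x.mean()
            if not np.any(xc != 0.0):
                continue
            res = analyze_snp(Ystd, xc, h0=1.0 / n, K_sq=K_sq, K_sqcp=K_sqcp)
            K_sq, K_sqcp = res["K_sq"], res["K_sqcp"]
            counts["alit"] += res["p_alit"] < alpha
            counts["wlit"] += res["p_wlit"] < alpha
            counts["ulit"] += res["p_ulit"] < alpha
            counts["marginal_sq"] += res["minp_sq"] < alpha / res["K_sq"]
            counts["marginal_sqcp"] += res["minp_sqcp"] < alpha / res["K_sqcp"]
            if collect_pvalues:
                pvals["alit"].append(res["p_alit"])
                pvals["wlit"].append(res["p_wlit"])
                pvals["ulit"].append(res["p_ulit"])
            total += 1
    out = {
        "total_tests": total,
        "alpha": alpha,
        "rates": {m: counts[m] / total for m in METHODS},
        "counts": dict(counts),
    }
    from scipy.stats import binom

    out["binom_interval_95"] = tuple(
        int(v) for v in binom.interval(0.95, total, alpha)
    )
    if collect_pvalues:
        out["pvalues"] = {m: np.asarray(v) for m, v in pvals.items()}
    return out
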