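"""Two-population GWAS summary-statistics simulator with known truth.

Generates the inputs the MR pipeline consumes — per-trait, per-population
summary-statistics tables and block-diagonal LD matrices — directly on the
estimate scale, without individual-level genotypes: observed effects are
the true marginal effects plus sampling noise with the analytic standard
error implied by allele frequency and sample size.

The generating model mirrors a two-biobank design: quantitative exposures
whose per-SNP effects are spike-and-slab, correlated between populations
on the slab; a binary outcome on the log-odds scale whose true SNP
effects are the causal combination of the exposure effects plus direct
(horizontally pleiotropic) effects for a configurable fraction of causal
variants; LD as block-diagonal correlation, which both propagates causal
effects to tagging SNPs and correlates their sampling noise; and optional
exposure/outcome sample overlap, emulated as correlated sampling noise
with correlation (overlap rate x phenotypic correlation).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ivselect import LdMatrix
from .sumstats import SummaryStats, TraitMeta, effective_n

DEFAULT_POPS = ("EAS", "EUR")


@dataclasses.dataclass
class SimConfig:
    """Generating parameters of a simulated two-population MR study.

    Defaults emulate a Biobank-Japan-scale and a UK-Biobank-scale GWAS of
    one quantitative exposure and a binary outcome.  ``causal_effect``
    maps exposure -> population -> true causal effect on the outcome
    (log-odds per exposure SD); a bare float applies to both populations.
    """

    n_snps: int = 2000
    seed: int = 0
    populations: tuple = DEFAULT_POPS
    exposures: tuple = ("exposure",)
    outcome: str = "outcome"
    # sample sizes: quantitative exposure GWAS N, outcome cases/controls
    n_exposure: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"EAS": 150_000, "EUR": 360_000})
    n_cases: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"EAS": 29_000, "EUR": 60_000})
    n_controls: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"EAS": 170_000, "EUR": 123_000})
    causal_effect: Mapping[str, Mapping[str, float] | float] = dataclasses.field(
        default_factory=lambda: {"exposure": 0.3})
    polygenicity: float = 0.02     # fraction of SNPs with nonzero exposure effect
    effect_sd: float = 0.015       # slab SD of causal exposure effects (SD units)
    cross_pop_effect_corr: float = 0.8
    pleiotropy_frac: float = 0.05  # fraction of causal SNPs with direct outcome effects
    pleiotropy_sd: float = 0.05    # SD of direct effects (log-odds)
    ld_block_size: int = 5
    ld_r2: float = 0.4             # within-block squared correlation
    overlap_rate: float = 0.0      # exposure/outcome sample overlap r
    pheno_corr_xy: float = 0.2     # phenotypic exposure-outcome correlation

    def __post_init__(self):
        for name in ("polygenicity", "pleiotropy_frac", "overlap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.cross_pop_effect_corr <= 1.0:
            raise ValueError("cross_pop_effect_corr must lie in [-1, 1]")
        if not 0.0 <= self.ld_r2 < 1.0:
            raise ValueError("ld_r2 must lie in [0, 1)")
        if self.n_snps < 1 or self.ld_block_size < 1:
            raise ValueError("n_snps and ld_block_size must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def beta_true(self, exposure: str, pop: str) -> float:
        v = self.causal_effect.get(exposure, 0.0)
        if isinstance(v, Mapping):
            return float(v.get(pop, 0.0))
        return float(v)


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated study, for recovery testing."""

    config: SimConfig
    snp_ids: list
    # trait -> pop -> per-SNP true marginal effect (exposures and outcome)
    true_effects: dict
    pleiotropic_snps: list
    causal_beta: dict  # exposure -> pop -> beta

    def to_frame(self) -> pd.DataFrame:
        cols = {"snp": self.snp_ids}
        for trait, pops in self.true_effects.items():
            for pop, eff in pops.items():
                cols[f"{trait}_{pop}"] = eff
        df = pd.DataFrame(cols)
        df["pleiotropic"] = df["snp"].isin(set(self.pleiotropic_snps))
        return df


def _block_corr(n_snps: int, block: int, r2: float) -> np.ndarray:
    """Signed correlation matrix: constant r = sqrt(r2) within blocks."""
    r = np.sqrt(r2)
    c = np.eye(n_snps)
    for start in range(0, n_snps, block):
        stop = min(start + block, n_snps)
        c[start:stop, start:stop] = r
        np.fill_diagonal(c[start:stop, start:stop], 1.0)
    return c


def _block_chol(n_snps: int, block: int, r2: float) -> np.ndarray:
    return np.linalg.cholesky(
        _block_corr(n_snps, block, r2) + 1e-12 * np.eye(n_snps))


def _sumstats_frame(snp_ids, chrom, pos, eaf, beta, se, n) -> pd.DataFrame:
    z = beta / se
    return pd.DataFrame({
        "snp": snp_ids, "chrom": chrom, "pos": pos,
        "ea": "A", "oa": "G", "eaf": eaf,
        "beta": beta, "se": se,
        "p": 2.0 * sps.norm.sf(np.abs(z)),
        "n": n,
    })


def simulate_study(config: SimConfig):
    """Simulate one study; returns ``(stats, ld, truth)``.

    ``stats`` maps (trait, population) to :class:`SummaryStats`; ``ld``
    maps population to :class:`LdMatrix`.  Fully reproducible for a given
    config (the seed is part of the config).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    snp_ids = [f"rs{j + 1}" for j in range(n)]
    chrom = np.repeat("1", n)
    pos = 1 + 10_000 * np.arange(n)

    corr = _block_corr(n, cfg.ld_block_size, cfg.ld_r2)
    chol = _block_chol(n, cfg.ld_block_size, cfg.ld_r2)
    r2 = corr**2
    np.fill_diagonal(r2, 1.0)
    ld = {pop: LdMatrix(list(snp_ids), r2.copy()) for pop in cfg.populations}

    pop_a, pop_b = cfg.populations
    eaf = {pop: rng.uniform(0.05, 0.95, size=n) for pop in cfg.populations}

    # --- true causal and marginal effects --------------------------------
    causal = rng.random(n) < cfg.polygenicity
    c = cfg.cross_pop_effect_corr
    gamma = {}       # exposure -> pop -> marginal effects
    gamma_causal = {}
    for exp_t in cfg.exposures:
        za = rng.standard_normal(n)
        zb = c * za + np.sqrt(max(0.0, 1.0 - c**2)) * rng.standard_normal(n)
        g = {pop_a: np.where(causal, cfg.effect_sd * za, 0.0),
             pop_b: np.where(causal, cfg.effect_sd * zb, 0.0)}
        gamma_causal[exp_t] = g
        gamma[exp_t] = {pop: corr @ g[pop] for pop in cfg.populations}

    causal_idx = np.flatnonzero(causal)
    n_pleio = int(round(cfg.pleiotropy_frac * len(causal_idx)))
    pleio_idx = rng.choice(causal_idx, size=n_pleio, replace=False) \
        if n_pleio else np.array([], dtype=int)
    alpha_causal = np.zeros(n)
    alpha_causal[pleio_idx] = rng.normal(0.0, cfg.pleiotropy_sd, size=n_pleio)
    alpha = corr @ alpha_causal  # shared direct effects across populations

    big_gamma = {}
    for pop in cfg.populations:
        big_gamma[pop] = alpha.copy()
        for exp_t in cfg.exposures:
            big_gamma[pop] += cfg.beta_true(exp_t, pop) * gamma[exp_t][pop]

    # --- sampling noise and observed statistics --------------------------
    rho = cfg.overlap_rate * cfg.pheno_corr_xy
    stats: dict = {}
    for pop in cfg.populations:
        n_exp = cfg.n_exposure[pop]
        n_eff = effective_n(cfg.n_cases[pop], cfg.n_controls[pop])
        se_out = 1.0 / np.sqrt(2.0 * eaf[pop] * (1.0 - eaf[pop]) * n_eff)
        z_shared = chol @ rng.standard_normal(n)
        for exp_t in cfg.exposures:
            se_exp = 1.0 / np.sqrt(2.0 * eaf[pop] * (1.0 - eaf[pop]) * n_exp)
            z_exp = chol @ rng.standard_normal(n)
            beta_obs = gamma[exp_t][pop] + se_exp * z_exp
            stats[(exp_t, pop)] = SummaryStats(
                meta=TraitMeta(exp_t, "quantitative", population=pop,
                               sd_native=1.0),
                table=_sumstats_frame(snp_ids, chrom, pos, eaf[pop],
                                      beta_obs, se_exp, n_exp))
            if exp_t == cfg.exposures[0]:
                z_first_exp = z_exp
        # overlap couples the outcome noise to the first exposure's noise
        z_out = rho * z_first_exp + np.sqrt(1.0 - rho**2) * z_shared
        beta_out = big_gamma[pop] + se_out * z_out
        stats[(cfg.outcome, pop)] = SummaryStats(
            meta=TraitMeta(cfg.outcome, "binary", population=pop,
                           n_cases=cfg.n_cases[pop],
                           n_controls=cfg.n_controls[pop]),
            table=_sumstats_frame(snp_ids, chrom, pos, eaf[pop],
                                  beta_out, se_out, n_eff))

    true_effects = {t: {p: gamma[t][p] for p in cfg.populations}
                    for t in cfg.exposures}
    true_effects[cfg.outcome] = big_gamma
    truth = SimTruth(
        config=cfg, snp_ids=list(snp_ids), true_effects=true_effects,
        pleiotropic_snps=[snp_ids[j] for j in pleio_idx],
        causal_beta={t: {p: cfg.beta_true(t, p) for p in cfg.populations}
                     for t in cfg.exposures},
    )
    return stats, ld, truth


def simulate_pair(n_iv: int, beta: float, rng,
                  bx_sd: float = 0.03, sex: float = 0.003,
                  sey: float = 0.02, pleiotropy_sd: float = 0.0,
                  n_outliers: int = 0, outlier_size: float = 0.0):
    """Directly simulate a harmonized IV set (no selection stage).

    Convenience generator for estimator calibration: ``n_iv`` instruments
    with true exposure effects ~ N(0, bx_sd²), observed with SE ``sex``;
    outcome effects beta*bx plus optional balanced pleiotropy and
    ``n_outliers`` planted directional outliers of ``outlier_size`` (on
    the outcome-effect scale).
    """
    from .sumstats import HarmonizedPair

    bx_true = rng.normal(0.0, bx_sd, size=n_iv)
    by_true = beta * bx_true
    if pleiotropy_sd > 0:
        by_true = by_true + rng.normal(0.0, pleiotropy_sd, size=n_iv)
    if n_outliers:
        by_true = by_true.copy()
        by_true[:n_outliers] += outlier_size
    bx = bx_true + rng.normal(0.0, sex, size=n_iv)
    by = by_true + rng.normal(0.0, sey, size=n_iv)
    ids = np.array([f"iv{j}" for j in range(n_iv)])
    return HarmonizedPair(ids, bx, np.full(n_iv, sex), by, np.full(n_iv, sey),
                          n_exposure=200_000, n_outcome=150_000)


def recovery_report(truth: Mapping[str, Mapping[str, float]] | SimTruth,
                    estimates: pd.DataFrame,
                    alpha: float = 0.05 / 37,
                    level: float = 0.95) -> pd.DataFrame:
    """Bias / RMSE / CI coverage / power of repeated estimates vs truth.

    ``estimates`` is long-format with columns exposure, population (or
    'meta'), beta, se, p over replicates.  Power is the rejection rate at
    ``alpha`` (Bonferroni threshold by default).
    """
    if isinstance(truth, SimTruth):
        truth = truth.causal_beta
    z = sps.norm.ppf(0.5 + level / 2.0)
    required = {"exposure", "population", "beta", "se", "p"}
    if not required <= set(estimates.columns):
        raise ValueError(f"estimates must carry columns {sorted(required)}")
    rows = []
    for (exp_t, pop), grp in estimates.groupby(["exposure", "population"]):
        pops = truth.get(exp_t)
        if pops is None:
            raise ValueError(f"no truth for exposure {exp_t!r}")
        if isinstance(pops, Mapping):
            b_true = (np.mean(list(pops.values())) if pop == "meta"
                      else pops.get(pop))
        else:
            b_true = pops
        if b_true is None:
            raise ValueError(f"no truth for {exp_t!r} in {pop!r}")
        err = grp["beta"] - b_true
        cover = ((grp["beta"] - z * grp["se"] <= b_true)
                 & (b_true <= grp["beta"] + z * grp["se"]))
        rows.append({
            "exposure": exp_t, "population": pop, "beta_true": b_true,
            "n_reps": len(grp), "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "coverage": float(cover.mean()),
            "power": float((grp["p"] < alpha).mean()),
        })
    return pd.DataFrame(rows)
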