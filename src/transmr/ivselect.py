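"""Instrument-selection cascade and instrument-strength diagnostics.

The cascade runs in a fixed order on trans-cohort discovery statistics:

1. discovery meta-analysis of the two cohorts' per-SNP effects;
2. cross-cohort consistency filter (nominal significance in both cohorts,
   concordant effect direction);
3. greedy LD clumping (index SNPs by discovery P, pruning linked
   neighbours within a window);
4. cross-trait pleiotropy screen against all other traits' discovery
   statistics;
5. MR-PRESSO global and per-SNP outlier testing on the harmonized
   exposure-outcome pair.

Every SNP exits with exactly one selection state, so filter counts are
fully auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .meta import EffectEstimate, fe_meta
from .sumstats import HarmonizedPair, SummaryStats

log = logging.getLogger(__name__)

# selection states a candidate IV can end in
STATES = ("candidate", "dropped_consistency", "dropped_clump",
          "dropped_pleiotropy", "dropped_presso", "selected")

# cascade defaults
P_SINGLE = 0.05          # per-cohort consistency threshold
P_META = 5e-8            # discovery / pleiotropy significance
R2_MAX = 0.01            # clumping LD cutoff
WINDOW_BP = 1_000_000    # clump radius each side of the index SNP
PRESSO_ALPHA = 0.05
PRESSO_NSIM = 1000


class InsufficientInstrumentsError(ValueError):
    """Too few IVs for the requested procedure."""


@dataclasses.dataclass
class LdMatrix:
    """Squared-correlation LD matrix over an ordered SNP list."""

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 must be square over snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 must be symmetric")
        if np.any((self.r2 < -1e-12) | (self.r2 > 1 + 1e-12)):
            raise ValueError("r2 entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        self._pos = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a, snp_b) -> float:
        """r² for a pair; missing SNPs are treated as unlinked (r²=0)."""
        ia = self._pos.get(snp_a)
        ib = self._pos.get(snp_b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def read(cls, matrix_path, ids_path) -> "LdMatrix":
        ids = [ln.strip() for ln in open(ids_path) if ln.strip()]
        r2 = np.loadtxt(matrix_path)
        return cls(ids, np.atleast_2d(r2))

    @classmethod
    def from_long(cls, triplets: pd.DataFrame, snp_ids: Sequence) -> "LdMatrix":
        """Build from long-format (snpA, snpB, r2) rows; absent pairs are 0."""
        idx = {s: i for i, s in enumerate(snp_ids)}
        k = len(snp_ids)
        r2 = np.eye(k)
        for a, b, v in triplets.itertuples(index=False):
            if a in idx and b in idx:
                r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = float(v)
        return cls(list(snp_ids), r2)

    def write(self, matrix_path, ids_path) -> None:
        np.savetxt(matrix_path, self.r2, fmt="%.6g")
        with open(ids_path, "w") as fh:
            fh.write("\n".join(map(str, self.snp_ids)) + "\n")


@dataclasses.dataclass(frozen=True)
class InstrumentStrength:
    """Per-set instrument-strength summary: PVE sum, per-IV F, mean F."""

    pve: np.ndarray
    f_stat: np.ndarray
    mean_f: float
    n: float


@dataclasses.dataclass(frozen=True)
class OverlapBias:
    """Approximate bias of an MR estimate from exposure/outcome sample overlap."""

    beta: float
    r: float
    f: float
    bias: float


# ---------------------------------------------------------------------------
# cascade stages

def discovery_meta(cohort_a: SummaryStats, cohort_b: SummaryStats
                   ) -> pd.DataFrame:
    """Per-SNP fixed-effect meta-analysis of two cohorts' effects.

    Both cohorts must already be on a common effect allele and scale.
    Returns the candidate-IV table with per-cohort and meta statistics and
    every SNP in state ``candidate``; SNPs absent from either cohort are
    excluded.
    """
    a = cohort_a.indexed()
    b = cohort_b.indexed()
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no shared SNPs between cohorts")
    a = a.loc[common]
    b = b.loc[common]
    wa = 1.0 / a["se"].to_numpy() ** 2
    wb = 1.0 / b["se"].to_numpy() ** 2
    beta_meta = (wa * a["beta"].to_numpy() + wb * b["beta"].to_numpy()) / (wa + wb)
    se_meta = (wa + wb) ** -0.5
    p_meta = 2.0 * sps.norm.sf(np.abs(beta_meta / se_meta))
    return pd.DataFrame({
        "snp": common,
        "chrom": a["chrom"].to_numpy(),
        "pos": a["pos"].to_numpy(),
        "beta_a": a["beta"].to_numpy(), "se_a": a["se"].to_numpy(),
        "p_a": a["p"].to_numpy(),
        "beta_b": b["beta"].to_numpy(), "se_b": b["se"].to_numpy(),
        "p_b": b["p"].to_numpy(),
        "beta_meta": beta_meta, "se_meta": se_meta, "p_meta": p_meta,
        "state": "candidate", "reason": "",
    }).reset_index(drop=True)


def _mark(df: pd.DataFrame, mask, state: str, reason: str) -> None:
    hit = mask & (df["state"] == "candidate")
    df.loc[hit, "state"] = state
    df.loc[hit, "reason"] = reason


def consistency_filter(candidates: pd.DataFrame,
                       p_single: float = P_SINGLE) -> pd.DataFrame:
    """Drop SNPs not nominally significant in both cohorts or with
    discordant effect directions."""
    df = candidates.copy()
    weak = (df["p_a"] >= p_single) | (df["p_b"] >= p_single)
    discordant = np.sign(df["beta_a"]) != np.sign(df["beta_b"])
    _mark(df, weak, "dropped_consistency", f"P >= {p_single} in a cohort")
    _mark(df, discordant & ~weak, "dropped_consistency", "opposite effects")
    return df


def clump(candidates: pd.DataFrame, ld: LdMatrix,
          r2_max: float = R2_MAX, p_max: float = P_META,
          window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Greedy LD clumping on the discovery meta P.

    Repeatedly takes the remaining candidate with smallest ``p_meta``
    (below ``p_max``) as an index SNP and drops candidates on the same
    chromosome within ``window_bp`` of it with r² >= ``r2_max``.  Ties on
    p_meta break by (chrom, pos, snp).  SNP pairs missing from the LD
    matrix count as unlinked.
    """
    df = candidates.copy()
    live = df.index[df["state"] == "candidate"]
    sub = df.loc[live].sort_values(
        ["p_meta", "chrom", "pos", "snp"], kind="mergesort")
    too_weak = sub.index[sub["p_meta"] >= p_max]
    _mark(df, df.index.isin(too_weak), "dropped_clump", f"p_meta >= {p_max:g}")
    sub = sub[sub["p_meta"] < p_max]

    kept: list = []
    removed: set = set()
    for idx, row in sub.iterrows():
        if idx in removed:
            continue
        kept.append(idx)
        near = sub[(sub["chrom"] == row["chrom"])
                   & ((sub["pos"] - row["pos"]).abs() <= window_bp)]
        for jdx, other in near.iterrows():
            if jdx == idx or jdx in removed or jdx in kept:
                continue
            if ld.lookup(row["snp"], other["snp"]) >= r2_max:
                removed.add(jdx)
    _mark(df, df.index.isin(removed), "dropped_clump", "linked to index SNP")
    return df


def pleiotropy_screen(candidates: pd.DataFrame,
                      other_traits: Mapping[str, pd.DataFrame],
                      p_thresh: float = P_META,
                      exceptions: Iterable[tuple] = ()) -> pd.DataFrame:
    """Drop candidates in genome-wide significant association with any
    non-exposure trait.

    ``other_traits`` maps trait id to that trait's discovery-meta table
    (must carry ``snp`` and ``p_meta``).  ``exceptions`` is an allow-list
    of (snp, trait) pairs exempt from the screen.  SNPs absent from a
    trait's table count as non-significant.
    """
    df = candidates.copy()
    exc = {(str(s), str(t)) for s, t in exceptions}
    hit = pd.Series(False, index=df.index)
    reasons = pd.Series("", index=df.index)
    for trait, table in other_traits.items():
        lut = table.set_index("snp")["p_meta"]
        p_other = df["snp"].map(lut)
        sig = p_other.notna() & (p_other < p_thresh)
        allowed = df["snp"].astype(str).map(lambda s, t=str(trait): (s, t) in exc)
        if (sig & allowed).any():
            log.info("pleiotropy screen: %d exception(s) applied for trait %s",
                     int((sig & allowed).sum()), trait)
        newly = sig & ~allowed & ~hit
        reasons[newly] = f"associated with {trait}"
        hit |= sig & ~allowed
    _mark(df, hit, "dropped_pleiotropy", "")
    df.loc[hit & (df["reason"] == ""), "reason"] = reasons[hit]
    return df


# ---------------------------------------------------------------------------
# MR-PRESSO

def _loo_ivw(bx, by, w):
    """Leave-one-out fixed-effect IVW slopes, vectorised over IVs."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def presso_test(pair: HarmonizedPair, n_sim: int = PRESSO_NSIM,
                seed: int | np.random.Generator = 0,
                alpha: float = PRESSO_ALPHA):
    """Residual-sum-and-outlier (MR-PRESSO style) pleiotropy test.

    For each IV j the outcome effect is compared with the prediction
    ``bx_j * beta_{-j}`` from a leave-one-out IVW fit; the global statistic
    is the sum of weighted squared residuals, referred to a parametric null
    built by ``n_sim`` simulations (outcome effects redrawn about their
    leave-one-out predictions, exposure effects about their observed
    values).  Per-IV outlier P-values are empirical tail probabilities,
    Bonferroni-adjusted; IVs enter the removal set only when the global
    test itself rejects.

    Returns ``(global_p, outlier_p_adjusted_by_snp, removal_snp_ids)``.
    """
    k = len(pair)
    if k < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= 4 instruments, got {k}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bx, by, sex, sey = pair.bx, pair.by, pair.sex, pair.sey
    w = 1.0 / sey**2
    beta_loo = _loo_ivw(bx, by, w)
    rss_obs = w * (by - beta_loo * bx) ** 2
    global_obs = rss_obs.sum()

    # parametric null: redraw effects about the no-pleiotropy expectation
    bx_sim = bx + sex * rng.standard_normal((n_sim, k))
    by_sim = beta_loo * bx + sey * rng.standard_normal((n_sim, k))
    s_xy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s_xx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    beta_loo_sim = (s_xy - w * bx_sim * by_sim) / (s_xx - w * bx_sim * bx_sim)
    rss_sim = w * (by_sim - beta_loo_sim * bx_sim) ** 2

    global_p = float((np.sum(rss_sim.sum(axis=1) >= global_obs) + 1)
                     / (n_sim + 1))
    outlier_p = (np.sum(rss_sim >= rss_obs, axis=0) + 1) / (n_sim + 1)
    outlier_p_adj = np.minimum(outlier_p * k, 1.0)

    removal: list = []
    if global_p < alpha:
        removal = [s for s, p in zip(pair.snp_ids, outlier_p_adj) if p < alpha]
    return global_p, dict(zip(pair.snp_ids, outlier_p_adj)), removal


def apply_presso(candidates: pd.DataFrame, pair: HarmonizedPair,
                 n_sim: int = PRESSO_NSIM, seed=0,
                 alpha: float = PRESSO_ALPHA) -> pd.DataFrame:
    """Run the pleiotropy outlier test and mark removed SNPs; survivors
    become ``selected``."""
    df = candidates.copy()
    live = df["state"] == "candidate"
    ids = set(df.loc[live, "snp"])
    mask = np.array([s in ids for s in pair.snp_ids])
    sub = pair.subset(mask)
    if len(sub) >= 4:
        _, _, removal = presso_test(sub, n_sim=n_sim, seed=seed, alpha=alpha)
        removal = set(removal)
        _mark(df, df["snp"].isin(removal), "dropped_presso",
              "pleiotropy outlier")
    else:
        log.info("MR-PRESSO skipped: only %d instruments", len(sub))
    _mark(df, pd.Series(True, index=df.index), "selected", "")
    return df


# ---------------------------------------------------------------------------
# instrument strength and overlap bias

def compute_pve(beta, se, n) -> np.ndarray | float:
    """Proportion of trait variance explained by an instrument.

    Uses the z-score convention PVE = z^2 / (z^2 + N - 2), which composes
    with :func:`f_statistic` to give F = z^2 exactly.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n <= 1):
        raise ValueError("sample size must exceed 1")
    z2 = (np.asarray(beta, float) / np.asarray(se, float)) ** 2
    out = z2 / (z2 + n - 2.0)
    return float(out) if np.ndim(out) == 0 else out


def compute_pve_eaf(beta, eaf) -> np.ndarray | float:
    """Alternative PVE = 2*eaf*(1-eaf)*beta^2 for quantitative traits whose
    effects are in phenotype-SD units (config switch)."""
    eaf = np.asarray(eaf, dtype=float)
    out = 2.0 * eaf * (1.0 - eaf) * np.asarray(beta, float) ** 2
    return float(out) if np.ndim(out) == 0 else out


def f_statistic(pve, n) -> np.ndarray | float:
    """Instrument-strength F statistic: F = PVE*(N-2)/(1-PVE)."""
    pve = np.asarray(pve, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(pve >= 1) or np.any(pve < 0):
        raise ValueError("PVE must lie in [0, 1)")
    if np.any(n <= 2):
        raise ValueError("sample size must exceed 2")
    out = pve * (n - 2.0) / (1.0 - pve)
    return float(out) if np.ndim(out) == 0 else out


def instrument_strength(beta, se, n) -> InstrumentStrength:
    """Per-IV PVE and F plus the arithmetic mean F over the set."""
    pve = np.atleast_1d(compute_pve(beta, se, n))
    f = np.atleast_1d(f_statistic(pve, n))
    return InstrumentStrength(pve=pve, f_stat=f, mean_f=float(f.mean()),
                              n=float(np.mean(n)))


def overlap_bias(beta: float, r: float, f: float) -> OverlapBias:
    """Approximate sample-overlap bias of an MR estimate: beta * r / F,
    with r the exposure/outcome sample overlap rate and F the mean
    instrument F."""
    if not 0 <= r <= 1:
        raise ValueError("overlap rate must lie in [0, 1]")
    if f <= 0:
        raise ValueError("F must be > 0")
    return OverlapBias(beta=beta, r=r, f=f, bias=beta * r / f)


# ---------------------------------------------------------------------------
# full cascade

def run_cascade(cohort_a: SummaryStats, cohort_b: SummaryStats,
                ld_by_pop: Mapping[str, LdMatrix],
                other_traits: Mapping[str, pd.DataFrame],
                pair_by_pop: Mapping[str, HarmonizedPair] | None = None,
                *, p_single: float = P_SINGLE, p_meta: float = P_META,
                r2_max: float = R2_MAX, window_bp: int = WINDOW_BP,
                presso_alpha: float = PRESSO_ALPHA,
                presso_nsim: int = PRESSO_NSIM,
                clump_combine: str = "intersect",
                exceptions: Iterable[tuple] = (), seed=0) -> pd.DataFrame:
    """Run the full IV-selection cascade; returns the audit table.

    Clumping runs once per population LD panel; survivors are combined by
    ``clump_combine`` ("intersect" keeps SNPs surviving both panels,
    "union" either).  MR-PRESSO runs per population on the harmonized
    exposure-outcome pairs when supplied; a SNP removed in either
    population is dropped.
    """
    if clump_combine not in ("intersect", "union"):
        raise ValueError("clump_combine must be 'intersect' or 'union'")
    df = discovery_meta(cohort_a, cohort_b)
    df = consistency_filter(df, p_single=p_single)

    survivors = []
    clumped_states = []
    for pop, ld in ld_by_pop.items():
        c = clump(df, ld, r2_max=r2_max, p_max=p_meta, window_bp=window_bp)
        survivors.append(set(c.loc[c["state"] == "candidate", "snp"]))
        clumped_states.append(c)
    if survivors:
        combined = set.intersection(*survivors) if clump_combine == "intersect" \
            else set.union(*survivors)
        pre = df["state"] == "candidate"
        weak = pre & (df["p_meta"] >= p_meta)
        _mark(df, weak, "dropped_clump", f"p_meta >= {p_meta:g}")
        _mark(df, ~df["snp"].isin(combined), "dropped_clump",
              "linked to index SNP")

    df = pleiotropy_screen(df, other_traits, p_thresh=p_meta,
                           exceptions=exceptions)

    if pair_by_pop:
        rng = np.random.default_rng(seed)
        removed: set = set()
        live_ids = set(df.loc[df["state"] == "candidate", "snp"])
        for pop, pair in pair_by_pop.items():
            mask = np.array([s in live_ids for s in pair.snp_ids])
            sub = pair.subset(mask)
            if len(sub) >= 4:
                _, _, rem = presso_test(sub, n_sim=presso_nsim, seed=rng,
                                        alpha=presso_alpha)
                removed |= set(rem)
            else:
                log.info("MR-PRESSO skipped for %s: %d instruments", pop, len(sub))
        _mark(df, df["snp"].isin(removed), "dropped_presso",
              "pleiotropy outlier")
    _mark(df, pd.Series(True, index=df.index), "selected", "")
    return df


def cascade_counts(audit: pd.DataFrame) -> dict:
    """Filter bookkeeping: SNP counts per selection state."""
    counts = audit["state"].value_counts().to_dict()
    return {s: int(counts.get(s, 0)) for s in STATES}
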