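"""Multivariable MR: direct effects of several exposures fitted jointly.

Regresses outcome effects on a k-SNP x m-exposure matrix of exposure
effects (no intercept, inverse-variance weights), with Huber M-estimation
so single pleiotropic instruments cannot dominate.  Instrument strength
per exposure, given the others, is measured by the conditional F
statistic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .ivselect import LdMatrix, P_META
from .sumstats import or_from_logodds

HUBER_C = 1.345


class UnderIdentifiedError(ValueError):
    """Fewer usable instruments than exposures."""


@dataclasses.dataclass
class MvmrDesign:
    """Design matrix for a multivariable MR fit.

    ``bx``/``sx`` are k x m exposure effects and SEs aligned to a common
    effect allele per SNP, ``by``/``sey`` the outcome effects, and
    ``pheno_corr`` the m x m phenotypic correlation used by the
    conditional-F weighting.
    """

    exposures: list
    snp_ids: np.ndarray
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sey: np.ndarray
    pheno_corr: np.ndarray | None = None

    def __post_init__(self):
        self.bx = np.atleast_2d(np.asarray(self.bx, float))
        self.sx = np.atleast_2d(np.asarray(self.sx, float))
        self.by = np.asarray(self.by, float)
        self.sey = np.asarray(self.sey, float)
        k, m = self.bx.shape
        if m != len(self.exposures):
            raise ValueError("bx columns must match exposures")
        if self.bx.shape != self.sx.shape or len(self.by) != k or len(self.sey) != k:
            raise ValueError("inconsistent design dimensions")
        if k <= m:
            raise UnderIdentifiedError(
                f"{k} instruments for {m} exposures (need k > m)")
        if self.pheno_corr is None:
            self.pheno_corr = np.eye(m)
        self.pheno_corr = np.asarray(self.pheno_corr, float)
        if self.pheno_corr.shape != (m, m):
            raise ValueError("pheno_corr must be m x m")
        if not np.allclose(self.pheno_corr, self.pheno_corr.T, atol=1e-8):
            raise ValueError("pheno_corr must be symmetric")
        if not np.allclose(np.diag(self.pheno_corr), 1.0):
            raise ValueError("pheno_corr must have unit diagonal")

    @property
    def k(self) -> int:
        return self.bx.shape[0]

    @property
    def m(self) -> int:
        return self.bx.shape[1]


@dataclasses.dataclass
class MVMRResults:
    """Direct (conditional) causal effects per exposure."""

    exposures: list
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    conditional_f: np.ndarray
    n_iv: int

    def or_ci(self, level: float = 0.95) -> pd.DataFrame:
        rows = [or_from_logodds(b, s, level) for b, s in zip(self.beta, self.se)]
        return pd.DataFrame(rows, columns=["or", "ci_low", "ci_high"],
                            index=self.exposures)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "exposure": self.exposures, "beta": self.beta, "se": self.se,
            "p": self.pvalue, "conditional_f": self.conditional_f,
        })
        oc = self.or_ci().reset_index(drop=True)
        return pd.concat([df, oc], axis=1)

    def summary(self) -> str:
        lines = [f"Multivariable MR (robust), {self.n_iv} instruments, "
                 f"{len(self.exposures)} exposures"]
        for _, r in self.to_frame().iterrows():
            lines.append(
                f"  {r['exposure']:<12} beta {r['beta']: .4f} (SE {r['se']:.4f})"
                f"  OR {r['or']:.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f})"
                f"  P {r['p']:.3g}  cond.F {r['conditional_f']:.2f}")
        return "\n".join(lines)


def build_mvmr_ivs(candidate_sets: Mapping[str, pd.DataFrame],
                   ld: LdMatrix,
                   priority_trait: str | None = None,
                   excluded_trait_screen: Mapping[str, pd.DataFrame] | None = None,
                   r2_max: float = 0.01,
                   p_thresh: float = P_META) -> pd.DataFrame:
    """Assemble the instrument union for a multivariable fit.

    Takes each exposure's candidate table (post-clumping states), unions
    the SNPs, prunes to pairwise LD r² < ``r2_max`` greedily — within a
    correlated group an IV of ``priority_trait`` wins, then smaller
    discovery P, then genomic position — and removes IVs genome-wide
    significant for any trait in ``excluded_trait_screen`` (traits not
    included as exposures).  Returns the retained rows with a ``source``
    column naming the contributing exposure.
    """
    rows = []
    for trait, tab in candidate_sets.items():
        live = tab[tab["state"].isin(["candidate", "selected"])]
        for _, r in live.iterrows():
            rows.append({"snp": r["snp"], "chrom": r["chrom"], "pos": r["pos"],
                         "p_meta": r["p_meta"], "source": trait})
    if not rows:
        raise UnderIdentifiedError("no candidate instruments supplied")
    uni = pd.DataFrame(rows)
    # a SNP instrumenting several exposures keeps its best claim
    uni["is_priority"] = uni["source"] == priority_trait
    uni = (uni.sort_values(["is_priority", "p_meta"], ascending=[False, True])
              .drop_duplicates("snp", keep="first"))
    uni = uni.sort_values(["is_priority", "p_meta", "chrom", "pos", "snp"],
                          ascending=[False, True, True, True, True],
                          kind="mergesort").reset_index(drop=True)
    kept: list[int] = []
    for i in range(len(uni)):
        snp_i = uni.loc[i, "snp"]
        if any(ld.lookup(snp_i, uni.loc[j, "snp"]) >= r2_max for j in kept):
            continue
        kept.append(i)
    out = uni.loc[kept].reset_index(drop=True)

    if excluded_trait_screen:
        drop = pd.Series(False, index=out.index)
        for trait, tab in excluded_trait_screen.items():
            lut = tab.set_index("snp")["p_meta"]
            p_other = out["snp"].map(lut)
            drop |= p_other.notna() & (p_other < p_thresh)
        out = out.loc[~drop].reset_index(drop=True)
    return out.drop(columns="is_priority")


class MVMRRobust:
    """Robust multivariable MR model.

    Weighted (1/sey²) regression of outcome effects on the exposure-effect
    matrix without intercept, fitted by Huber M-estimation (tuning 1.345)
    with iteratively reweighted least squares; sandwich standard errors.
    """

    def __init__(self, design: MvmrDesign, maxiter: int = 200,
                 tol: float = 1e-8):
        self.design = design
        self.maxiter = maxiter
        self.tol = tol

    def fit(self) -> MVMRResults:
        d = self.design
        scale = 1.0 / d.sey
        y = d.by * scale
        X = d.bx * scale[:, None]

        # exact-fit guard: zero residual variance breaks the MAD scale
        beta_wls, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_wls
        ref = max(np.abs(y).max(), 1.0)
        if np.abs(resid).max() < 1e-10 * ref:
            XtX = X.T @ X
            cov = np.linalg.inv(XtX)
            se = np.sqrt(np.diag(cov))
            se = np.where(np.abs(resid).max() == 0.0, 0.0, se)
            p = 2.0 * sps.norm.sf(np.abs(beta_wls) / np.where(se > 0, se, np.inf))
            p = np.where(se > 0, p, np.where(beta_wls == 0, 1.0, 0.0))
            cf = np.array([conditional_f(d, i) for i in range(d.m)])
            return MVMRResults(list(d.exposures), beta_wls, se, p, cf, d.k)

        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_C))
        res = rlm.fit(maxiter=self.maxiter, tol=self.tol, cov="H1")
        beta = np.asarray(res.params)
        se = np.asarray(res.bse)
        p = 2.0 * sps.norm.sf(np.abs(beta) / se)
        cf = np.array([conditional_f(d, i) for i in range(d.m)])
        return MVMRResults(list(d.exposures), beta, se, p, cf, d.k)


def mvmr_robust(design: MvmrDesign, **kw) -> MVMRResults:
    """Functional wrapper around :class:`MVMRRobust`."""
    return MVMRRobust(design, **kw).fit()


def conditional_f(design: MvmrDesign, exposure_index: int,
                  n_iter: int = 30, tol: float = 1e-10) -> float:
    """Conditional instrument-strength F for one exposure given the rest.

    Regresses exposure-i effects on the other exposures' effects with
    weights from the SE- and phenotypic-correlation-implied covariance of
    the residual, iterating weights to convergence; the weighted residual
    sum of squares Q is scaled by (k - m + 1).  With a single exposure
    this reduces to the mean per-IV F (mean z²).
    """
    d = design
    i = exposure_index
    k, m = d.k, d.m
    if k <= m:
        raise UnderIdentifiedError("k must exceed m")
    xi = d.bx[:, i]
    si = d.sx[:, i]
    if m == 1:
        q = float(np.sum((xi / si) ** 2))
        return q / (k - m + 1)

    others = [j for j in range(m) if j != i]
    Xo = d.bx[:, others]
    So = d.sx[:, others]
    rho_io = d.pheno_corr[i, others]
    rho_oo = d.pheno_corr[np.ix_(others, others)]

    delta, *_ = np.linalg.lstsq(Xo, xi, rcond=None)
    w = np.ones(k)
    for _ in range(n_iter):
        # var(xi_j - delta' xo_j) from the estimate covariance implied by
        # the SEs and phenotypic correlations
        cross = (So * rho_io[None, :]) @ delta * si
        quad = np.einsum("jl,l,jm,m,lm->j", So, delta, So, delta, rho_oo)
        v = si**2 - 2.0 * cross + quad
        v = np.clip(v, 1e-12 * np.max(si**2), None)
        w_new = 1.0 / v
        W = np.sqrt(w_new)
        delta_new, *_ = np.linalg.lstsq(Xo * W[:, None], xi * W, rcond=None)
        if (np.max(np.abs(delta_new - delta)) < tol
                and np.max(np.abs(w_new - w)) < tol * np.max(w_new)):
            delta, w = delta_new, w_new
            break
        delta, w = delta_new, w_new
    resid = xi - Xo @ delta
    q = float(np.sum(w * resid**2))
    return q / (k - m + 1)
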