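"""Univariable two-sample MR estimators and diagnostics.

Estimators follow the model/results idiom: construct a model from a
:class:`~transmr.sumstats.HarmonizedPair`, call :meth:`fit`, and read the
causal estimate, its uncertainty and per-IV heterogeneity off the returned
:class:`MRResults`.

Two estimators are provided:

* :class:`IVW` — inverse-variance-weighted regression of outcome on
  exposure effects through the origin, with a multiplicative
  random-effects SE inflation to absorb balanced pleiotropy;
* :class:`RAPS` — robust adjusted profile score, an estimating-equation
  method that accounts for measurement error in the exposure effects and,
  optionally, overdispersed pleiotropy, with an l2 or Huber influence
  function.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize, stats as sps

from .ivselect import compute_pve, instrument_strength
from .sumstats import HarmonizedPair, or_from_logodds

HUBER_C = 1.345  # 95% Gaussian efficiency


class DegenerateInstrumentError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    """RAPS found no sign-consistent root; carries the searched bracket."""

    def __init__(self, bracket):
        self.bracket = bracket
        super().__init__(f"no root of the profile score in {bracket}")


@dataclasses.dataclass
class MRResults:
    """Causal-effect estimate from a univariable MR fit.

    ``beta`` is on the outcome scale per SD of exposure (log-odds per SD
    for a binary outcome).  ``q_stat``/``q_p`` are per-IV Cochran
    heterogeneity at ``n_iv - 1`` degrees of freedom (NaN for one IV).
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_iv: int
    q_stat: float = math.nan
    q_p: float = math.nan
    mean_f: float = math.nan
    extra: dict = dataclasses.field(default_factory=dict)

    def or_ci(self, level: float = 0.95) -> tuple[float, float, float]:
        """Odds ratio and CI, for binary outcomes."""
        return or_from_logodds(self.beta, self.se, level)

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        z = sps.norm.ppf(0.5 + level / 2.0)
        return self.beta - z * self.se, self.beta + z * self.se

    def summary(self) -> str:
        o, lo, hi = self.or_ci()
        lines = [
            f"Univariable MR ({self.method}), {self.n_iv} instruments",
            f"  beta     {self.beta: .5f}  (SE {self.se:.5f})",
            f"  OR       {o:.3f}  (95% CI {lo:.3f}, {hi:.3f})",
            f"  P        {self.pvalue:.3g}",
        ]
        if not math.isnan(self.q_stat):
            lines.append(f"  Cochran Q {self.q_stat:.3f} "
                         f"(df {self.n_iv - 1}, P {self.q_p:.3g})")
        if not math.isnan(self.mean_f):
            lines.append(f"  mean F   {self.mean_f:.2f}")
        return "\n".join(lines)


def wald_ratio(bx: float, sex: float, by: float, sey: float) -> MRResults:
    """Single-instrument causal estimate by/bx with first-order SE sey/|bx|."""
    if bx == 0:
        raise DegenerateInstrumentError("exposure effect is zero")
    beta = by / bx
    se = sey / abs(bx)
    p = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta else 1.0)
    return MRResults("wald", float(beta), float(se), float(p), n_iv=1)


class IVW:
    """Inverse-variance-weighted MR with multiplicative random effects.

    Weighted least squares of by on bx through the origin with weights
    1/sey²; the fixed-effect SE is inflated by max(1, sqrt(Q/(k-1))) so
    that over-dispersion beyond sampling noise widens the interval without
    moving the point estimate.
    """

    def __init__(self, pair: HarmonizedPair, random_effects: bool = True):
        self.pair = pair
        self.random_effects = random_effects

    def fit(self) -> MRResults:
        p = self.pair
        k = len(p)
        if k == 0:
            raise DegenerateInstrumentError("no instruments")
        if k == 1:
            res = wald_ratio(p.bx[0], p.sex[0], p.by[0], p.sey[0])
            return dataclasses.replace(res, method="ivw_mre", extra={"fallback": "wald"})
        w = 1.0 / p.sey**2
        sxx = float(np.sum(w * p.bx**2))
        beta = float(np.sum(w * p.bx * p.by) / sxx)
        se_fe = sxx**-0.5
        q = float(np.sum(w * (p.by - beta * p.bx) ** 2))
        q_p = float(sps.chi2.sf(q, df=k - 1))
        infl = max(1.0, math.sqrt(q / (k - 1))) if self.random_effects else 1.0
        se = se_fe * infl
        pval = float(2.0 * sps.norm.sf(abs(beta) / se))
        mean_f = float(np.mean((p.bx / p.sex) ** 2))
        return MRResults("ivw_mre" if self.random_effects else "ivw_fe",
                         beta, se, pval, n_iv=k, q_stat=q, q_p=q_p,
                         mean_f=mean_f, extra={"se_fixed": se_fe})


def ivw_mre(pair: HarmonizedPair) -> MRResults:
    """Functional wrapper around :class:`IVW` with random effects."""
    return IVW(pair, random_effects=True).fit()


# ---------------------------------------------------------------------------
# RAPS

def _psi(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "l2":
        return t
    return np.clip(t, -HUBER_C, HUBER_C)


def _psi_prime(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "l2":
        return np.ones_like(t)
    return (np.abs(t) <= HUBER_C).astype(float)


def _delta(loss: str) -> float:
    # E[psi(Z) Z] for standard normal Z
    if loss == "l2":
        return 1.0
    return 2.0 * sps.norm.cdf(HUBER_C) - 1.0


class RAPS:
    """Robust adjusted profile score MR estimator.

    Solves the estimating equation sum_j psi(t_j(beta)) * bx_j / s_j = 0
    with standardised residual t_j = (by_j - beta*bx_j)/s_j and
    s_j² = sey_j² + beta²·sex_j² + tau²; the overdispersion tau² (if
    enabled) is profiled so the mean of psi(t)·t matches its standard
    normal expectation.  Robustness comes from the Huber influence
    function (tuning 1.345); ``loss="l2"`` gives the plain profile score.
    The root is located by scanning a bounded bracket with multiple starts
    and refined by Brent's method; the SE is the sandwich of the
    estimating equation.
    """

    def __init__(self, pair: HarmonizedPair, overdispersion: bool = True,
                 loss: str = "huber", bracket: tuple = (-10.0, 10.0),
                 n_starts: int = 20):
        if loss not in ("l2", "huber"):
            raise ValueError("loss must be 'l2' or 'huber'")
        if len(pair) < 3:
            raise DegenerateInstrumentError("RAPS needs >= 3 instruments")
        self.pair = pair
        self.overdispersion = overdispersion
        self.loss = loss
        self.bracket = bracket
        self.n_starts = n_starts

    # -- internals ---------------------------------------------------------

    def _tau2(self, beta: float) -> float:
        """Profile tau² >= 0 so mean(psi(t) t) hits its null expectation."""
        if not self.overdispersion:
            return 0.0
        p = self.pair
        target = _delta(self.loss)

        def excess(tau2):
            s = np.sqrt(p.sey**2 + beta**2 * p.sex**2 + tau2)
            t = (p.by - beta * p.bx) / s
            return float(np.mean(_psi(t, self.loss) * t)) - target

        if excess(0.0) <= 0.0:
            return 0.0
        hi = float(np.max(p.sey**2))
        while excess(hi) > 0.0 and hi < 1e6:
            hi *= 4.0
        return float(optimize.brentq(excess, 0.0, hi, xtol=1e-12))

    def _score(self, beta: float) -> float:
        p = self.pair
        tau2 = self._tau2(beta)
        s = np.sqrt(p.sey**2 + beta**2 * p.sex**2 + tau2)
        t = (p.by - beta * p.bx) / s
        return float(np.sum(_psi(t, self.loss) * p.bx / s))

    # -- fitting -----------------------------------------------------------

    def fit(self) -> MRResults:
        lo, hi = self.bracket
        grid = np.linspace(lo, hi, self.n_starts + 1)
        vals = np.array([self._score(b) for b in grid])
        roots = []
        for i in range(len(grid) - 1):
            a, b = vals[i], vals[i + 1]
            if a == 0.0:
                roots.append(float(grid[i]))
            elif a * b < 0:
                roots.append(float(optimize.brentq(self._score, grid[i],
                                                   grid[i + 1], xtol=1e-12)))
        if vals[-1] == 0.0:
            roots.append(float(grid[-1]))
        if not roots:
            raise NonConvergenceError(self.bracket)
        # prefer the root nearest the IVW estimate (score may have
        # spurious sign changes at extreme beta where weights collapse)
        ref = ivw_mre(self.pair).beta
        beta = min(roots, key=lambda r: abs(r - ref))

        p = self.pair
        tau2 = self._tau2(beta)
        s = np.sqrt(p.sey**2 + beta**2 * p.sex**2 + tau2)
        t = (p.by - beta * p.bx) / s
        u = p.bx / s
        bread = np.sum(_psi_prime(t, self.loss) * u**2)  # ~ -dS/dbeta
        meat = np.sum(_psi(t, self.loss) ** 2 * u**2)
        se = float(np.sqrt(meat) / bread) if bread > 0 else math.inf
        pval = float(2.0 * sps.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        k = len(p)
        q = float(np.sum(((p.by - beta * p.bx) ** 2)
                         / (p.sey**2 + beta**2 * p.sex**2)))
        q_p = float(sps.chi2.sf(q, df=k - 1))
        mean_f = float(np.mean((p.bx / p.sex) ** 2))
        return MRResults("raps", float(beta), se, pval, n_iv=k,
                         q_stat=q, q_p=q_p, mean_f=mean_f,
                         extra={"tau2": tau2, "loss": self.loss,
                                "overdispersion": self.overdispersion})


def raps(pair: HarmonizedPair, overdispersion: bool = True,
         loss: str = "huber") -> MRResults:
    """Functional wrapper around :class:`RAPS`."""
    return RAPS(pair, overdispersion=overdispersion, loss=loss).fit()


# ---------------------------------------------------------------------------
# directionality and funnel diagnostics

@dataclasses.dataclass(frozen=True)
class SteigerResult:
    pve_exposure_sum: float
    pve_outcome_sum: float
    direction: str  # exposure_to_outcome | outcome_to_exposure | indeterminate
    pvalue: float


def steiger(pair: HarmonizedPair, n_exposure: float | None = None,
            n_outcome: float | None = None,
            p_threshold: float = 0.05) -> SteigerResult:
    """Directionality test comparing instrument-explained correlation in
    exposure vs outcome.

    Summed per-IV PVE on each side is converted to a correlation (sqrt)
    and the two correlations compared by the z-test on Fisher transforms.
    A binary outcome uses the same z-score PVE approximation on the
    log-odds effects.
    """
    if len(pair) < 1:
        raise DegenerateInstrumentError("no instruments")
    nx = n_exposure if n_exposure is not None else pair.n_exposure
    ny = n_outcome if n_outcome is not None else pair.n_outcome
    if nx is None or ny is None or nx <= 3 or ny <= 3:
        raise ValueError("sample sizes > 3 required on both sides")
    pve_x = float(np.sum(compute_pve(pair.bx, pair.sex, nx)))
    pve_y = float(np.sum(compute_pve(pair.by, pair.sey, ny)))
    r_x = math.sqrt(min(pve_x, 1.0 - 1e-12))
    r_y = math.sqrt(min(pve_y, 1.0 - 1e-12))
    z = (math.atanh(r_x) - math.atanh(r_y)) / math.sqrt(
        1.0 / (nx - 3.0) + 1.0 / (ny - 3.0))
    p = float(2.0 * sps.norm.sf(abs(z)))
    if p < p_threshold:
        direction = ("exposure_to_outcome" if pve_x > pve_y
                     else "outcome_to_exposure")
    else:
        direction = "indeterminate"
    if pve_x == pve_y:
        direction, p = "indeterminate", 1.0
    return SteigerResult(pve_x, pve_y, direction, p)


def funnel_table(pair: HarmonizedPair, beta_hat: float):
    """Plot-ready per-IV Wald ratios and precisions about a fitted slope.

    Asymmetric scatter about ``beta_hat`` suggests directional pleiotropy.
    """
    import pandas as pd

    ratio = pair.by / pair.bx
    precision = np.abs(pair.bx) / pair.sey  # 1/SE of the Wald ratio
    return pd.DataFrame({
        "snp": pair.snp_ids,
        "wald_ratio": ratio,
        "precision": precision,
        "reference": beta_hat,
    })


def bidirectional_mr(*args, **kwargs):
    """Forward and reverse MR between two traits; see
    :func:`transmr.pipeline.bidirectional_mr` (re-exported here for
    discoverability)."""
    from .pipeline import bidirectional_mr as _impl
    return _impl(*args, **kwargs)
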