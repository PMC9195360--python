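"""Fixed-effect inverse-variance meta-analysis and Cochran's Q heterogeneity.

Used in two places in the trans-ancestry MR design: combining per-SNP
effects across discovery cohorts, and combining population-specific MR
estimates, with Cochran's Q testing whether the populations disagree.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: exact standard-normal quantile at 95% two-sided, used for CI conversion
Z_95 = float(sps.norm.ppf(0.975))

#: populations flagged as heterogeneous when p_het falls below this
HET_FLAG_P = 0.01


@dataclasses.dataclass(frozen=True)
class EffectEstimate:
    """One effect estimate on a common scale, with its SE and a source tag."""

    beta: float
    se: float
    label: str = ""

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be > 0")


@dataclasses.dataclass(frozen=True)
class MetaEstimate:
    """Inverse-variance fixed-effect combination with heterogeneity stats.

    ``q_stat``/``p_het`` are Cochran's Q and its chi-square P at ``q_df``
    degrees of freedom; both are NaN for a single input.
    """

    beta_meta: float
    se_meta: float
    pvalue: float
    q_stat: float
    q_df: int
    p_het: float
    k: int


def fe_meta(estimates: Sequence[EffectEstimate] | Iterable) -> MetaEstimate:
    """Fixed-effect inverse-variance meta-analysis.

    Weights are 1/se^2; the combined P is two-sided normal.  Cochran's Q is
    the weighted sum of squared deviations about the pooled estimate,
    referred to chi-square with k-1 degrees of freedom.
    """
    est = list(estimates)
    if not est:
        raise ValueError("fe_meta requires at least one estimate")
    b = np.array([e.beta for e in est], dtype=float)
    se = np.array([e.se for e in est], dtype=float)
    w = 1.0 / se**2
    sw = w.sum()
    beta = float((w * b).sum() / sw)
    se_meta = float(sw**-0.5)
    p = float(2.0 * sps.norm.sf(abs(beta) / se_meta))
    k = len(est)
    if k >= 2:
        q = float((w * (b - beta) ** 2).sum())
        p_het = float(sps.chi2.sf(q, df=k - 1))
    else:
        q, p_het = math.nan, math.nan
    return MetaEstimate(beta, se_meta, p, q, k - 1, p_het, k)


def cochran_q_two(est1: EffectEstimate, est2: EffectEstimate
                  ) -> tuple[float, float]:
    """Two-group Cochran's Q: (b1-b2)^2/(se1^2+se2^2), chi-square at df 1.

    Algebraically identical to the Q of :func:`fe_meta` on the two inputs.
    """
    q = (est1.beta - est2.beta) ** 2 / (est1.se**2 + est2.se**2)
    return float(q), float(sps.chi2.sf(q, df=1))


def se_from_ci(or_point: float, ci_low: float, ci_high: float,
               level: float = 0.95) -> tuple[float, float]:
    """Recover (log-OR, SE) from a printed odds ratio and confidence interval.

    Lets published per-population tables be re-used as meta-analysis inputs.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValueError("require 0 < ci_low <= or_point <= ci_high")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    beta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return beta, se


def meta_table(rows: pd.DataFrame, group_cols: Sequence[str],
               beta_col: str = "beta", se_col: str = "se") -> pd.DataFrame:
    """Meta-analyse a long table of estimates within groups.

    Returns one row per group with beta_meta, se_meta, p, q, df, p_het and
    the heterogeneity flag at ``p_het < 0.01``.
    """
    out = []
    for key, grp in rows.groupby(list(group_cols)):
        ests = [EffectEstimate(b, s) for b, s in zip(grp[beta_col], grp[se_col])]
        m = fe_meta(ests)
        rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        rec.update(beta_meta=m.beta_meta, se_meta=m.se_meta, p=m.pvalue,
                   q=m.q_stat, df=m.q_df, p_het=m.p_het,
                   het_flag=bool(m.p_het < HET_FLAG_P) if m.k > 1 else False)
        out.append(rec)
    return pd.DataFrame(out)
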