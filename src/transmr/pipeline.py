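"""End-to-end study orchestration: cascade, estimation, meta-analysis.

``run_study`` executes the full design for every configured
exposure-outcome pair: per-SNP trans-cohort discovery meta-analysis, the
IV-selection cascade, per-population UVMR estimation, cross-population
fixed-effect meta-analysis with a heterogeneity flag, and instrument
diagnostics (mean F, Steiger directionality, sample-overlap bias).
Stage failures are recorded per pair and the run continues.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ivselect, meta, uvmr
from .meta import EffectEstimate, cochran_q_two, fe_meta, HET_FLAG_P
from .sumstats import (HarmonizedPair, SummaryStats, harmonize,
                       or_from_logodds, rescale_effects)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class StudyConfig:
    """Thresholds and layout of one study run.

    ``bonferroni_m`` gives the number of tests for each direction; the
    significance threshold is 0.05/m (0.05/37 forward and 0.05/4 reverse
    in a 37-exposure design with 4 reverse outcomes).
    """

    exposures: Sequence[str]
    outcome: str
    populations: Sequence[str] = ("EAS", "EUR")
    direction: str = "forward"  # forward | reverse | both
    estimators: Sequence[str] = ("ivw", "raps")
    p_single: float = ivselect.P_SINGLE
    p_meta: float = ivselect.P_META
    r2_max: float = ivselect.R2_MAX
    window_bp: int = ivselect.WINDOW_BP
    presso_alpha: float = ivselect.PRESSO_ALPHA
    presso_nsim: int = ivselect.PRESSO_NSIM
    bonferroni_m_forward: int = 37
    bonferroni_m_reverse: int = 4
    het_flag_p: float = HET_FLAG_P
    clump_combine: str = "intersect"
    overlap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError("direction must be forward | reverse | both")
        for name, v in (("p_single", self.p_single), ("p_meta", self.p_meta),
                        ("presso_alpha", self.presso_alpha)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} out of range")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max out of range")

    @property
    def alpha_forward(self) -> float:
        return 0.05 / self.bonferroni_m_forward

    @property
    def alpha_reverse(self) -> float:
        return 0.05 / self.bonferroni_m_reverse


@dataclasses.dataclass
class StudyReport:
    """Results and audit trail of one study run."""

    results: pd.DataFrame          # per pair x population x method + meta rows
    audit: dict                    # (exposure, direction) -> cascade counts
    diagnostics: pd.DataFrame
    skipped: dict                  # (exposure, direction) -> reason
    config: StudyConfig


def _fit_estimators(pair: HarmonizedPair, estimators: Sequence[str]):
    out = {}
    for est in estimators:
        if est == "ivw":
            out[est] = uvmr.IVW(pair).fit()
        elif est == "raps":
            out[est] = uvmr.RAPS(pair).fit()
        else:
            raise ValueError(f"unknown estimator {est!r}")
    return out


def _one_direction(exposure: str, outcome: str, direction: str,
                   stats: Mapping, ld: Mapping, cfg: StudyConfig,
                   other_traits: Mapping[str, pd.DataFrame],
                   exceptions=()) -> tuple:
    """Cascade + estimation + meta for one exposure->outcome pair."""
    pop_a, pop_b = cfg.populations
    exp_a, exp_b = stats[(exposure, pop_a)], stats[(exposure, pop_b)]
    out_by_pop = {p: stats[(outcome, p)] for p in cfg.populations}

    pairs_full = {p: harmonize(stats[(exposure, p)], out_by_pop[p])
                  for p in cfg.populations}
    audit = ivselect.run_cascade(
        exp_a, exp_b, ld_by_pop=ld, other_traits=other_traits,
        pair_by_pop=pairs_full, p_single=cfg.p_single, p_meta=cfg.p_meta,
        r2_max=cfg.r2_max, window_bp=cfg.window_bp,
        presso_alpha=cfg.presso_alpha, presso_nsim=cfg.presso_nsim,
        clump_combine=cfg.clump_combine, exceptions=exceptions,
        seed=cfg.seed)
    selected = set(audit.loc[audit["state"] == "selected", "snp"])
    if not selected:
        raise ivselect.InsufficientInstrumentsError(
            "no instruments survive the cascade")

    alpha = cfg.alpha_forward if direction == "forward" else cfg.alpha_reverse
    rows, diag_rows = [], []
    per_pop: dict = {}
    for pop in cfg.populations:
        pair = pairs_full[pop].subset(
            np.array([s in selected for s in pairs_full[pop].snp_ids]))
        if len(pair) == 0:
            raise ivselect.InsufficientInstrumentsError(
                f"no instruments in population {pop}")
        fits = _fit_estimators(pair, cfg.estimators)
        per_pop[pop] = fits
        strength = ivselect.instrument_strength(
            pair.bx, pair.sex, pair.n_exposure or np.inf)
        try:
            st = uvmr.steiger(pair)
            steiger_dir, steiger_p = st.direction, st.pvalue
        except (ValueError, uvmr.DegenerateInstrumentError):
            steiger_dir, steiger_p = "unavailable", np.nan
        primary = fits[cfg.estimators[0]]
        bias = ivselect.overlap_bias(primary.beta, cfg.overlap_rate,
                                     strength.mean_f).bias \
            if strength.mean_f > 0 else np.nan
        diag_rows.append({
            "exposure": exposure, "outcome": outcome, "direction": direction,
            "population": pop, "n_iv": len(pair),
            "mean_f": strength.mean_f, "steiger_direction": steiger_dir,
            "steiger_p": steiger_p, "overlap_bias": bias,
        })
        for est, res in fits.items():
            o, lo, hi = res.or_ci()
            rows.append({
                "exposure": exposure, "outcome": outcome,
                "direction": direction, "population": pop, "method": est,
                "beta": res.beta, "se": res.se, "p": res.pvalue,
                "or": o, "ci_low": lo, "ci_high": hi, "n_iv": res.n_iv,
                "mean_f": res.mean_f, "q": res.q_stat, "q_p": res.q_p,
                "significant": res.pvalue < alpha, "p_het": np.nan,
                "het_flag": False,
            })
    for est in cfg.estimators:
        ests = [EffectEstimate(per_pop[p][est].beta, per_pop[p][est].se, p)
                for p in cfg.populations]
        m = fe_meta(ests)
        o, lo, hi = or_from_logodds(m.beta_meta, m.se_meta)
        rows.append({
            "exposure": exposure, "outcome": outcome, "direction": direction,
            "population": "meta", "method": est,
            "beta": m.beta_meta, "se": m.se_meta, "p": m.pvalue,
            "or": o, "ci_low": lo, "ci_high": hi,
            "n_iv": int(np.mean([per_pop[p][est].n_iv for p in cfg.populations])),
            "mean_f": np.nan, "q": m.q_stat, "q_p": np.nan,
            "significant": m.pvalue < alpha, "p_het": m.p_het,
            "het_flag": bool(m.p_het < cfg.het_flag_p),
        })
    return rows, ivselect.cascade_counts(audit), diag_rows, audit


def run_study(config: StudyConfig, stats: Mapping, ld: Mapping,
              other_traits_by_exposure: Mapping[str, Mapping] | None = None,
              exceptions=()) -> StudyReport:
    """Execute the configured study.

    ``stats`` maps (trait, population) -> :class:`SummaryStats`; ``ld``
    maps population -> :class:`LdMatrix`.  For each exposure the
    cross-trait pleiotropy screen uses the discovery tables of all other
    exposures unless ``other_traits_by_exposure`` overrides them.
    """
    cfg = config
    directions = {"forward": ["forward"], "reverse": ["reverse"],
                  "both": ["forward", "reverse"]}[cfg.direction]

    # discovery tables of every exposure, for the pleiotropy screen
    discovery: dict = {}
    pop_a, pop_b = cfg.populations
    for t in cfg.exposures:
        try:
            discovery[t] = ivselect.discovery_meta(stats[(t, pop_a)],
                                                   stats[(t, pop_b)])
        except (KeyError, ValueError) as e:
            log.warning("discovery meta failed for %s: %s", t, e)

    rows, diags, audits, skipped = [], [], {}, {}
    for direction in directions:
        for exposure in cfg.exposures:
            if direction == "forward":
                src, dst = exposure, cfg.outcome
            else:
                src, dst = cfg.outcome, exposure
            if other_traits_by_exposure and exposure in other_traits_by_exposure:
                others = other_traits_by_exposure[exposure]
            else:
                others = {t: tab for t, tab in discovery.items()
                          if t != exposure}
                if direction == "reverse":
                    others = {}  # reverse IVs come from the outcome trait
            try:
                r, counts, d, audit = _one_direction(
                    src, dst, direction, stats, ld, cfg, others, exceptions)
                rows.extend(r)
                diags.extend(d)
                audits[(exposure, direction)] = counts
                audits[(exposure, direction, "table")] = audit
            except Exception as e:  # noqa: BLE001 — stage errors recorded, run continues
                log.warning("pair %s->%s (%s) skipped: %s", src, dst,
                            direction, e)
                skipped[(exposure, direction)] = str(e)

    results = pd.DataFrame(rows)
    diagnostics = pd.DataFrame(diags)
    return StudyReport(results=results, audit=audits,
                       diagnostics=diagnostics, skipped=skipped, config=cfg)


def bidirectional_mr(trait_a: str, trait_b: str, stats: Mapping, ld: Mapping,
                     config: StudyConfig | None = None) -> StudyReport:
    """Forward (trait_a -> trait_b) and reverse MR with the same cascade,
    at direction-specific Bonferroni thresholds."""
    cfg = config or StudyConfig(exposures=[trait_a], outcome=trait_b,
                                direction="both")
    cfg = dataclasses.replace(cfg, exposures=[trait_a], outcome=trait_b,
                              direction="both")
    return run_study(cfg, stats, ld)


def render_report(report: StudyReport, out_dir) -> dict:
    """Write the report as TSV tables plus a text summary; returns paths."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    res_path = out / "results.tsv"
    report.results.to_csv(res_path, sep="\t", index=False, float_format="%.10g")
    paths["results"] = res_path

    diag_path = out / "diagnostics.tsv"
    report.diagnostics.to_csv(diag_path, sep="\t", index=False,
                              float_format="%.10g")
    paths["diagnostics"] = diag_path

    audit_rows = []
    for key, val in report.audit.items():
        if len(key) == 2:
            exposure, direction = key
            rec = {"exposure": exposure, "direction": direction}
            rec.update(val)
            audit_rows.append(rec)
    audit_path = out / "cascade_counts.tsv"
    pd.DataFrame(audit_rows).to_csv(audit_path, sep="\t", index=False)
    paths["audit"] = audit_path

    lines = ["transmr study summary", "=" * 40]
    for rec in audit_rows:
        total = sum(v for k, v in rec.items()
                    if k not in ("exposure", "direction"))
        lines.append(f"{rec['exposure']} ({rec['direction']}): "
                     f"{rec.get('selected', 0)} IVs selected of {total}")
    for key, reason in report.skipped.items():
        lines.append(f"skipped {key}: {reason}")
    if not report.results.empty:
        sig = report.results.query("population == 'meta' and significant")
        lines.append(f"significant meta-analysed pairs: {len(sig)}")
    summary_path = out / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    paths["summary"] = summary_path
    return paths
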