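"""GWAS summary-statistics containers, I/O, harmonization and scale conversions.

A :class:`SummaryStats` holds one trait in one population as a validated
pandas DataFrame with canonical columns ``snp, chrom, pos, ea, oa, eaf,
beta, se, p, n``.  Effects of quantitative traits are in SD units of the
trait; effects of binary traits are on the natural-log odds scale.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
CANON_COLS = ["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

#: default header mapping (input name -> canonical name)
DEFAULT_DIALECT = {
    "snp": "snp", "chr": "chrom", "pos": "pos", "ea": "ea", "oa": "oa",
    "eaf": "eaf", "beta": "beta", "se": "se", "p": "p", "n": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsFormatError(ValueError):
    """Malformed summary-statistics input (missing columns, empty file)."""


class HarmonizationError(ValueError):
    """No SNPs survive harmonization."""


@dataclasses.dataclass(frozen=True)
class TraitMeta:
    """Metadata for one trait in one population.

    ``sd_native`` is the trait SD in measurement units (quantitative traits
    only) used to put per-allele effects from different cohorts on a common
    SD scale.  Binary traits carry case/control counts instead.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    population: str = ""
    sd_native: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "quantitative":
            if self.sd_native is not None and self.sd_native <= 0:
                raise ValueError("sd_native must be > 0")
        else:
            for v in (self.n_cases, self.n_controls):
                if v is not None and v <= 0:
                    raise ValueError("case/control counts must be > 0")


@dataclasses.dataclass
class SummaryStats:
    """Per-SNP association records for one trait in one population."""

    meta: TraitMeta
    table: pd.DataFrame
    n_dropped: int = 0  # rows removed by validation

    def __post_init__(self):
        if self.table["snp"].duplicated().any():
            dup = self.table["snp"][self.table["snp"].duplicated()].iloc[0]
            raise ValueError(f"duplicate snp id {dup!r}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.table["snp"])

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("snp")


@dataclasses.dataclass
class HarmonizedPair:
    """Exposure/outcome effects aligned to a common effect allele per SNP.

    The standard two-sample MR data layout: parallel arrays of exposure
    effects ``bx``/``sex`` and outcome effects ``by``/``sey``.
    """

    snp_ids: np.ndarray
    bx: np.ndarray
    sex: np.ndarray
    by: np.ndarray
    sey: np.ndarray
    n_exposure: float | None = None
    n_outcome: float | None = None

    def __post_init__(self):
        k = len(self.snp_ids)
        for name in ("bx", "sex", "by", "sey"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if len(v) != k:
                raise ValueError("all HarmonizedPair vectors must share length")
        if np.any(self.sex <= 0) or np.any(self.sey <= 0):
            raise ValueError("standard errors must be > 0")
        object.__setattr__(self, "snp_ids", np.asarray(self.snp_ids))

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask) -> "HarmonizedPair":
        mask = np.asarray(mask)
        return HarmonizedPair(
            self.snp_ids[mask], self.bx[mask], self.sex[mask],
            self.by[mask], self.sey[mask], self.n_exposure, self.n_outcome,
        )


# ---------------------------------------------------------------------------
# validation / IO

def _validate(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the record invariants; return (clean, n_dropped)."""
    n0 = len(df)
    df = df.copy()
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    for c in ("pos", "eaf", "beta", "se", "p", "n"):
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = (
        df["se"].gt(0)
        & df["beta"].notna()
        & df["ea"].ne(df["oa"])
        & df["n"].gt(0)
    )
    if "eaf" in df and df["eaf"].notna().any():
        ok &= df["eaf"].isna() | df["eaf"].between(0.0, 1.0)
    # recompute missing p from z; flag gross inconsistencies but keep the row
    z = df["beta"] / df["se"]
    p_z = 2.0 * sps.norm.sf(np.abs(z))
    missing_p = df["p"].isna() | df["p"].le(0) | df["p"].gt(1)
    df.loc[missing_p, "p"] = p_z[missing_p]
    with np.errstate(divide="ignore"):
        ratio = df["p"] / np.clip(p_z, 1e-300, None)
    bad = (~missing_p) & ((ratio > 10) | (ratio < 0.1)) & (df["p"] > 1e-280)
    if bad.any():
        log.warning("%d rows: reported P disagrees with beta/se by >10x", bad.sum())
    dropped = int(n0 - ok.sum())
    return df.loc[ok].reset_index(drop=True), dropped


def read_sumstats(path, meta: TraitMeta,
                  dialect: Mapping[str, str] | None = None,
                  sep: str = "\t") -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    ``dialect`` maps file column names to the canonical names in
    :data:`DEFAULT_DIALECT`; rows failing validation (se <= 0, equal
    alleles, eaf outside [0,1], n <= 0) are dropped and counted in
    ``n_dropped``.  Gzip-compressed files are handled transparently by
    pandas.
    """
    dialect = dict(dialect or DEFAULT_DIALECT)
    try:
        raw = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as e:
        raise SumstatsFormatError(f"{path}: empty file") from e
    if raw.empty:
        raise SumstatsFormatError(f"{path}: no data rows")
    rename = {src: dst for src, dst in dialect.items() if src in raw.columns}
    df = raw.rename(columns=rename)
    required = ["snp", "chrom", "pos", "ea", "oa", "beta", "se"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing columns {missing}")
    for c in CANON_COLS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[CANON_COLS]
    df["snp"] = df["snp"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    clean, dropped = _validate(df)
    if dropped:
        log.info("%s: dropped %d invalid rows", path, dropped)
    return SummaryStats(meta=meta, table=clean, n_dropped=dropped)


def write_sumstats(stats: SummaryStats, path, sep: str = "\t") -> None:
    stats.table.to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization

def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindromic_policy: str = "drop",
              eaf_threshold: float = 0.42) -> HarmonizedPair:
    """Align outcome records to the exposure's effect alleles.

    Where the outcome's effect allele equals the exposure's other allele
    (directly or via strand complement), the outcome beta sign is flipped.
    Irreconcilable allele pairs are excluded.  A/T and C/G (palindromic)
    SNPs are dropped under policy ``"drop"``; under ``"keep_with_eaf"``
    they are kept when both cohorts report an allele frequency clearly away
    from 0.5 (min(eaf, 1-eaf) < ``eaf_threshold``), aligning by frequency.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise HarmonizationError("empty input")
    if palindromic_policy not in ("drop", "keep_with_eaf"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")

    ex = exposure.indexed()
    ou = outcome.indexed()
    common = ex.index.intersection(ou.index)
    if len(common) == 0:
        raise HarmonizationError("no shared SNPs between exposure and outcome")
    ex = ex.loc[common]
    ou = ou.loc[common]

    pal = _is_palindromic(ex["ea"], ex["oa"])
    same = (ou["ea"] == ex["ea"]) & (ou["oa"] == ex["oa"])
    flipped = (ou["ea"] == ex["oa"]) & (ou["oa"] == ex["ea"])
    # strand flip: compare on the complementary strand (non-palindromic only)
    ou_ea_c = ou["ea"].map(_COMPLEMENT)
    ou_oa_c = ou["oa"].map(_COMPLEMENT)
    same_c = (~pal) & (ou_ea_c == ex["ea"]) & (ou_oa_c == ex["oa"])
    flip_c = (~pal) & (ou_ea_c == ex["oa"]) & (ou_oa_c == ex["ea"])

    keep = same | flipped | same_c | flip_c
    sign = np.where(flipped | flip_c, -1.0, 1.0)

    if palindromic_policy == "drop":
        keep &= ~pal
    else:
        eaf_x = ex["eaf"].to_numpy(float)
        eaf_y = ou["eaf"].to_numpy(float)
        maf_ok = (
            np.minimum(eaf_x, 1 - eaf_x) < eaf_threshold
        ) & (np.minimum(eaf_y, 1 - eaf_y) < eaf_threshold)
        informative = pd.notna(eaf_x) & pd.notna(eaf_y) & maf_ok
        keep &= (~pal) | informative
        # palindromic SNPs: allele labels are strand-ambiguous, so frequency
        # alone decides orientation; express the outcome eaf in terms of the
        # exposure's effect allele label first
        pal_np = pal.to_numpy()
        eaf_y_ea = np.where((ou["ea"] == ex["ea"]).to_numpy(), eaf_y, 1.0 - eaf_y)
        same_side = (eaf_x - 0.5) * (eaf_y_ea - 0.5) >= 0
        sign = np.where(pal_np & keep.to_numpy(), np.where(same_side, 1.0, -1.0), sign)

    keep_np = keep.to_numpy()
    if not keep_np.any():
        raise HarmonizationError("no SNPs survive allele harmonization")
    return HarmonizedPair(
        snp_ids=common.to_numpy()[keep_np],
        bx=ex["beta"].to_numpy(float)[keep_np],
        sex=ex["se"].to_numpy(float)[keep_np],
        by=(sign * ou["beta"].to_numpy(float))[keep_np],
        sey=ou["se"].to_numpy(float)[keep_np],
        n_exposure=float(np.nanmedian(ex["n"])) if ex["n"].notna().any() else None,
        n_outcome=float(np.nanmedian(ou["n"])) if ou["n"].notna().any() else None,
    )


# ---------------------------------------------------------------------------
# scale conversions

def rescale_effects(stats: SummaryStats, sd_source: float,
                    sd_target: float) -> SummaryStats:
    """Rescale per-SNP effects (and SEs) by ``sd_target / sd_source``.

    Puts SD-unit effects measured against one cohort's trait SD onto
    another cohort's SD scale; z-scores, and hence P-values, are unchanged.
    Only meaningful for quantitative traits.
    """
    if sd_source <= 0 or sd_target <= 0:
        raise ValueError("trait SDs must be > 0")
    if stats.meta.trait_type != "quantitative":
        raise ValueError("rescale_effects applies to quantitative traits only")
    ratio = sd_target / sd_source
    out = stats.table.copy()
    out["beta"] = out["beta"] * ratio
    out["se"] = out["se"] * ratio
    return SummaryStats(meta=stats.meta, table=out, n_dropped=stats.n_dropped)


def effective_n(n_cases: int, n_controls: int) -> float:
    """Effective sample size of a case-control GWAS: 4/(1/cases + 1/controls)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be > 0")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def or_from_logodds(beta: float, se: float, level: float = 0.95
                    ) -> tuple[float, float, float]:
    """Odds ratio and confidence interval from a log-odds effect and its SE."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (float(np.exp(beta)),
            float(np.exp(beta - z * se)),
            float(np.exp(beta + z * se)))
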