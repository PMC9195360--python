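"""Summary-statistics I/O, harmonization and scale conversions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from transmr import (SummaryStats, TraitMeta, effective_n, harmonize,
                     or_from_logodds, read_sumstats, rescale_effects,
                     write_sumstats)
from transmr.sumstats import HarmonizedPair, HarmonizationError, \
    SumstatsFormatError

from conftest import make_sumstats

META_Q = TraitMeta("bmi", "quantitative", sd_native=4.8)


def _write(tmp_path, text, name="ss.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "snp\tchr\tpos\tea\toa\teaf\tbeta\tse\tp\tn\n"


class TestReadSumstats:
    def test_well_formed_roundtrip(self, tmp_path):
        path = _write(tmp_path, HEADER
                      + "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-20\t50000\n"
                      + "rs2\t1\t200\tC\tT\t0.5\t-0.05\t0.02\t0.012\t50000\n"
                      + "rs3\t2\t300\tG\tA\t0.1\t0.0\t0.05\t1.0\t50000\n")
        ss = read_sumstats(path, META_Q)
        assert len(ss) == 3 and ss.n_dropped == 0
        out = tmp_path / "rt.tsv"
        write_sumstats(ss, out)
        ss2 = read_sumstats(out, META_Q)
        pd.testing.assert_frame_equal(ss.table, ss2.table)

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        path = _write(tmp_path, HEADER
                      + "rs1\t1\t100\tA\tG\t0.3\t0.1\t0\t0.5\t50000\n"   # se=0
                      + "rs2\t1\t200\tC\tC\t0.5\t0.1\t0.02\t0.5\t50000\n"  # ea==oa
                      + "rs3\t1\t300\tA\tG\t1.5\t0.1\t0.02\t0.5\t50000\n"  # eaf>1
                      + "rs4\t1\t400\tA\tG\t0.4\t0.1\t0.02\t0.5\t50000\n")
        ss = read_sumstats(path, META_Q)
        assert len(ss) == 1 and ss.n_dropped == 3

    def test_lowercase_alleles_uppercased(self, tmp_path):
        lower = _write(tmp_path, HEADER
                       + "rs1\t1\t100\ta\tg\t0.3\t0.1\t0.01\t1e-20\t50000\n",
                       "lower.tsv")
        upper = _write(tmp_path, HEADER
                       + "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-20\t50000\n",
                       "upper.tsv")
        pd.testing.assert_frame_equal(read_sumstats(lower, META_Q).table,
                                      read_sumstats(upper, META_Q).table)

    def test_missing_column_and_empty_file(self, tmp_path):
        with pytest.raises(SumstatsFormatError):
            read_sumstats(_write(tmp_path, "snp\tchr\nrs1\t1\n"), META_Q)
        with pytest.raises(SumstatsFormatError):
            read_sumstats(_write(tmp_path, "", "e.tsv"), META_Q)

    def test_missing_p_recomputed_from_z(self, tmp_path):
        path = _write(tmp_path, "snp\tchr\tpos\tea\toa\tbeta\tse\tn\n"
                      + "rs1\t1\t100\tA\tG\t0.1\t0.05\t50000\n")
        ss = read_sumstats(path, META_Q)
        from scipy import stats as sps
        assert ss.table["p"][0] == pytest.approx(2 * sps.norm.sf(2.0))

    def test_duplicate_snp_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_sumstats([("rs1", "1", 1, "A", "G", 0.5, 0.1, 0.01, 1000),
                           ("rs1", "1", 2, "A", "G", 0.5, 0.1, 0.01, 1000)])


class TestHarmonize:
    def test_sign_flip_on_swapped_alleles(self, toy_exposure, toy_outcome):
        pair = harmonize(toy_exposure, toy_outcome)
        assert list(pair.snp_ids) == ["rs1", "rs2", "rs3", "rs4"]
        # rs2 outcome was reported on the opposite allele
        assert pair.by[1] == pytest.approx(-0.041)
        assert pair.by[0] == pytest.approx(0.050)

    def test_mismatched_alleles_excluded(self):
        exp = make_sumstats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1000),
                             ("rs2", "1", 2, "A", "G", 0.3, 0.1, 0.01, 1000)])
        out = make_sumstats([("rs1", "1", 1, "A", "C", 0.3, 0.2, 0.01, 1000),
                             ("rs2", "1", 2, "G", "A", 0.3, 0.2, 0.01, 1000)])
        pair = harmonize(exp, out)
        assert list(pair.snp_ids) == ["rs2"]
        assert pair.by[0] == pytest.approx(-0.2)

    def test_palindromic_policies(self):
        exp = make_sumstats([("rs1", "1", 1, "A", "T", 0.10, 0.1, 0.01, 1000),
                             ("rs2", "1", 2, "A", "G", 0.30, 0.1, 0.01, 1000)])
        out = make_sumstats([("rs1", "1", 1, "A", "T", 0.11, 0.2, 0.01, 1000),
                             ("rs2", "1", 2, "A", "G", 0.30, 0.2, 0.01, 1000)])
        dropped = harmonize(exp, out, palindromic_policy="drop")
        assert list(dropped.snp_ids) == ["rs2"]
        kept = harmonize(exp, out, palindromic_policy="keep_with_eaf")
        assert list(kept.snp_ids) == ["rs1", "rs2"]
        # aligned by frequency: both eafs near 0.1, same orientation
        assert kept.by[0] == pytest.approx(0.2)

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp = make_sumstats([("rs1", "1", 1, "C", "G", 0.49, 0.1, 0.01, 1000)])
        out = make_sumstats([("rs1", "1", 1, "C", "G", 0.50, 0.2, 0.01, 1000)])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out, palindromic_policy="keep_with_eaf")

    def test_idempotent(self, toy_exposure, toy_outcome):
        pair = harmonize(toy_exposure, toy_outcome)
        exp2 = make_sumstats([
            (s, "1", i + 1, "A", "G", 0.3, b, se, 1000)
            for i, (s, b, se) in enumerate(zip(pair.snp_ids, pair.bx, pair.sex))])
        out2 = make_sumstats([
            (s, "1", i + 1, "A", "G", 0.3, b, se, 1000)
            for i, (s, b, se) in enumerate(zip(pair.snp_ids, pair.by, pair.sey))])
        pair2 = harmonize(exp2, out2)
        np.testing.assert_allclose(np.sort(pair2.by), np.sort(pair.by))

    def test_empty_intersection_errors(self):
        a = make_sumstats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1000)])
        b = make_sumstats([("rs9", "1", 9, "A", "G", 0.3, 0.1, 0.01, 1000)])
        with pytest.raises(HarmonizationError):
            harmonize(a, b)


class TestRescaleEffects:
    def test_identity_and_arithmetic(self, toy_exposure):
        same = rescale_effects(toy_exposure, 2.0, 2.0)
        pd.testing.assert_frame_equal(same.table, toy_exposure.table)
        scaled = rescale_effects(toy_exposure, 1.0, 1.1)
        assert scaled.table["beta"][0] == pytest.approx(0.11)
        assert scaled.table["se"][0] == pytest.approx(0.011)

    @given(ratio=st.floats(0.1, 10.0))
    def test_z_preserved(self, ratio):
        ss = make_sumstats([("rs1", "1", 1, "A", "G", 0.3, 0.2, 0.05, 1000)])
        out = rescale_effects(ss, 1.0, ratio)
        z0 = ss.table["beta"] / ss.table["se"]
        z1 = out.table["beta"] / out.table["se"]
        np.testing.assert_allclose(z0, z1)

    def test_binary_trait_rejected(self, toy_outcome):
        with pytest.raises(ValueError):
            rescale_effects(toy_outcome, 1.0, 2.0)


class TestEffectiveN:
    @pytest.mark.parametrize("cases,controls,expected", [
        (1000, 1000, 2000.0),
        (1000, 3000, 3000.0),
        (123, 123, 246.0),
    ])
    def test_values(self, cases, controls, expected):
        assert effective_n(cases, controls) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            effective_n(0, 100)


class TestOrFromLogodds:
    def test_point_cases(self):
        assert or_from_logodds(0.0, 0.0) == (1.0, 1.0, 1.0)
        o, lo, hi = or_from_logodds(math.log(2), 0.0)
        assert (o, lo, hi) == pytest.approx((2.0, 2.0, 2.0))

    def test_ua_meta_worked_example(self):
        o, lo, hi = or_from_logodds(0.101999, 0.0356859)
        assert (round(o, 2), round(lo, 2), round(hi, 2)) == (1.11, 1.03, 1.19)

    @given(b1=st.floats(-2, 2), b2=st.floats(-2, 2), se=st.floats(0, 1))
    def test_monotone_and_ordered(self, b1, b2, se):
        o1 = or_from_logodds(b1, se)
        o2 = or_from_logodds(b2, se)
        if b1 + 1e-9 < b2:
            assert o1[0] < o2[0]
        assert o1[1] <= o1[0] <= o1[2]
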