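"""Instrument-selection cascade, MR-PRESSO and strength diagnostics."""

import numpy as np
import pandas as pd
import pytest

from transmr import (LdMatrix, clump, consistency_filter, discovery_meta,
                     f_statistic, instrument_strength, overlap_bias,
                     pleiotropy_screen, presso_test, run_cascade)
from transmr.ivselect import (InsufficientInstrumentsError, cascade_counts,
                              compute_pve)
from transmr.simulate import simulate_pair

from conftest import make_sumstats


def _candidates(rows):
    """rows: (snp, chrom, pos, beta_a, se_a, beta_b, se_b)"""
    from scipy import stats as sps

    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "beta_a", "se_a",
                                     "beta_b", "se_b"])
    for c in "ab":
        df[f"p_{c}"] = 2 * sps.norm.sf(np.abs(df[f"beta_{c}"] / df[f"se_{c}"]))
    wa, wb = 1 / df["se_a"] ** 2, 1 / df["se_b"] ** 2
    df["beta_meta"] = (wa * df["beta_a"] + wb * df["beta_b"]) / (wa + wb)
    df["se_meta"] = (wa + wb) ** -0.5
    df["p_meta"] = 2 * sps.norm.sf(np.abs(df["beta_meta"] / df["se_meta"]))
    df["state"] = "candidate"
    df["reason"] = ""
    return df


class TestDiscoveryMeta:
    def test_equal_weight_case(self):
        a = make_sumstats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.05, 1000)])
        b = make_sumstats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.05, 1000)])
        tab = discovery_meta(a, b)
        assert tab["beta_meta"][0] == pytest.approx(0.1)
        assert tab["se_meta"][0] == pytest.approx(0.05 / np.sqrt(2), abs=2e-5)

    def test_snp_in_one_cohort_excluded(self):
        a = make_sumstats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.05, 1000),
                           ("rs2", "1", 2, "A", "G", 0.3, 0.1, 0.05, 1000)])
        b = make_sumstats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.05, 1000)])
        assert list(discovery_meta(a, b)["snp"]) == ["rs1"]

    def test_matches_hand_precision_weighting(self, rng):
        rows_a, rows_b = [], []
        for j in range(5):
            rows_a.append((f"rs{j}", "1", j, "A", "G", 0.3,
                           rng.normal(), 0.02 + 0.01 * j, 1000))
            rows_b.append((f"rs{j}", "1", j, "A", "G", 0.3,
                           rng.normal(), 0.05 - 0.005 * j, 1000))
        tab = discovery_meta(make_sumstats(rows_a), make_sumstats(rows_b))
        for j in range(5):
            wa = 1 / rows_a[j][7] ** 2
            wb = 1 / rows_b[j][7] ** 2
            exp = (wa * rows_a[j][6] + wb * rows_b[j][6]) / (wa + wb)
            assert tab["beta_meta"][j] == pytest.approx(exp)


class TestConsistencyFilter:
    def test_rules(self):
        df = _candidates([
            ("rs1", "1", 1, 0.1, 0.01, -0.1, 0.01),   # opposite signs
            ("rs2", "1", 2, 0.1, 0.053, 0.1, 0.01),   # p_a ~ 0.06
            ("rs3", "1", 3, 0.1, 0.03, 0.1, 0.03),    # both significant
        ])
        out = consistency_filter(df, p_single=0.05)
        assert out.set_index("snp")["state"].to_dict() == {
            "rs1": "dropped_consistency", "rs2": "dropped_consistency",
            "rs3": "candidate"}


def _brute_force_clump(df, ld, r2_max, p_max, window_bp):
    """Independent greedy oracle on the explicit candidate ordering."""
    live = df[(df["state"] == "candidate") & (df["p_meta"] < p_max)]
    order = live.sort_values(["p_meta", "chrom", "pos", "snp"]).index.tolist()
    kept, removed = [], set()
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in order:
            if j in removed or j in kept:
                continue
            same_chr = df.loc[i, "chrom"] == df.loc[j, "chrom"]
            near = abs(df.loc[i, "pos"] - df.loc[j, "pos"]) <= window_bp
            if same_chr and near and \
                    ld.lookup(df.loc[i, "snp"], df.loc[j, "snp"]) >= r2_max:
                removed.add(j)
    return {df.loc[i, "snp"] for i in kept}


class TestClump:
    def test_single_significant_snp_selected(self):
        df = _candidates([("rs1", "1", 1, 0.2, 0.03, 0.2, 0.03)])
        ld = LdMatrix(["rs1"], np.eye(1))
        out = clump(df, ld)
        assert out["state"][0] == "candidate"

    def test_three_snp_example(self):
        df = _candidates([
            ("rs1", "1", 1000, 0.30, 0.03, 0.30, 0.03),
            ("rs2", "1", 2000, 0.28, 0.03, 0.28, 0.03),
            ("rs3", "1", 3000, 0.25, 0.03, 0.25, 0.03),
        ])
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        ld = LdMatrix(["rs1", "rs2", "rs3"], r2)
        out = clump(df, ld)
        states = out.set_index("snp")["state"].to_dict()
        assert states == {"rs1": "candidate", "rs2": "dropped_clump",
                          "rs3": "candidate"}

    def test_all_below_threshold_empty(self):
        df = _candidates([("rs1", "1", 1, 0.01, 0.03, 0.01, 0.03)])
        ld = LdMatrix(["rs1"], np.eye(1))
        out = clump(df, ld)
        assert (out["state"] == "dropped_clump").all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = 20
        rows = [(f"rs{j}", str(rng.integers(1, 3)),
                 int(rng.integers(0, 3_000_000)),
                 float(rng.normal(0.2, 0.05)), 0.02,
                 float(rng.normal(0.2, 0.05)), 0.02) for j in range(k)]
        df = _candidates(rows)
        a = rng.normal(size=(k, k))
        c = np.corrcoef(a @ a.T)
        r2 = np.clip(c**2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix([r[0] for r in rows], r2)
        out = clump(df, ld, r2_max=0.2, p_max=1e-4, window_bp=1_000_000)
        got = set(out.loc[out["state"] == "candidate", "snp"])
        assert got == _brute_force_clump(df, ld, 0.2, 1e-4, 1_000_000)

    def test_selected_pairwise_unlinked(self, rng):
        k = 15
        rows = [(f"rs{j}", "1", 10_000 * j, float(rng.normal(0.2, 0.03)),
                 0.02, float(rng.normal(0.2, 0.03)), 0.02) for j in range(k)]
        df = _candidates(rows)
        a = rng.normal(size=(k, k))
        r2 = np.clip(np.corrcoef(a @ a.T) ** 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix([r[0] for r in rows], r2)
        out = clump(df, ld, r2_max=0.1)
        sel = out.loc[out["state"] == "candidate", "snp"].tolist()
        for i, a_id in enumerate(sel):
            for b_id in sel[i + 1:]:
                assert ld.lookup(a_id, b_id) < 0.1


class TestPleiotropyScreen:
    def _setup(self):
        cand = _candidates([("rs1", "1", 1, 0.3, 0.03, 0.3, 0.03),
                            ("rs2", "1", 2, 0.3, 0.03, 0.3, 0.03)])
        other = pd.DataFrame({"snp": ["rs1"], "p_meta": [1e-10]})
        return cand, {"ldl": other}

    def test_associated_iv_dropped(self):
        cand, others = self._setup()
        out = pleiotropy_screen(cand, others)
        assert out.set_index("snp")["state"]["rs1"] == "dropped_pleiotropy"
        assert out.set_index("snp")["state"]["rs2"] == "candidate"

    def test_exception_list_retains(self):
        cand, others = self._setup()
        out = pleiotropy_screen(cand, others, exceptions=[("rs1", "ldl")])
        assert (out["state"] == "candidate").all()

    def test_absent_lookup_non_significant(self):
        cand, _ = self._setup()
        out = pleiotropy_screen(cand, {"tg": pd.DataFrame(
            {"snp": ["rs99"], "p_meta": [1e-10]})})
        assert (out["state"] == "candidate").all()


class TestPresso:
    def test_planted_outlier_detected(self):
        rng = np.random.default_rng(42)
        pair = simulate_pair(30, 0.3, rng, n_outliers=1,
                             outlier_size=10 * 0.02)
        gp, _, removal = presso_test(pair, n_sim=1000, seed=7)
        assert gp < 0.05
        assert "iv0" in removal

    def test_null_mostly_clean(self):
        hits = 0
        for seed in range(20):
            pair = simulate_pair(30, 0.3, np.random.default_rng(100 + seed))
            _, _, removal = presso_test(pair, n_sim=300, seed=seed)
            hits += bool(removal)
        assert hits <= 2

    def test_global_p_calibrated_under_null(self):
        # empirical rejection rate at alpha 0.05 close to nominal
        from transmr.calibration import presso_null_rejection

        res = presso_null_rejection(n_reps=500, seed=60_000, n_sim=300)
        assert 0.02 <= res["rate"] <= 0.09

    def test_too_few_instruments(self):
        pair = simulate_pair(3, 0.3, np.random.default_rng(0))
        with pytest.raises(InsufficientInstrumentsError):
            presso_test(pair, n_sim=200, seed=0)

    def test_deterministic_under_seed(self):
        pair = simulate_pair(25, 0.2, np.random.default_rng(5))
        r1 = presso_test(pair, n_sim=300, seed=9)
        r2 = presso_test(pair, n_sim=300, seed=9)
        assert r1[0] == r2[0] and r1[2] == r2[2]


class TestStrengthDiagnostics:
    def test_pve_values(self):
        assert compute_pve(0.0, 0.1, 100) == 0.0
        # z^2 == n-2 is the half-way point
        assert compute_pve(10.0, 1.0, 102) == pytest.approx(0.5)
        assert compute_pve(10.0, 1.0, 10002) == pytest.approx(100 / 10100)

    def test_f_values(self):
        assert f_statistic(0.0, 100) == 0.0
        assert f_statistic(0.001, 100_002) == pytest.approx(100.1001)

    def test_f_of_pve_recovers_z2(self):
        for z in (1.0, 3.3, 8.0):
            n = 5000
            assert f_statistic(compute_pve(z, 1.0, n), n) == pytest.approx(z**2)

    def test_f_monotone_in_pve(self):
        grid = np.linspace(0.0, 0.5, 20)
        f = f_statistic(grid, 1000)
        assert np.all(np.diff(f) > 0)

    def test_mean_f(self):
        s = instrument_strength(np.array([0.1, 0.2]), np.array([0.02, 0.02]),
                                10_000)
        assert s.mean_f == pytest.approx(np.mean(s.f_stat))

    def test_overlap_bias(self):
        assert overlap_bias(0.2, 0.1, 20.0).bias == pytest.approx(0.001)
        assert overlap_bias(0.2, 0.0, 20.0).bias == 0.0
        assert overlap_bias(0.0, 0.5, 20.0).bias == 0.0
        with pytest.raises(ValueError):
            overlap_bias(0.2, 1.5, 20.0)
        with pytest.raises(ValueError):
            overlap_bias(0.2, 0.5, 0.0)


class TestCascade:
    def test_states_partition_candidates(self, rng):
        from transmr import SimConfig, simulate_study

        stats, ld, _ = simulate_study(SimConfig(seed=77, n_snps=400))
        from transmr.sumstats import harmonize

        pairs = {p: harmonize(stats[("exposure", p)], stats[("outcome", p)])
                 for p in ("EAS", "EUR")}
        audit = run_cascade(stats[("exposure", "EAS")],
                            stats[("exposure", "EUR")], ld_by_pop=ld,
                            other_traits={}, pair_by_pop=pairs,
                            presso_nsim=200, seed=1)
        counts = cascade_counts(audit)
        assert sum(counts.values()) == 400
        assert counts["candidate"] == 0
        assert (audit["state"].isin(
            ["dropped_consistency", "dropped_clump", "dropped_pleiotropy",
             "dropped_presso", "selected"])).all()
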