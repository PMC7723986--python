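"""FPKM arithmetic, library summaries, the NB exact test against
brute-force oracles, dispersion estimation and DE calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, nbinom

from lnclact.datasets import example_library_qc
from lnclact.expression import (
    ExpressionMatrix,
    call_differential,
    compute_fpkm,
    estimate_common_dispersion,
    nb_exact_test,
    summarize_libraries,
)

GROUPS_2V3 = ["LP", "LP", "DP", "DP", "DP"]
EQUAL_LIBS = np.full(5, 1e6)


def oracle_exact_p(y, groups, phi):
    """Independent route: conditional null of the group-A sum from products
    of scipy NB pmfs at an arbitrary mean, normalized by enumeration."""
    y = np.asarray(y)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    mask = groups == levels[0]
    S = int(y.sum())
    if S == 0:
        return 1.0
    a_obs = int(y[mask].sum())
    n_a, n_b = int(mask.sum()), int((~mask).sum())
    a = np.arange(S + 1)
    if phi == 0:
        probs = binom.pmf(a, S, n_a / (n_a + n_b))
    else:
        r = 1.0 / phi
        mu = 7.3  # arbitrary: the conditional law is mean-free
        p0 = r / (r + mu)
        probs = nbinom.pmf(a, n_a * r, p0) * nbinom.pmf(S - a, n_b * r, p0)
        probs = probs / probs.sum()
    return min(1.0, float(probs[probs <= probs[a_obs] * (1 + 1e-10)].sum()))


class TestComputeFpkm:
    def test_formula(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["a", "b"])
        fpkm = compute_fpkm(counts, pd.Series({"a": 2000, "b": 500}),
                            pd.Series({"s1": 5e6}))
        assert fpkm.loc["a", "s1"] == pytest.approx(10.0)
        assert fpkm.loc["b", "s1"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, (20, 2)),
                              columns=["s1", "s2"])
        lengths = pd.Series(rng.integers(200, 5000, 20), index=counts.index)
        f1 = compute_fpkm(counts, lengths, pd.Series({"s1": 1e6, "s2": 1e6}))
        f2 = compute_fpkm(counts, lengths, pd.Series({"s1": 2e6, "s2": 1e6}))
        np.testing.assert_allclose(f2["s1"], f1["s1"] / 2)
        np.testing.assert_allclose(f2["s2"], f1["s2"])

    def test_linear_in_counts(self):
        counts = pd.DataFrame({"s1": [10]}, index=["a"])
        lengths = pd.Series({"a": 1000})
        libs = pd.Series({"s1": 1e6})
        f1 = compute_fpkm(counts, lengths, libs)
        f3 = compute_fpkm(3 * counts, lengths, libs)
        np.testing.assert_allclose(f3.values, 3 * f1.values)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            compute_fpkm(pd.DataFrame({"s1": [1]}, index=["a"]),
                         pd.Series({"a": 0}), pd.Series({"s1": 1e6}))


class TestLibrarySummary:
    def test_example_table_arithmetic(self):
        qc, groups = example_library_qc()
        s = summarize_libraries(qc, groups)
        per = s["per_sample"]["mapping_pct"]
        assert per["DP1"] == 86.27
        assert per["DP2"] == 86.32
        assert per["DP3"] == 83.79
        assert per["LP1"] == 86.48
        assert per["LP2"] == 85.76
        assert s["total_clean_reads_million"] == 784.05
        assert s["group_sums"]["DP"]["raw_reads_million"] == 503.07
        assert s["group_sums"]["LP"]["raw_reads_million"] == 299.23

    def test_fully_mapped_sample(self):
        qc = pd.DataFrame(
            {"raw_reads": [100], "clean_reads": [90], "q30_pct": [95.0],
             "gc_pct": [50.0], "total_mapped": [90], "uniquely_mapped": [80]},
            index=["s1"])
        s = summarize_libraries(qc, {"s1": "LP"})
        assert s["per_sample"]["mapping_pct"]["s1"] == 100.0

    def test_mapped_exceeding_clean_is_rejected(self):
        qc = pd.DataFrame(
            {"raw_reads": [100], "clean_reads": [90], "q30_pct": [95.0],
             "gc_pct": [50.0], "total_mapped": [91], "uniquely_mapped": [80]},
            index=["s1"])
        with pytest.raises(ValueError, match="s1"):
            summarize_libraries(qc, {"s1": "LP"})


class TestExactTest:
    def test_balanced_split_gives_p_one(self):
        # equal normalized totals in a symmetric 1-vs-1 design are modal
        assert nb_exact_test(np.array([15, 15]), ["A", "B"],
                             np.full(2, 1e6), 0.1) == pytest.approx(1.0)
        # equal group means in the 2-vs-3 design sit within one count of the
        # (discrete, slightly asymmetric) mode: p stays near 1
        y = np.full(5, 20)
        assert nb_exact_test(y, GROUPS_2V3, EQUAL_LIBS, 0.1) > 0.9

    def test_zero_total_is_p_one(self):
        assert nb_exact_test(np.zeros(5), GROUPS_2V3, EQUAL_LIBS, 0.1) == 1.0

    def test_poisson_limit_one_vs_one(self):
        # phi=0, equal libraries, 1-vs-1, split 0|10: null Binomial(10, 1/2)
        p = nb_exact_test(np.array([0, 10]), ["A", "B"], np.full(2, 1e6), 0.0)
        assert p == pytest.approx(2 * 0.5 ** 10, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle_on_random_small_cases(self, phi):
        rng = np.random.default_rng(41)
        for _ in range(60):
            y = rng.integers(0, 8, 5)
            if y.sum() > 30:
                continue
            p = nb_exact_test(y, GROUPS_2V3, EQUAL_LIBS, phi)
            p_oracle = oracle_exact_p(y, GROUPS_2V3, phi)
            assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_symmetric_under_group_relabeling(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            y = rng.integers(0, 50, 5)
            flipped = ["DP" if g == "LP" else "LP" for g in GROUPS_2V3]
            assert nb_exact_test(y, GROUPS_2V3, EQUAL_LIBS, 0.1) == \
                pytest.approx(nb_exact_test(y, flipped, EQUAL_LIBS, 0.1))

    def test_p_in_unit_interval_and_monotone_toward_mode(self):
        # 1-vs-1 Poisson null: p must grow as the split approaches balance
        total = 40
        ps = [nb_exact_test(np.array([a, total - a]), ["A", "B"],
                            np.full(2, 1e6), 0.0)
              for a in range(0, total // 2 + 1)]
        assert all(0 < p <= 1 for p in ps)
        assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(len(ps) - 1))

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.ones(5), GROUPS_2V3, EQUAL_LIBS, -0.1)


class TestDispersion:
    def _simulate(self, phi, n_features=2000, mu=100.0, seed=19):
        rng = np.random.default_rng(seed)
        if phi == 0:
            mat = rng.poisson(mu, size=(n_features, 5))
        else:
            r = 1.0 / phi
            mat = rng.negative_binomial(r, r / (r + mu), size=(n_features, 5))
        counts = pd.DataFrame(mat, columns=["LP1", "LP2", "DP1", "DP2", "DP3"])
        groups = dict(zip(counts.columns, GROUPS_2V3))
        libs = pd.Series(EQUAL_LIBS, index=counts.columns)
        return counts, groups, libs

    def test_recovers_planted_dispersion(self):
        counts, groups, libs = self._simulate(phi=0.1)
        phi_hat = estimate_common_dispersion(counts, groups, libs)
        assert 0.05 <= phi_hat <= 0.2

    def test_poisson_data_gives_near_zero(self):
        counts, groups, libs = self._simulate(phi=0.0)
        assert estimate_common_dispersion(counts, groups, libs) < 0.02

    def test_identical_counts_give_zero(self):
        counts = pd.DataFrame(np.full((50, 5), 17),
                              columns=["LP1", "LP2", "DP1", "DP2", "DP3"])
        groups = dict(zip(counts.columns, GROUPS_2V3))
        libs = pd.Series(EQUAL_LIBS, index=counts.columns)
        assert estimate_common_dispersion(counts, groups, libs) == 0.0

    def test_all_zero_matrix_errors(self):
        counts = pd.DataFrame(np.zeros((5, 5), dtype=int),
                              columns=["LP1", "LP2", "DP1", "DP2", "DP3"])
        groups = dict(zip(counts.columns, GROUPS_2V3))
        with pytest.raises(ValueError):
            estimate_common_dispersion(counts, groups,
                                       pd.Series(EQUAL_LIBS, index=counts.columns))

    def test_trimming_resists_outlier_features(self):
        counts, groups, libs = self._simulate(phi=0.05, n_features=900)
        rng = np.random.default_rng(7)
        wild = pd.DataFrame(
            rng.negative_binomial(0.25, 0.25 / (0.25 + 100.0), size=(100, 5)),
            columns=counts.columns, index=range(900, 1000))
        mixed = pd.concat([counts, wild])
        plain = estimate_common_dispersion(mixed, groups, libs)
        robust = estimate_common_dispersion(mixed, groups, libs, trim=0.15)
        assert robust < plain
        assert robust < 0.15


class TestCallDifferential:
    def _matrix(self, mat):
        counts = pd.DataFrame(mat, columns=["LP1", "LP2", "DP1", "DP2", "DP3"])
        counts.index = [f"f{i}" for i in range(len(counts))]
        groups = dict(zip(counts.columns, GROUPS_2V3))
        libs = pd.Series(EQUAL_LIBS, index=counts.columns)
        return ExpressionMatrix(counts, groups, libs)

    def test_empty_feature_set(self):
        m = self._matrix(np.zeros((0, 5), dtype=int))
        assert len(call_differential(m, phi=0.1)) == 0

    def test_direction_and_significance_flags(self):
        m = self._matrix(np.array([
            [400, 400, 100, 100, 100],   # 4x up in LP
            [100, 100, 400, 400, 400],   # 4x down
            [200, 200, 200, 200, 200],   # flat
        ]))
        de = call_differential(m, phi=0.05).set_index("feature_id")
        assert de.loc["f0", "direction"] == "up" and de.loc["f0", "significant"]
        assert de.loc["f1", "direction"] == "down" and de.loc["f1", "significant"]
        assert not de.loc["f2", "significant"]
        assert de.loc["f0", "log2fc"] == pytest.approx(2.0, abs=0.01)

    def test_null_features_rarely_called(self):
        # planted log2FC = 0: non-significant in >= 93% of simulations
        rng = np.random.default_rng(53)
        phi, mu = 0.1, 100.0
        r = 1.0 / phi
        mat = rng.negative_binomial(r, r / (r + mu), size=(1000, 5))
        de = call_differential(self._matrix(mat), phi=phi)
        assert (~de["significant"]).mean() >= 0.93

    def test_power_on_planted_two_fold_log2(self):
        # |log2FC| = 2 with mu >= 50 in the low group: called with the
        # planted direction in >= 90% of replicates
        rng = np.random.default_rng(59)
        phi = 0.1
        r = 1.0 / phi
        mu = np.tile([200.0, 200.0, 50.0, 50.0, 50.0], (500, 1))
        mat = rng.negative_binomial(r, r / (r + mu))
        de = call_differential(self._matrix(mat), phi=phi)
        called = (de["significant"] & (de["direction"] == "up")).mean()
        assert called >= 0.90

    def test_zero_count_group_uses_pseudocount(self):
        m = self._matrix(np.array([[40, 40, 0, 0, 0]]))
        de = call_differential(m, phi=0.1)
        assert np.isfinite(de.loc[0, "log2fc"])
        assert de.loc[0, "log2fc"] > 0

    def test_bh_column_dominates_raw_p(self, bundle):
        m = ExpressionMatrix(bundle["counts"], bundle["groups"], bundle["libs"])
        de = call_differential(m, phi=0.1)
        assert (de["p_adj_bh"] >= de["p_value"] - 1e-12).all()
        assert de["p_value"].between(0, 1, inclusive="right").all()

    def test_recovers_planted_de_on_default_bundle(self, bundle):
        gt = bundle["gt"]
        m = ExpressionMatrix(bundle["counts"], bundle["groups"], bundle["libs"])
        phi = estimate_common_dispersion(bundle["counts"], bundle["groups"],
                                         bundle["libs"], trim=0.1)
        de = call_differential(m, phi=phi).set_index("feature_id")
        hits = [
            bool(de.loc[f, "significant"])
            and (de.loc[f, "log2fc"] > 0) == (gt.de_log2fc[f] > 0)
            for f in gt.de_log2fc
        ]
        assert np.mean(hits) >= 0.9
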