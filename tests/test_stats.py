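"""Tests for the statistical battery: normality screen, Friedman, Wilcoxon,
Holm, JZS Bayes factors, quartile split and cluster permutation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from diversitrace.errors import (
    DegenerateSignalError,
    DesignError,
    PrecisionError,
    SampleSizeError,
)
from diversitrace.montage import STUDY_64, build_adjacency, standard_positions
from diversitrace.stats import (
    ConditionMatrix,
    bf_one_way_rm,
    check_normality,
    cluster_permutation_test,
    friedman_test,
    holm_adjust,
    interpret_bf,
    jzs_bf_from_t,
    jzs_bf_paired,
    quartile_split,
    wilcoxon_signed_rank,
)

from oracles import friedman_exact_p, jzs_bf_oracle, wilcoxon_exact_p


class TestNormalityScreen:
    def test_gaussian_samples_pass(self):
        rng = np.random.default_rng(1)
        decisions = [
            check_normality(rng.standard_normal(1000))[2] for _ in range(100)
        ]
        assert decisions.count("normal") >= 90

    def test_exponential_samples_fail(self):
        rng = np.random.default_rng(2)
        decisions = [
            check_normality(rng.exponential(size=1000))[2] for _ in range(100)
        ]
        assert decisions.count("non-normal") >= 99

    def test_sample_against_own_ecdf_has_vanishing_distance(self):
        # KS distance to (an interpolant of) the sample's own empirical CDF
        # vanishes up to the 1/n discretization step
        rng = np.random.default_rng(3)
        x = np.sort(rng.standard_normal(200))
        mid = (np.arange(x.size) + 0.5) / x.size
        ecdf = lambda q: np.interp(q, x, mid, left=0.0, right=1.0)
        stat, _, _ = check_normality(x, cdf=ecdf)
        assert stat <= 1.0 / x.size

    def test_too_small_sample(self):
        with pytest.raises(SampleSizeError):
            check_normality([1.0, 2.0, 3.0])


# frozen 5x3 table (random normal draws) with its exact permutation p
# computed by enumerating all (3!)^5 within-subject rank assignments
FRIEDMAN_TABLE = np.array(
    [
        [0.00, 0.30, -0.27],
        [-0.89, -0.45, -0.99],
        [0.06, 1.34, -0.49],
        [-0.62, 0.49, 0.36],
        [0.11, -0.93, -0.03],
    ]
)
FRIEDMAN_EXACT_P = 0.18209876543209877


class TestFriedman:
    def test_identical_conditions_give_null_result(self):
        stat, df, p = friedman_test(np.tile([[1.0], [2.0], [3.0]], (1, 4)))
        assert stat == 0.0
        assert df == 3
        assert p == 1.0

    def test_chi2_p_close_to_exact_enumeration(self):
        assert friedman_exact_p(FRIEDMAN_TABLE) == pytest.approx(FRIEDMAN_EXACT_P)
        _, _, p = friedman_test(FRIEDMAN_TABLE)
        assert p == pytest.approx(FRIEDMAN_EXACT_P, abs=0.02)

    def test_maximal_concordance_closed_form(self):
        # every subject ranks the k=3 conditions identically: chi2 = n(k-1)
        m = np.tile([1.0, 2.0, 3.0], (10, 1)) + np.arange(10)[:, None]
        stat, df, _ = friedman_test(m)
        assert stat == pytest.approx(20.0)
        assert df == 2

    def test_incomplete_matrix_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(DesignError):
            friedman_test(m)


class TestWilcoxon:
    def test_five_concordant_pairs_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        z, p = wilcoxon_signed_rank(a + 1.0, a)
        assert p == pytest.approx(2 / 32)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            wilcoxon_signed_rank(np.ones(6), np.ones(6))

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12) - 0.5
        z, p = wilcoxon_signed_rank(a, b)
        exact = wilcoxon_exact_p(a - b)
        assert p == pytest.approx(exact, abs=1e-12)
        approx = 2 * sps.norm.sf(abs(z))
        assert approx == pytest.approx(exact, abs=0.01)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(40)
        z, p = wilcoxon_signed_rank(a + 0.8, a)
        ref = sps.wilcoxon(a + 0.8, a, correction=True, mode="approx")
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestHolm:
    def test_step_down_example(self):
        adj = holm_adjust([0.010, 0.040, 0.030])
        assert adj == pytest.approx([0.030, 0.060, 0.060])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_dominates_raw_and_bonferroni(self, ps):
        adj = holm_adjust(ps)
        p = np.asarray(ps)
        bonf = np.minimum(p * p.size, 1.0)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= bonf + 1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.random(9)
        _, ref, _, _ = multipletests(p, method="holm")
        assert holm_adjust(p) == pytest.approx(ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestJzsBayesFactor:
    def test_null_t_supports_null(self):
        assert jzs_bf_from_t(0.0, 19) < 1.0

    @pytest.mark.parametrize("t", [0.0, 1.0, 2.0, 3.0, 4.0])
    def test_matches_dense_quadrature_oracle(self, t):
        bf = jzs_bf_from_t(t, 19)
        assert bf == pytest.approx(jzs_bf_oracle(t, 19), rel=1e-4)

    def test_strictly_increasing_in_t(self):
        vals = [jzs_bf_from_t(t, 19) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(2.5, 19), (0.7, 12)]:
            ref = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert jzs_bf_from_t(t, n, 0.707) == pytest.approx(ref, rel=1e-6)

    def test_fixed_effect_grows_without_bound_in_n(self):
        # a fixed standardized effect (t = 0.5 * sqrt(n)) becomes ever
        # stronger evidence as the sample grows
        vals = [jzs_bf_from_t(0.5 * np.sqrt(n), n) for n in (10, 50, 200)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 1e6

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSignalError):
            jzs_bf_paired(np.ones(6) + 1.0, np.ones(6))


class TestRmAnovaBayesFactor:
    def test_null_data_median_bf_below_one(self):
        rng = np.random.default_rng(10)
        bfs = []
        for i in range(60):
            y = rng.standard_normal((19, 5)) + rng.standard_normal((19, 1))
            bfs.append(bf_one_way_rm(y, seed=i).bf10)
        assert np.median(bfs) < 1.0

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(11)
        hit = 0
        runs = 40
        for i in range(runs):
            cond = rng.standard_normal(5)
            cond = (cond - cond.mean()) / cond.std()  # standardized effect 1.0
            y = rng.standard_normal((19, 5)) + rng.standard_normal((19, 1)) + cond
            hit += bf_one_way_rm(y, seed=i).bf10 > 10
        assert hit >= int(0.95 * runs)

    def test_mc_error_shrinks_with_draws(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal((10, 4))
        se1 = bf_one_way_rm(y, draws=10_000, seed=1).mc_se
        se2 = bf_one_way_rm(y, draws=40_000, seed=2).mc_se
        assert se2 == pytest.approx(se1 / 2, rel=0.5)

    def test_insufficient_draws_rejected(self):
        with pytest.raises(PrecisionError):
            bf_one_way_rm(np.random.default_rng(0).standard_normal((6, 3)), draws=100)


class TestInterpretBf:
    @pytest.mark.parametrize(
        "bf,expected",
        [
            (0.14, "moderate evidence for the null"),
            (26.89, "strong evidence for the alternative"),
            (1.0, "inconclusive"),
            (0.05, "strong evidence for the null"),
            (0.1, "strong evidence for the null"),  # boundary -> lower band
            (5.0, "moderate evidence for the alternative"),
        ],
    )
    def test_bands(self, bf, expected):
        assert interpret_bf(bf) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            interpret_bf(0.0)


class TestQuartileSplit:
    def test_study_epoch_count_splits_evenly(self):
        q = quartile_split(np.arange(252))
        assert [np.sum(q == i) for i in range(4)] == [63, 63, 63, 63]

    def test_remainder_goes_to_early_quartiles(self):
        q = quartile_split(np.arange(10))
        assert [np.sum(q == i) for i in range(4)] == [3, 3, 2, 2]

    def test_split_depends_only_on_order(self):
        rng = np.random.default_rng(13)
        order = rng.permutation(20) * 7  # arbitrary spacing
        q = quartile_split(order)
        # epoch with the smallest session order is in Q1, largest in Q4
        assert q[np.argmin(order)] == 0
        assert q[np.argmax(order)] == 3

    def test_too_few_epochs(self):
        with pytest.raises(SampleSizeError):
            quartile_split([1, 2, 3])


@pytest.fixture(scope="module")
def adjacency():
    return build_adjacency(standard_positions(STUDY_64))


class TestClusterPermutation:

    def test_zero_differences_yield_no_clusters(self, adjacency):
        res = cluster_permutation_test(
            np.zeros((8, 64)), adjacency=adjacency, n_perm=500, seed=0
        )
        assert res.clusters == []
        assert np.allclose(res.t_values, 0.0)

    def test_planted_parietal_shift_detected(self, adjacency):
        planted = [STUDY_64.index(c) for c in ["P3", "P1", "Pz", "P2", "P4", "CPz"]]
        rng = np.random.default_rng(14)
        hits = 0
        runs = 10
        for i in range(runs):
            diff = rng.standard_normal((19, 64))
            diff[:, planted] += 1.0  # 1 SD shift
            res = cluster_permutation_test(
                diff, adjacency=adjacency, n_perm=500, seed=i
            )
            found = set()
            for c in res.significant_clusters():
                found.update(c["channels"])
            hits += len(found & set(planted)) >= 4
        assert hits >= int(0.9 * runs)

    def test_null_familywise_error_controlled(self, adjacency):
        rng = np.random.default_rng(15)
        any_sig = 0
        runs = 60
        for i in range(runs):
            res = cluster_permutation_test(
                rng.standard_normal((12, 64)), adjacency=adjacency,
                n_perm=500, seed=i,
            )
            any_sig += bool(res.significant_clusters())
        assert any_sig / runs <= 0.12

    def test_precision_and_sample_size_guards(self, adjacency):
        with pytest.raises(PrecisionError):
            cluster_permutation_test(
                np.zeros((8, 64)), adjacency=adjacency, n_perm=100
            )
        with pytest.raises(SampleSizeError):
            cluster_permutation_test(
                np.zeros((3, 64)), adjacency=adjacency, n_perm=500
            )

    def test_cluster_p_in_unit_interval(self, adjacency):
        rng = np.random.default_rng(16)
        diff = rng.standard_normal((10, 64)) + 0.8
        res = cluster_permutation_test(diff, adjacency=adjacency, n_perm=500, seed=3)
        assert res.clusters
        for c in res.clusters:
            assert 0.0 < c["p"] <= 1.0


def test_condition_matrix_validation():
    with pytest.raises(DesignError):
        ConditionMatrix(np.ones((3, 2)), ["a"])
    with pytest.raises(DesignError):
        ConditionMatrix(np.ones((1, 3)), ["a", "b", "c"])
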