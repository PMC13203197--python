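"""Stratification, agreement statistics, clustering, and pairing analysis."""

import itertools

import numpy as np
import pytest

from crabtai import (
    bland_altman,
    bootstrap_jaccard,
    correlate,
    group_difference_test,
    icc_consistency,
    kmeans_silhouette,
    normality_gate,
    pairing_analysis,
    reference_model_predict,
    spearman_brown,
    stratify,
    zscore,
)
from crabtai.errors import DomainError, ParameterError


class TestStratify:
    def test_quartile_sizes_at_cohort_scale(self):
        rng = np.random.default_rng(0)
        labels = stratify(rng.normal(size=200))
        counts = {g: int(np.sum(labels == g)) for g in ("HA", "MA", "LA")}
        assert counts == {"HA": 50, "MA": 100, "LA": 50}

    def test_minimal_cohort(self):
        labels = stratify([1.0, 2.0, 3.0, 4.0])
        assert list(labels) == ["LA", "MA", "MA", "HA"]

    def test_all_ties_resolved_by_input_order(self):
        labels = stratify(np.zeros(200))
        assert list(labels[:50]) == ["LA"] * 50
        assert list(labels[-50:]) == ["HA"] * 50
        assert list(labels[50:150]) == ["MA"] * 100

    def test_groups_are_ordered_partitions(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=83)  # distinct with probability 1
        labels = stratify(scores)
        assert scores[labels == "HA"].min() >= scores[labels == "MA"].max()
        assert scores[labels == "MA"].min() >= scores[labels == "LA"].max()
        assert len(scores) == sum((labels == g).sum() for g in ("HA", "MA", "LA"))

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ParameterError):
            stratify([1.0, 2.0, 3.0])


class TestNormalityGate:
    def test_normal_samples_usually_pass(self):
        parametric = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = normality_gate(rng.normal(size=500))
            parametric += res.branch == "parametric"
        assert parametric >= 90

    def test_heavy_skew_fails_decisively(self):
        nonparametric = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = normality_gate(rng.lognormal(0.0, 1.0, size=500))
            nonparametric += res.branch == "nonparametric"
        assert nonparametric >= 99

    def test_ks_variant_available(self):
        rng = np.random.default_rng(0)
        res = normality_gate(rng.normal(size=200), method="ks")
        assert res.method == "ks" and res.branch == "parametric"

    def test_constant_vector_rejected(self):
        with pytest.raises(ParameterError):
            normality_gate(np.ones(10))


class TestZscoreAndCorrelate:
    def test_three_point_example(self):
        np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_standardized_moments(self):
        rng = np.random.default_rng(2)
        z = zscore(rng.gamma(2.0, size=400))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ParameterError):
            zscore(np.full(5, 3.3))

    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        r, _ = correlate([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_spearman_sees_monotone_nonlinearity(self):
        x = np.arange(1.0, 20.0)
        assert correlate(x, np.exp(x / 5), method="spearman")[0] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            correlate([1, 1, 1], [1, 2, 3])


class TestReferenceModel:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [(0.0, 0.0, -0.002), (10.0, 100.0, 0.128), (1.0, 1.0, 0.020)],
    )
    def test_direct_evaluation(self, x1, x2, expected):
        assert reference_model_predict(x1, x2) == pytest.approx(expected)

    def test_vectorized(self):
        out = reference_model_predict([0.0, 1.0], [0.0, 1.0])
        np.testing.assert_allclose(out, [-0.002, 0.020])


def _anova_oracle(m):
    """Independent sums-of-squares route to the consistency ICCs."""
    n, k = m.shape
    grand = m.mean()
    ss_rows = sum(k * (row.mean() - grand) ** 2 for row in m)
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((v - grand) ** 2 for v in m.ravel())
    ms_r = ss_rows / (n - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e), (ms_r - ms_e) / ms_r


class TestIcc:
    def test_identical_columns_give_perfect_consistency(self):
        m = np.column_stack([np.arange(10.0), np.arange(10.0)])
        rep = icc_consistency(m)
        assert rep.icc_c1 == pytest.approx(1.0)
        assert rep.icc_ck == pytest.approx(1.0)

    def test_small_integer_matrix_matches_anova_oracle(self):
        m = np.array([[9, 2], [1, 10], [8, 4], [6, 8], [8, 6], [7, 8]], dtype=float)
        rep = icc_consistency(m)
        icc1, icck = _anova_oracle(m)
        assert rep.icc_c1 == pytest.approx(icc1, abs=1e-12)
        assert rep.icc_ck == pytest.approx(icck, abs=1e-12)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        m = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "rater": np.tile(np.arange(3), 20),
                "score": m.ravel(),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="rater",
                                   ratings="score").set_index("Type")
        rep = icc_consistency(m)
        assert rep.icc_c1 == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert rep.icc_ck == pytest.approx(table.loc["ICC(C,k)", "ICC"], abs=1e-9)
        ci = table.loc["ICC(C,1)", "CI95"]
        assert rep.ci_c1[0] == pytest.approx(ci[0], abs=0.01)
        assert rep.ci_c1[1] == pytest.approx(ci[1], abs=0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_average_measure_equals_spearman_brown_of_single(self, seed):
        rng = np.random.default_rng(seed)
        k = 2 + seed % 3
        m = rng.normal(size=(15, k)) + 2.0 * rng.normal(size=(15, 1))
        rep = icc_consistency(m)
        assert rep.icc_ck == pytest.approx(spearman_brown(rep.icc_c1, k), abs=1e-12)

    def test_missing_cells_rejected(self):
        m = np.ones((6, 2))
        m[0, 0] = np.nan
        with pytest.raises(ParameterError):
            icc_consistency(m)


class TestSpearmanBrown:
    def test_published_single_to_average_step(self):
        assert round(spearman_brown(0.554, 2), 3) == 0.713

    def test_fixed_points_and_hand_value(self):
        assert spearman_brown(1.0, 7) == pytest.approx(1.0)
        assert spearman_brown(0.5, 2) == pytest.approx(2.0 / 3.0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            spearman_brown(1.2, 2)
        with pytest.raises(DomainError):
            spearman_brown(-0.9, 12)


class TestBlandAltman:
    def test_identical_methods(self):
        a = np.arange(10.0)
        rep = bland_altman(a, a)
        assert rep.mean_diff == 0.0
        assert rep.loa_low == rep.loa_high == 0.0

    def test_constant_offset(self):
        a = np.arange(10.0)
        rep = bland_altman(a, a + 5.0)
        assert rep.mean_diff == pytest.approx(-5.0)
        assert rep.loa_high - rep.loa_low == pytest.approx(0.0)

    def test_gaussian_coverage_near_95_percent(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10_000)
        b = a + rng.normal(0.0, 0.5, size=10_000)
        rep = bland_altman(a, b)
        assert rep.fraction_within_loa == pytest.approx(0.95, abs=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])


def _two_blobs(rng, n0=80, n1=20, sep=10.0):
    pts = np.vstack([
        rng.normal(0.0, 0.5, size=(n0, 2)),
        rng.normal(sep, 0.5, size=(n1, 2)),
    ])
    return pts


class TestKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(5)
        rep = kmeans_silhouette(_two_blobs(rng), k=2, seed=0)
        assert rep.silhouette > 0.9
        assert rep.sizes == (80, 20)
        assert rep.fractions == pytest.approx((0.8, 0.2))

    def test_six_points_match_exhaustive_partition_search(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 10, size=(6, 2))

        def within_ss(assign):
            total = 0.0
            for g in (0, 1):
                sub = pts[np.array(assign) == g]
                if len(sub):
                    total += ((sub - sub.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            (a for a in itertools.product([0, 1], repeat=6) if len(set(a)) == 2),
            key=within_ss,
        )
        rep = kmeans_silhouette(pts, k=2, seed=0)
        # compare as partitions (label names are arbitrary)
        got = rep.labels == rep.labels[0]
        want = np.array(best) == best[0]
        assert np.array_equal(got, want)

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        pts = _two_blobs(rng, sep=3.0)
        a = kmeans_silhouette(pts, k=2, seed=42).labels
        b = kmeans_silhouette(pts, k=2, seed=42).labels
        assert np.array_equal(a, b)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ParameterError):
            kmeans_silhouette(np.zeros((2, 2)), k=2)


class TestBootstrapJaccard:
    def test_stable_clusters_score_near_one(self):
        rng = np.random.default_rng(8)
        pts = _two_blobs(rng)
        rep = kmeans_silhouette(pts, k=2, seed=0)
        jac = bootstrap_jaccard(pts, rep.labels, b=20, seed=0)
        assert all(j >= 0.99 for j in jac)

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(40, 2))
        jac = bootstrap_jaccard(pts, np.zeros(40, dtype=int), b=10, seed=0, k=2)
        assert all(0.0 <= j <= 1.0 for j in jac)

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        pts = _two_blobs(rng, sep=2.0)
        labels = kmeans_silhouette(pts, k=2, seed=1).labels
        assert bootstrap_jaccard(pts, labels, b=15, seed=3) == bootstrap_jaccard(
            pts, labels, b=15, seed=3
        )

    def test_invalid_resample_count_rejected(self):
        with pytest.raises(ParameterError):
            bootstrap_jaccard(np.zeros((10, 2)), np.zeros(10), b=0)


def _kw_oracle(values, sizes):
    """Tie-corrected Kruskal–Wallis H computed from first principles."""
    from scipy.stats import rankdata

    n = len(values)
    ranks = rankdata(values)
    h, start = 0.0, 0
    for size in sizes:
        h += ranks[start : start + size].sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


class TestPairingAnalysis:
    def test_four_contexts_have_three_degrees_of_freedom(self):
        rng = np.random.default_rng(11)
        counts = {c: rng.poisson(3, size=25) + rng.integers(0, 2, size=25)
                  for c in ("H-H", "M-M", "L-L", "H-L")}
        rep = pairing_analysis(counts)
        assert rep.df == 3
        assert set(rep.dunn_p_adjusted) == set(itertools.combinations(counts, 2))
        assert all(0.0 <= p <= 1.0 for p in rep.dunn_p_adjusted.values())

    def test_statistic_matches_rank_oracle(self):
        counts = {"A": [1.0, 2.0], "B": [3.0, 4.0]}
        rep = pairing_analysis(counts)
        assert rep.h_statistic == pytest.approx(_kw_oracle([1, 2, 3, 4], [2, 2]))

    def test_statistic_matches_oracle_with_ties_eight_obs(self):
        values = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 6.0, 9.0]
        counts = {"A": values[:2], "B": values[2:4], "C": values[4:6], "D": values[6:]}
        rep = pairing_analysis(counts)
        assert rep.h_statistic == pytest.approx(_kw_oracle(values, [2, 2, 2, 2]))

    def test_exhaustive_relabeling_null_distribution(self):
        """The observed H sits inside the permutation distribution over all
        4!/(2!2!) relabelings of {1,2} vs {3,4}, and matches the relabeling
        that reproduces the observed grouping."""
        values = np.array([1.0, 2.0, 3.0, 4.0])
        stats = []
        for pick in itertools.combinations(range(4), 2):
            g1 = values[list(pick)]
            g2 = values[[i for i in range(4) if i not in pick]]
            stats.append(pairing_analysis({"A": g1, "B": g2}).h_statistic)
        observed = pairing_analysis({"A": [1.0, 2.0], "B": [3.0, 4.0]}).h_statistic
        assert observed == pytest.approx(max(stats))
        assert any(s == pytest.approx(observed) for s in stats)

    def test_type_i_error_near_nominal_level(self):
        rejections = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            groups = {c: rng.normal(size=12) for c in ("A", "B", "C", "D")}
            rejections += pairing_analysis(groups).pvalue < 0.05
        rate = rejections / n_seeds
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / n_seeds) + 0.01

    def test_sparse_context_rejected_by_name(self):
        with pytest.raises(ParameterError, match="L-L"):
            pairing_analysis({"H-H": [1, 2, 3], "L-L": [0]})

    def test_summary_statistics_reported(self):
        rep = pairing_analysis({"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0]})
        assert rep.mean_per_context["A"] == pytest.approx(2.0)
        assert rep.sd_per_context["B"] == pytest.approx(1.0)
        assert rep.n_per_context == {"A": 3, "B": 3}


class TestGroupDifferenceDispatch:
    def test_identical_samples_give_null_statistic(self):
        a = np.arange(10.0)
        stat, p, detail = group_difference_test({"g1": a, "g2": a.copy()}, "parametric")
        assert detail == "welch-t"
        assert stat == pytest.approx(0.0)

    def test_nonparametric_four_groups_delegates_to_pairing(self):
        rng = np.random.default_rng(12)
        groups = {c: rng.normal(size=10) for c in "ABCD"}
        stat, p, detail = group_difference_test(groups, "nonparametric")
        assert hasattr(detail, "dunn_p_adjusted")
        assert detail.df == 3

    def test_power_against_one_sd_shift(self):
        rejections = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            groups = {"a": rng.normal(0, 1, 200), "b": rng.normal(1, 1, 200)}
            _, p, _ = group_difference_test(groups, "parametric")
            rejections += p < 0.05
        assert rejections >= 50 * 0.99
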