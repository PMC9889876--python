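"""Cohort statistics: CAP scoring, group tests, PCA, clustering, trends."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from actincap.cohort import (
    SampleMeta,
    aggregate_medians,
    benjamini_hochberg,
    cap_score,
    kmeans_phenotypes,
    load_hd_cohort,
    mann_whitney,
    pca_embed,
    severity_class,
    trend_fit,
)


class TestCapScore:
    def test_constants_recovered_from_reference_table(self):
        """Fit CAP = age*(CAG-L)/K over the 28-donor reference table.

        Independent oracle: linear least squares on the reference scores,
        CAP*K = age*CAG - age*L, solved for (1/K, L/K) -> expects L = 30,
        K = 6.49 to within printed precision.
        """
        df = load_hd_cohort()
        # cap = (1/K)*age*cag - (L/K)*age  => regress on [age*cag, age]
        X = np.column_stack([df.age_years * df.cag_repeats, df.age_years])
        coef, *_ = np.linalg.lstsq(X, df.cap_score_reference.to_numpy(), rcond=None)
        K = 1.0 / coef[0]
        L = -coef[1] * K
        assert K == pytest.approx(6.49, abs=1e-3)
        assert L == pytest.approx(30.0, abs=1e-2)

    def test_reference_cohort_reproduced_to_four_decimals(self):
        df = load_hd_cohort()
        computed = df.apply(lambda r: cap_score(r.age_years, r.cag_repeats), axis=1)
        # printed values carry 4-7 significant decimals; compare at 4
        assert np.allclose(computed, df.cap_score_reference, atol=5e-4)

    def test_spot_values(self):
        assert cap_score(57, 46) == pytest.approx(140.5239, abs=5e-5)
        assert cap_score(60, 45) == pytest.approx(138.6749, abs=5e-5)
        assert cap_score(23, 47) == pytest.approx(60.24653, abs=5e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cap_score(0, 45)
        with pytest.raises(ValueError):
            cap_score(40, 30)


class TestSeverity:
    def test_reference_labels_reproduced(self):
        df = load_hd_cohort()
        assert (df.severity == df.severity_reference).all()

    def test_subgroup_sizes(self):
        counts = load_hd_cohort().severity.value_counts()
        assert counts["Premanifest"] == 6
        assert counts["Mild"] == 10
        assert counts["Severe"] == 12

    @pytest.mark.parametrize(
        "cap,expected",
        [
            (140.5239, "Severe"),
            (114.0216, "Severe"),
            (114.0, "Mild"),
            (100.1541, "Mild"),
            (90.0, "Mild"),
            (84.12943, "Premanifest"),
        ],
    )
    def test_cutoffs(self, cap, expected):
        assert severity_class(cap) == expected

    def test_sample_meta_autocomputes(self):
        m = SampleMeta("GM02165", "HD", age=57, sex="M", cag_repeats=46)
        assert m.cap_score == pytest.approx(140.5239, abs=5e-5)
        assert m.severity == "Severe"
        with pytest.raises(ValueError):
            SampleMeta("x", "HD", age=40, sex="F", cag_repeats=20)


class TestAggregateMedians:
    def test_single_cell_wells_pass_through(self):
        cells = pd.DataFrame({"well": ["A", "B"], "f": [1.5, 2.5]})
        out = aggregate_medians(cells, by="well")
        assert out.loc["A", "f"] == 1.5 and out.loc["B", "f"] == 2.5

    def test_median_of_three(self):
        cells = pd.DataFrame({"well": ["A"] * 3, "f": [1, 2, 3]})
        assert aggregate_medians(cells, by="well").loc["A", "f"] == 2

    def test_missing_values_excluded(self):
        cells = pd.DataFrame({"well": ["A"] * 3, "f": [1.0, np.nan, 3.0]})
        assert aggregate_medians(cells, by="well").loc["A", "f"] == 2.0

    def test_missing_grouping_key_raises(self):
        with pytest.raises(KeyError):
            aggregate_medians(pd.DataFrame({"f": [1]}), by="well")


def brute_force_mw_p(a, b):
    """Exact two-sided p by enumerating all group-label assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y) + 0.5 * sum(
            1 for x in sample_a for y in sample_b if x == y
        )

    u_obs = u_stat(a, b)
    n1n2 = n1 * len(b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_textbook_separation(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "exact"

    def test_identical_groups_degenerate(self):
        res = mann_whitney([1, 1], [1, 1])
        assert res.degenerate and res.p_value == 1.0

    def test_symmetry(self):
        a, b = [1.0, 3.0, 7.0], [2.0, 9.0]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(b, a)
        assert r1.u_statistic + r2.u_statistic == len(a) * len(b)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_exact_mode_matches_permutation_enumeration(self):
        """Exact p equals brute-force enumeration for all n1, n2 <= 5."""
        rng = np.random.default_rng(12)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
                a, b = vals[:n1], vals[n1:]
                res = mann_whitney(a, b)
                assert res.p_value == pytest.approx(
                    brute_force_mw_p(a, b), abs=1e-12
                ), (n1, n2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_bh_adjustment_monotone(self):
        p = [0.001, 0.02, 0.04, 0.8]
        q = benjamini_hochberg(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()
        assert (q >= p).all() and (q <= 1).all()


class TestPcaEmbed:
    def test_collinear_features_load_on_single_component(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"f1": x, "f2": 3 * x + 1})
        _, ratios = pca_embed(table)
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance_of_variance_ratios(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3)) @ np.diag([3.0, 1.0, 0.3])
        table = pd.DataFrame(X, columns=list("abc"))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = pd.DataFrame(X @ q, columns=list("abc"))
        _, r1 = pca_embed(table, standardize=False)
        _, r2 = pca_embed(rotated, standardize=False)
        assert np.allclose(r1, r2, atol=1e-9)

    def test_shifted_populations_separate(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, size=(30, 4))
        b = rng.normal(2, 1, size=(30, 4))  # 2-SD mean shift on every feature
        table = pd.DataFrame(np.vstack([a, b]))
        scores, ratios = pca_embed(table)
        assert ratios[:2].sum() >= 0.5
        pc1 = scores["PC1"].to_numpy()
        between = abs(pc1[:30].mean() - pc1[30:].mean())
        within = max(pc1[:30].std(), pc1[30:].std())
        assert between > within

    def test_zero_variance_feature_dropped_with_warning(self):
        table = pd.DataFrame(
            {"f1": [1.0, 2, 3, 4], "f2": [1.0, 1, 1, 1], "f3": [2.0, 1, 4, 3]}
        )
        with pytest.warns(UserWarning):
            scores, _ = pca_embed(table)
        assert scores.shape[1] == 2

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            pca_embed(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))


class TestKmeansPhenotypes:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.5, size=(40, 3))
        b = rng.normal(4, 0.5, size=(40, 3))
        table = pd.DataFrame(np.vstack([a, b]), columns=list("xyz"))
        labels = pd.Series(["g0"] * 40 + ["g1"] * 40)
        return table, labels

    def test_two_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        table, truth = self._blobs()
        report = kmeans_phenotypes(table, k=2, seed=1, groups=truth)
        ari = adjusted_rand_score(truth, report.labels)
        assert ari >= 0.95

    def test_composition_rows_sum_to_hundred(self):
        table, truth = self._blobs(seed=3)
        report = kmeans_phenotypes(table, k=2, seed=1, groups=truth)
        assert np.allclose(report.composition.sum(axis=1), 100.0, atol=0.1)

    def test_k_one_single_cluster(self):
        table, truth = self._blobs()
        report = kmeans_phenotypes(table, k=1, seed=0, groups=truth)
        assert (report.labels == 0).all()
        assert np.allclose(report.composition.loc[0], [50.0, 50.0])

    def test_same_seed_same_labels(self):
        table, _ = self._blobs(seed=4)
        r1 = kmeans_phenotypes(table, k=3, seed=7)
        r2 = kmeans_phenotypes(table, k=3, seed=7)
        assert (r1.labels == r2.labels).all()

    def test_too_few_distinct_rows_rejected(self):
        table = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            kmeans_phenotypes(table, k=2)


class TestTrendFit:
    def test_exact_line_recovered(self):
        df = pd.DataFrame({"cap_score": [60.0, 90, 120, 150], "f": [121.0, 181, 241, 301]})
        fit = trend_fit(df, "f")
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)

    def test_normal_equations_hold(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"cap_score": rng.uniform(60, 150, 20), "f": rng.normal(size=20)}
        )
        fit = trend_fit(df, "f")
        resid = df["f"] - fit.predict(df["cap_score"])
        assert abs((resid * df["cap_score"]).sum()) < 1e-6
        assert abs(resid.sum()) < 1e-6

    def test_affine_equivariance_in_predictor(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"cap_score": rng.uniform(60, 150, 15), "f": rng.normal(size=15)}
        )
        fit = trend_fit(df, "f")
        shifted = df.assign(cap_score=df.cap_score + 40.0)
        fit2 = trend_fit(shifted, "f")
        assert fit2.slope == pytest.approx(fit.slope, rel=1e-9)
        assert fit2.intercept == pytest.approx(
            fit.intercept - 40.0 * fit.slope, rel=1e-6, abs=1e-9
        )

    def test_generative_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(7)
        caps = rng.uniform(60, 150, 28)
        true_slope = 0.002
        y = 0.6 + true_slope * caps + rng.normal(0, 0.02, len(caps))
        df = pd.DataFrame({"cap_score": caps, "f": y})
        fit = trend_fit(df, "f")
        # standard error of the OLS slope
        resid = y - fit.predict(caps)
        se = math.sqrt(
            (resid**2).sum() / (len(caps) - 2) / ((caps - caps.mean()) ** 2).sum()
        )
        assert abs(fit.slope - true_slope) < 2 * se

    def test_opposite_phenotype_directions(self):
        """Rising circularity and falling slope-SD give opposite-sign trends."""
        rng = np.random.default_rng(8)
        caps = np.sort(rng.uniform(60, 150, 28))
        df = pd.DataFrame(
            {
                "cap_score": caps,
                "circ": 0.5 + 0.003 * caps + rng.normal(0, 0.02, 28),
                "sstd": 5.0 - 0.02 * caps + rng.normal(0, 0.2, 28),
            }
        )
        assert trend_fit(df, "circ").slope > 0
        assert trend_fit(df, "sstd").slope < 0

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"cap_score": [100.0] * 5, "f": np.arange(5.0)})
        with pytest.raises(ValueError):
            trend_fit(df, "f")

    def test_envelope_and_subgroup_means(self):
        df = load_hd_cohort()
        rng = np.random.default_rng(9)
        df["f"] = 0.6 + 0.002 * df.cap_score + rng.normal(0, 0.01, len(df))
        df["f_max"] = df["f"] + 0.05
        df["f_min"] = df["f"] - 0.05
        fit = trend_fit(df, "f", max_col="f_max", min_col="f_min")
        assert fit.slope_max == pytest.approx(fit.slope, rel=1e-6)
        assert fit.intercept_max > fit.intercept > fit.intercept_min
        assert set(fit.subgroup_means.index) == {"Premanifest", "Mild", "Severe"}
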