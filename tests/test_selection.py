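import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from radstage.selection import (
    EmptyFeatureTableError,
    SelectionConfig,
    bhattacharyya_coefficient,
    clean_features,
    dedup_parameter_variants,
    long_to_wide,
    manhattan_data,
    match_count_by_pvalue,
    reduce_redundancy,
    screen_features,
    ttest_screen,
)


def wide_frame(data, prefix="f"):
    arr = np.asarray(data, float)
    return pd.DataFrame(
        arr,
        index=[f"case_{i:03d}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestClean:
    def test_inoperable_and_constant_dropped_with_reasons(self):
        w = wide_frame(np.ones((4, 3)))
        w["f0"] = [1.0, 2.0, 3.0, 4.0]
        w.loc["case_001", "f1"] = np.nan  # inoperable
        # f2 stays constant
        clean, drops = clean_features(w)
        assert list(clean.columns) == ["f0"]
        reasons = dict(zip(drops["feature_id"], drops["reason"]))
        assert reasons == {
            "f1": "inoperable_or_nonfinite",
            "f2": "zero_variance",
        }

    def test_clean_table_unchanged(self, rng):
        w = wide_frame(rng.normal(size=(5, 4)))
        clean, drops = clean_features(w)
        assert clean.equals(w)
        assert drops.empty

    def test_everything_dropped_is_an_error(self):
        w = wide_frame(np.ones((4, 2)))
        with pytest.raises(EmptyFeatureTableError):
            clean_features(w)


class TestRedundancy:
    def test_duplicate_column_pruned(self, rng):
        base = rng.normal(size=(10, 1))
        w = wide_frame(np.hstack([base, base, rng.normal(size=(10, 1))]))
        out = reduce_redundancy(w, r_threshold=0.95)
        assert out.shape[1] == 2

    def test_threshold_one_keeps_non_duplicates(self, rng):
        a = rng.normal(size=10)
        w = wide_frame(np.column_stack([a, a * 2 + 0.001 * rng.normal(size=10)]))
        out = reduce_redundancy(w, r_threshold=1.0)
        assert out.shape[1] == 2

    def test_planted_high_correlation_pruned(self, rng):
        a = rng.normal(size=40)
        b = a + 0.05 * rng.normal(size=40)  # r ~ 0.999
        w = wide_frame(np.column_stack([a, b, rng.normal(size=40)]))
        out = reduce_redundancy(w, r_threshold=0.95)
        assert out.shape[1] == 2


class TestTtestScreen:
    def test_identical_groups_t_zero(self, feature_labels):
        w = wide_frame(np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]]))
        labels = feature_labels(3, 3)
        res = ttest_screen(w, labels)
        assert res["t_statistic"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_null_flag_rate_near_alpha(self, rng, feature_labels):
        w = wide_frame(rng.standard_normal((28, 2000)))
        res = ttest_screen(w, feature_labels(14, 14))
        frac = (res["p_value"] < 0.05).mean()
        # binomial 99% CI around 0.05 at n = 2000
        assert 0.0375 <= frac <= 0.0625

    def test_planted_two_sd_shift_detected(self, rng, feature_labels):
        x = rng.standard_normal((28, 50))
        x[14:, :] += 2.0
        res = ttest_screen(wide_frame(x), feature_labels(14, 14))
        assert (res["p_value"] < 0.05).mean() >= 0.99

    def test_label_permutation_destroys_significance(self, rng, feature_labels):
        x = rng.standard_normal((28, 400))
        x[14:, :] += 2.0
        labels = feature_labels(14, 14)
        permuted = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        res = ttest_screen(wide_frame(x), permuted)
        assert (res["p_value"] < 0.05).mean() < 0.2


class TestBhattacharyya:
    def test_identical_distributions_bc_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert bhattacharyya_coefficient(a, a) == pytest.approx(1.0)

    def test_two_sigma_separation_closed_form(self, rng):
        # equal unit variances, means 0 and 2: BC = exp(-1/4 * 4 / 2) = e^-0.5
        a = rng.normal(0, 1, 200_000)
        b = rng.normal(2, 1, 200_000)
        assert bhattacharyya_coefficient(a, b) == pytest.approx(
            np.exp(-0.5), abs=0.01
        )

    def test_agrees_with_numerical_integration(self, rng):
        a = rng.normal(1.0, 1.5, 500)
        b = rng.normal(-0.5, 0.7, 500)
        closed = bhattacharyya_coefficient(a, b)
        m1, v1 = a.mean(), a.var(ddof=1)
        m2, v2 = b.mean(), b.var(ddof=1)

        def integrand(x):
            p = np.exp(-((x - m1) ** 2) / (2 * v1)) / np.sqrt(2 * np.pi * v1)
            q = np.exp(-((x - m2) ** 2) / (2 * v2)) / np.sqrt(2 * np.pi * v2)
            return np.sqrt(p * q)

        numeric, _ = integrate.quad(integrand, -30, 30, limit=200)
        assert abs(closed - numeric) < 1e-6

    def test_monotone_in_mean_separation(self, rng):
        a = rng.normal(0, 1, 5000)
        prev = 1.1
        for mu in (0.5, 1.0, 2.0, 4.0):
            bc = bhattacharyya_coefficient(a, a + mu)
            assert bc < prev
            prev = bc

    def test_zero_variance_inoperable(self):
        assert bhattacharyya_coefficient([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None


class TestManhattan:
    def _screen(self, pvals):
        return pd.DataFrame(
            {"p_value": pvals},
            index=pd.Index([f"fam|feat{i}|b1" for i in range(len(pvals))],
                           name="feature_id"),
        )

    def test_boundary_p_is_not_significant(self):
        data = manhattan_data(self._screen([0.05, 0.049, 1.0]))
        flagged = dict(zip(data["feature_id"], data["significant"]))
        assert flagged["fam|feat0|b1"] == False  # noqa: E712  (exact boundary)
        assert flagged["fam|feat1|b1"] == True  # noqa: E712
        assert float(data["threshold"].iloc[0]) == pytest.approx(-np.log10(0.05))

    def test_all_null_none_flagged(self):
        data = manhattan_data(self._screen([1.0] * 10))
        assert not data["significant"].any()

    def test_planted_third_flagged_about_third(self, rng, feature_labels):
        x = rng.standard_normal((28, 900))
        x[14:, :300] += 2.0  # a third of features carry real effects
        res = ttest_screen(wide_frame(x), feature_labels(14, 14))
        res.index.name = "feature_id"
        data = manhattan_data(res)
        assert 0.28 <= data["significant"].mean() <= 0.42


class TestDedupAndMatch:
    def _variants(self):
        idx = [
            "glcm|Contrast|b2|k1|a0",
            "glcm|Contrast|b3|k2|a45",
            "glcm|Contrast|b4|k1|a90",
            "glrlm|RunEntropy|b2|a0",
        ]
        return pd.DataFrame(
            {"p_value": [0.001, 0.002, 0.003, 0.004]},
            index=pd.Index(idx, name="feature_id"),
        )

    def test_one_record_per_base_feature(self):
        out = dedup_parameter_variants(self._variants(), seed=5)
        assert len(out) == 2
        bases = {i.split("|")[1] for i in out.index}
        assert bases == {"Contrast", "RunEntropy"}

    def test_seeded_determinism(self):
        a = dedup_parameter_variants(self._variants(), seed=5)
        b = dedup_parameter_variants(self._variants(), seed=5)
        assert list(a.index) == list(b.index)
        seen = {
            tuple(dedup_parameter_variants(self._variants(), seed=s).index)
            for s in range(12)
        }
        assert len(seen) > 1  # different seeds may differ

    def test_match_count_takes_smallest_p(self):
        df = pd.DataFrame(
            {"p_value": np.linspace(0.001, 0.03, 30)},
            index=pd.Index([f"f|x{i:02d}" for i in range(30)], name="feature_id"),
        )
        final, threshold = match_count_by_pvalue(df, 12)
        assert len(final) == 12
        assert threshold == pytest.approx(df["p_value"].iloc[11])

    def test_boundary_ties_break_lexicographically(self):
        df = pd.DataFrame(
            {"p_value": [0.01, 0.02, 0.02, 0.02]},
            index=pd.Index(["f|d", "f|c", "f|a", "f|b"], name="feature_id"),
        )
        final, _ = match_count_by_pvalue(df, 2)
        assert list(final.index) == ["f|d", "f|a"]

    def test_short_list_returned_whole_with_warning(self):
        df = self._variants()
        with pytest.warns(UserWarning):
            final, _ = match_count_by_pvalue(df, 10)
        assert len(final) == 4


class TestSelectionConfig:
    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(alpha_screen=0.01, final_p=0.05)
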