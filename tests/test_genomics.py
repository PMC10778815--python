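import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radstage.genomics import (
    intersect_degs,
    nb_wald_de,
    normalized_log_expression,
    signature_stage_test,
    significance_stars,
    size_factors,
    ssgsea_scores,
)
from radstage.synthetic import CohortConfig, generate_counts


def toy_counts():
    return pd.DataFrame(
        {
            "A": [10, 20, 30, 40, 50],
            "B": [20, 40, 60, 80, 100],
        },
        index=[f"g{i}" for i in range(5)],
    )


def de_labels(n0=10, n1=10):
    ids = [f"s{i:02d}" for i in range(n0 + n1)]
    return pd.Series(["intra"] * n0 + ["extra"] * n1, index=ids)


class TestSizeFactors:
    def test_doubled_sample_has_double_factor(self):
        s = size_factors(toy_counts())
        assert s["B"] / s["A"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        c = toy_counts()
        c["B"] = c["A"]
        s = size_factors(c)
        assert s["A"] == pytest.approx(s["B"])

    def test_gene_order_irrelevant(self, rng):
        c = toy_counts()
        shuffled = c.sample(frac=1.0, random_state=1)
        assert np.allclose(size_factors(c).to_numpy(), size_factors(shuffled).to_numpy())

    def test_fallback_warns_without_all_positive_gene(self):
        c = toy_counts()
        for g, col in enumerate([0, 1, 0, 1, 0]):  # a zero somewhere in every gene
            c.iat[g, col] = 0
        with pytest.warns(UserWarning):
            s = size_factors(c)
        assert (s > 0).all()


class TestNBWaldDE:
    def test_null_labels_give_uniformish_p(self):
        cfg = CohortConfig(n_intra=10, n_extra=10, n_de_genes=0, log2fc=0.0, seed=3)
        counts, _ = generate_counts(cfg, de_labels())
        res = nb_wald_de(counts, de_labels())
        p = res["p_value"].dropna()
        assert 0.02 < (p < 0.05).mean() < 0.08
        assert 0.45 < (p < 0.5).mean() < 0.55

    def test_planted_effect_recovered_with_direction(self):
        cfg = CohortConfig(n_intra=10, n_extra=10, n_de_genes=50, log2fc=2.0, seed=4)
        counts, truth = generate_counts(cfg, de_labels())
        res = nb_wald_de(counts, de_labels())
        planted = truth["planted_degs"]
        called = res[res["significant"]]
        recovered = set(called.index) & set(planted)
        assert len(recovered) / len(planted) >= 0.9
        for g in recovered:
            assert called.loc[g, "direction"] == planted[g]

    def test_direction_matches_fold_change_sign(self):
        cfg = CohortConfig(n_intra=10, n_extra=10, n_de_genes=50, log2fc=1.0, seed=5)
        counts, _ = generate_counts(cfg, de_labels())
        res = nb_wald_de(counts, de_labels())
        ok = res[~res["skipped"]]
        assert (
            (ok["direction"] == "up_in_high") == (ok["log2fc"] > 0)
        ).all()
        assert (ok["adj_p"] >= ok["p_value"] - 1e-12).all()

    def test_size_factor_absorbs_sample_scaling(self):
        cfg = CohortConfig(n_intra=10, n_extra=10, n_de_genes=9, log2fc=1.0, seed=6,
                           n_genes=200)
        counts, _ = generate_counts(cfg, de_labels())
        res1 = nb_wald_de(counts, de_labels())
        scaled = counts.copy()
        scaled["s00"] = scaled["s00"] * 2  # exact doubling of one library
        res2 = nb_wald_de(scaled, de_labels())
        assert np.allclose(
            res1["log2fc"].dropna(), res2["log2fc"].dropna(), atol=1e-10
        )

    def test_needs_two_samples_per_class(self):
        counts = toy_counts()
        labels = pd.Series(["intra", "extra"], index=["A", "B"])
        with pytest.raises(ValueError):
            nb_wald_de(counts, labels)


class TestIntersectDEGs:
    def _frame(self, sig_up, sig_down, others=()):
        rows = []
        for g in sig_up:
            rows.append({"gene": g, "adj_p": 0.001, "direction": "up_in_high", "skipped": False})
        for g in sig_down:
            rows.append({"gene": g, "adj_p": 0.001, "direction": "up_in_low", "skipped": False})
        for g in others:
            rows.append({"gene": g, "adj_p": 0.9, "direction": "up_in_high", "skipped": False})
        return pd.DataFrame(rows).set_index("gene")

    def test_common_up_intersection(self):
        r1 = self._frame(["A", "B", "C"], [])
        r2 = self._frame(["B", "C", "D"], [])
        up, down = intersect_degs([r1, r2])
        assert up == ["B", "C"]
        assert down == []

    def test_direction_conflict_excluded(self):
        r1 = self._frame(["X"], [])
        r2 = self._frame([], ["X"])
        up, down = intersect_degs([r1, r2])
        assert up == [] and down == []

    def test_commutative_and_associative(self):
        r1 = self._frame(["A", "B"], ["Z"])
        r2 = self._frame(["B", "C"], ["Z"])
        r3 = self._frame(["B"], ["Z", "Y"])
        forward = intersect_degs([r1, r2, r3])
        backward = intersect_degs([r3, r1, r2])
        assert forward == backward == (["B"], ["Z"])


class TestSsgsea:
    def test_hand_enumerated_top_singleton(self):
        expr = pd.DataFrame({"s1": [3.0, 2.0, 1.0]}, index=["g1", "g2", "g3"])
        s = ssgsea_scores(expr, {"S": ["g1"]}, alpha_weight=0.0)
        assert s.loc["S", "s1"] == pytest.approx(1.5)

    def test_bottom_singleton_scores_lower(self):
        expr = pd.DataFrame({"s1": [3.0, 2.0, 1.0]}, index=["g1", "g2", "g3"])
        s = ssgsea_scores(expr, {"top": ["g1"], "bottom": ["g3"]}, alpha_weight=0.25)
        assert s.loc["bottom", "s1"] < s.loc["top", "s1"]

    def test_monotone_transform_invariance(self, rng):
        expr = pd.DataFrame(
            rng.gamma(2.0, 50.0, size=(40, 6)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        sets = {"S1": [f"g{i}" for i in range(5)], "S2": [f"g{i}" for i in range(20, 30)]}
        s1 = ssgsea_scores(expr, sets)
        s2 = ssgsea_scores(np.log1p(expr), sets)  # monotone per-sample transform
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_absent_set_flagged_missing(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        s = ssgsea_scores(expr, {"gone": ["nope"]})
        assert np.isnan(s.loc["gone", "s1"])

    def test_planted_up_set_scores_higher_in_extra(self):
        cfg = CohortConfig(n_intra=8, n_extra=8, n_de_genes=20, log2fc=2.0,
                           n_genes=500, seed=9)
        labels = pd.Series(["intra"] * 8 + ["extra"] * 8,
                           index=[f"s{i:02d}" for i in range(16)])
        counts, truth = generate_counts(cfg, labels)
        up_high = [g for g, d in truth["planted_degs"].items() if d == "up_in_high"]
        s = ssgsea_scores(normalized_log_expression(counts), {"UP": up_high})
        extra_mean = s.loc["UP", labels == "extra"].mean()
        intra_mean = s.loc["UP", labels == "intra"].mean()
        assert extra_mean > intra_mean


class TestStageTest:
    def test_two_group_agrees_with_rank_sum(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(3, 12)),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(12)],
        )
        labels = pd.Series(["g1"] * 6 + ["g2"] * 6, index=scores.columns)
        res = signature_stage_test(scores, labels)
        for sig in scores.index:
            x = scores.loc[sig, labels == "g1"]
            y = scores.loc[sig, labels == "g2"]
            h, p_kw = stats.kruskal(x, y)
            assert res.loc[sig, "p_value"] == pytest.approx(p_kw)

    def test_monotone_shifted_groups_significant(self, rng):
        base = rng.normal(size=(1, 30))
        shift = np.repeat([0.0, 2.0, 4.0], 10)[None, :]
        scores = pd.DataFrame(base + shift, index=["sig"],
                              columns=[f"s{i}" for i in range(30)])
        labels = pd.Series(np.repeat(["a", "b", "c"], 10), index=scores.columns)
        res = signature_stage_test(scores, labels)
        assert res.loc["sig", "p_value"] < 0.01

    def test_star_buckets(self):
        assert significance_stars(0.3) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.007) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.00005) == "****"
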