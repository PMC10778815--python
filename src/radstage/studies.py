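"""Reproducible study harnesses: calibration, recovery and comparison runs.

Each function regenerates its inputs from scratch under an explicit seed and
measures one quantity the pipeline is accountable for: the feature-family
census, the per-category RFE cap, null false-positive calibration of the
screens, planted-effect recovery, and the integrated-vs-single-omics model
comparison.  The problem sizes are the package's study conditions (28-case
training cohorts, 12-case external test cohorts, 2000-gene count matrices,
10 + 10 differential-expression designs) and are fixed here rather than in
the callers so that tests and reporting scripts measure the same thing.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .genomics import (
    nb_wald_de,
    normalized_log_expression,
    signature_stage_test,
    ssgsea_scores,
)
from .radiomics import ParamGrid, extract_all, extract_cohort
from .selection import (
    bhattacharyya_coefficient,
    clean_features,
    dedup_parameter_variants,
    long_to_wide,
    match_count_by_pvalue,
    screen_features,
    ttest_screen,
)
from .staging import StagingConfig, evaluate, train_rfe
from .synthetic import CohortConfig, generate_cohort, generate_counts

# single radiomic parameter triple used where the sweep itself is not under
# study; bin exponent 3 (8 gray levels), kernel 1, axial 0/90 degrees
FAST_GRID = ParamGrid(bin_exponents=(3,), kernels=(1, 2), angles=(0, 90))


# ---------------------------------------------------------------------------
# structural census


def feature_census(seed: int = 0) -> dict[str, int]:
    """Per-family feature counts from an actual single-triple extraction."""
    cfg = CohortConfig(n_intra=2, n_extra=2, seed=seed)
    cohort = generate_cohort(replace(cfg, n_genes=100, n_de_genes=0, log2fc=0.0))
    grid = ParamGrid(bin_exponents=(3,), kernels=(1,), angles=(0,))
    table = extract_all(cohort.volumes[0], cohort.masks[0], grid=grid)
    counts = table.groupby("family").size().to_dict()
    counts["total_single_combination"] = len(table)
    counts["full_grid_census"] = ParamGrid().census()
    return {k: int(v) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# RFE cap


def _gaussian_feature_block(
    rng: np.random.Generator,
    n_cases: int,
    n_features: int,
    n_informative: int,
    shift: float,
    y: np.ndarray,
    prefix: str,
) -> pd.DataFrame:
    x = rng.standard_normal((n_cases, n_features))
    x[:, :n_informative] += shift * y[:, None]
    cols = [f"{prefix}_{i:02d}" for i in range(n_features)]
    return pd.DataFrame(x, columns=cols, index=[f"case_{i:03d}" for i in range(n_cases)])


def rfe_cap_study(
    n_runs: int = 50,
    seed: int = 0,
    n_per_category: int = 10,
    cap: int = 8,
    family: str = "NB",
) -> dict:
    """Offer > cap strongly separating features per category across seeded
    runs and record the largest per-category count any fitted model retains.
    """
    max_gen = max_rad = 0
    for r in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77, r]))
        n_cases = 28
        y = np.array([0] * 18 + [1] * 10)
        g = _gaussian_feature_block(rng, n_cases, n_per_category, n_per_category, 1.5, y, "g")
        rd = _gaussian_feature_block(rng, n_cases, n_per_category, n_per_category, 1.5, y, "r")
        labels = pd.Series(np.where(y == 1, "extra", "intra"), index=g.index)
        cfg = StagingConfig(family=family, cap=cap, cv_folds=3, seed=seed + r)
        res = train_rfe(g, rd, labels, family, cfg)
        max_gen = max(max_gen, len(res.selected_genomic))
        max_rad = max(max_rad, len(res.selected_radiomic))
    return {
        "n_runs": n_runs,
        "offered_per_category": n_per_category,
        "cap": cap,
        "max_selected_genomic": max_gen,
        "max_selected_radiomic": max_rad,
        "max_selected_per_category": max(max_gen, max_rad),
    }


# ---------------------------------------------------------------------------
# null calibration


def null_screen_study(
    n_features: int = 2000, n_per_class: int = 14, seed: int = 0
) -> dict:
    """Fraction of independent null features the t-test screen flags at 0.05."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    n_cases = 2 * n_per_class
    x = rng.standard_normal((n_cases, n_features))
    wide = pd.DataFrame(
        x,
        index=[f"case_{i:03d}" for i in range(n_cases)],
        columns=[f"f{i:04d}" for i in range(n_features)],
    )
    labels = pd.Series(
        ["intra"] * n_per_class + ["extra"] * n_per_class, index=wide.index
    )
    res = ttest_screen(wide, labels)
    frac = float((res["p_value"] < 0.05).mean())
    return {"n_features": n_features, "flagged_fraction": frac}


def null_de_study(seed: int = 0) -> dict:
    """NB Wald p-value calibration under a zero-effect count model."""
    cfg = CohortConfig(
        n_intra=10, n_extra=10, n_de_genes=0, log2fc=0.0, seed=seed
    )
    labels = pd.Series(
        ["intra"] * 10 + ["extra"] * 10, index=[f"s{i:02d}" for i in range(20)]
    )
    counts, _ = generate_counts(cfg, labels)
    res = nb_wald_de(counts, labels)
    p = res["p_value"].dropna().to_numpy()
    ks = stats.kstest(p, "uniform")
    return {
        "n_genes": int(p.size),
        "fraction_below_05": float((p < 0.05).mean()),
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
    }


# ---------------------------------------------------------------------------
# planted-effect recovery


def deg_recovery_study(seed: int = 0) -> dict:
    """Recovery of 50 planted DEGs (|log2fc| = 2) in a 10 + 10 design."""
    cfg = CohortConfig(n_intra=10, n_extra=10, n_de_genes=50, log2fc=2.0, seed=seed)
    labels = pd.Series(
        ["intra"] * 10 + ["extra"] * 10, index=[f"s{i:02d}" for i in range(20)]
    )
    counts, truth = generate_counts(cfg, labels)
    res = nb_wald_de(counts, labels, alpha=0.05)
    planted = truth["planted_degs"]
    called = set(res.index[res["significant"]])
    hits = called & set(planted)
    direction_ok = all(
        res.loc[g, "direction"] == planted[g] for g in hits
    )
    recovery = len(hits) / len(planted)
    fdr = len(called - set(planted)) / max(1, len(called))
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "recovery": float(recovery),
        "observed_fdr": float(fdr),
        "directions_consistent": bool(direction_ok),
    }


def texture_detection_study(seed: int = 0, texture_effect: float = 1.0) -> dict:
    """Two-sample t on GLCM Contrast for a 10 + 10 textured cohort."""
    cfg = CohortConfig(
        n_intra=10, n_extra=10, texture_effect=texture_effect,
        n_genes=100, n_de_genes=0, log2fc=0.0, seed=seed,
    )
    cohort = generate_cohort(cfg)
    grid = ParamGrid(bin_exponents=(3,), kernels=(1,), angles=(0,))
    table = extract_cohort(cohort.volumes, cohort.masks, grid=grid)
    sub = table[(table["family"] == "glcm") & (table["feature"] == "Contrast")]
    vals = sub.set_index("case_id")["value"]
    a = vals[cohort.labels == "intra"]
    b = vals[cohort.labels == "extra"]
    t, p = stats.ttest_ind(a, b)
    return {"t_statistic": float(t), "p_value": float(p)}


# ---------------------------------------------------------------------------
# oracle agreement


def bhattacharyya_integration_error(seed: int = 0, n_pairs: int = 20) -> float:
    """Max |closed form - numerical integral of sqrt(p q)| over Gaussian pairs."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    worst = 0.0
    for _ in range(n_pairs):
        mu1, mu2 = rng.normal(0, 2, size=2)
        s1, s2 = rng.uniform(0.5, 3.0, size=2)
        a = rng.normal(mu1, s1, size=200_000)
        b = rng.normal(mu2, s2, size=200_000)
        closed = bhattacharyya_coefficient(a, b)
        # integrate with the *sample* moments so both routes see the same
        # distributions
        m1, v1 = a.mean(), a.var(ddof=1)
        m2, v2 = b.mean(), b.var(ddof=1)

        def integrand(x):
            p = np.exp(-((x - m1) ** 2) / (2 * v1)) / np.sqrt(2 * np.pi * v1)
            q = np.exp(-((x - m2) ** 2) / (2 * v2)) / np.sqrt(2 * np.pi * v2)
            return np.sqrt(p * q)

        lo = min(m1, m2) - 10 * max(np.sqrt(v1), np.sqrt(v2))
        hi = max(m1, m2) + 10 * max(np.sqrt(v1), np.sqrt(v2))
        numeric, _ = integrate.quad(integrand, lo, hi, limit=200)
        worst = max(worst, abs(closed - numeric))
    return float(worst)


# ---------------------------------------------------------------------------
# integrated vs single-omics comparison


# study conditions of the bimodal cohort: both modalities informative but
# each muted in half of the extra-vesical cases (complementary phenotypes)
BIMODAL_TEXTURE_EFFECT = 0.6
BIMODAL_LOG2FC = 1.0
BIMODAL_HETEROGENEITY = 0.8


def _comparison_one_seed(seed: int, family: str = "NB") -> dict[str, float]:
    train_cfg = CohortConfig(
        n_intra=18,
        n_extra=10,
        texture_effect=BIMODAL_TEXTURE_EFFECT,
        log2fc=BIMODAL_LOG2FC,
        heterogeneity=BIMODAL_HETEROGENEITY,
        seed=seed,
    )
    test_cfg = replace(train_cfg, n_intra=6, n_extra=6, seed=seed + 100_000)
    train = generate_cohort(train_cfg)
    test = generate_cohort(test_cfg)

    sets = train.truth["gene_sets"]
    sc_train = ssgsea_scores(normalized_log_expression(train.counts), sets)
    sc_test = ssgsea_scores(normalized_log_expression(test.counts), sets)
    stage = signature_stage_test(sc_train, train.labels)
    sig = list(stage.index[stage["p_value"] < 0.05])
    if not sig:
        sig = list(stage.sort_values("p_value").index[:2])

    feats_train = extract_cohort(train.volumes, train.masks, grid=FAST_GRID)
    feats_test = extract_cohort(test.volumes, test.masks, grid=FAST_GRID)
    clean, _ = clean_features(long_to_wide(feats_train))
    screening = screen_features(clean, train.labels)
    significant = screening[screening["significant_05"]]
    if significant.empty:
        significant = screening.sort_values("p_value").head(4)
    deduped = dedup_parameter_variants(significant, seed=seed)
    final, _ = match_count_by_pvalue(deduped, max(1, len(sig)))

    g_train, g_test = sc_train.loc[sig].T, sc_test.loc[sig].T
    r_train = clean[list(final.index)]
    r_test = long_to_wide(feats_test).reindex(columns=list(final.index))

    cfg = StagingConfig(family=family, seed=seed, cv_folds=5)
    truth = test.labels.to_numpy()
    res = train_rfe(g_train, r_train, train.labels, family, cfg)
    acc_rgs = evaluate(
        res.predict(genomic=g_test, radiomic=r_test).to_numpy(), truth
    ).accuracy
    res_g = train_rfe(g_train, None, train.labels, family, cfg)
    acc_gs = evaluate(res_g.predict(genomic=g_test).to_numpy(), truth).accuracy
    res_r = train_rfe(None, r_train, train.labels, family, cfg)
    acc_rs = evaluate(res_r.predict(radiomic=r_test).to_numpy(), truth).accuracy
    return {"RGs": acc_rgs, "Gs": acc_gs, "Rs": acc_rs}


def model_comparison_study(
    n_seeds: int = 20, seed: int = 0, family: str = "NB"
) -> dict:
    """Mean external-validation accuracy of the integrated model vs the
    genomic-only and radiomic-only baselines on bimodal cohorts (28 train,
    12 test) across seeds."""
    rows = [_comparison_one_seed(seed * 1009 + 13 * k, family) for k in range(n_seeds)]
    df = pd.DataFrame(rows)
    means = df.mean()
    return {
        "n_seeds": n_seeds,
        "integrated_mean_accuracy": float(means["RGs"]),
        "genomic_only_mean_accuracy": float(means["Gs"]),
        "radiomic_only_mean_accuracy": float(means["Rs"]),
        "delta_vs_genomic_pp": float(100 * (means["RGs"] - means["Gs"])),
        "delta_vs_radiomic_pp": float(100 * (means["RGs"] - means["Rs"])),
        "per_seed": df.to_dict(orient="records"),
    }
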