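"""Radiomic feature cleaning, redundancy pruning and statistical screening.

The screen follows a three-step recipe: (1) drop features with inoperable or
non-finite values and zero variance, (2) prune near-duplicate features by
greedy correlation filtering, (3) score the survivors with a two-sample
Student's t-test and the Gaussian Bhattacharyya coefficient.  The screened
set is then reduced in two phases: one representative per base feature among
its parameter variants (chosen at random under the run seed), then the
k smallest-p features so that the radiomic set matches the size of the
genomic predictor set.  No multiple-testing correction is applied to the
radiomic screen; thresholds use strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .radiomics.extract import feature_id


class EmptyFeatureTableError(ValueError):
    """Raised when cleaning removes every feature."""


@dataclass
class SelectionConfig:
    alpha_screen: float = 0.05
    final_p: float = 0.01
    redundancy_r_threshold: float = 0.95
    k_target: int = 8
    seed: int = 0
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.final_p <= self.alpha_screen < 1:
            raise ValueError(
                f"need 0 < final_p <= alpha_screen < 1, got "
                f"{self.final_p}, {self.alpha_screen}"
            )


def long_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format feature table to cases x feature-id wide format.

    Inoperable records become NaN so that cleaning can drop them.
    """
    t = table.copy()
    t["feature_id"] = t.apply(feature_id, axis=1)
    t.loc[~t["operable"].astype(bool), "value"] = np.nan
    wide = t.pivot_table(
        index="case_id", columns="feature_id", values="value", dropna=False
    )
    return wide.sort_index(axis=0).sort_index(axis=1)


def clean_features(wide: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop features with any non-finite value or zero variance.

    Returns (clean wide table, drop log with columns feature_id / reason).
    """
    drops = []
    keep = []
    for col in wide.columns:
        v = wide[col].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(v)):
            drops.append({"feature_id": col, "reason": "inoperable_or_nonfinite"})
        elif np.ptp(v) == 0:
            drops.append({"feature_id": col, "reason": "zero_variance"})
        else:
            keep.append(col)
    if not keep:
        raise EmptyFeatureTableError("cleaning removed every feature")
    return wide[keep], pd.DataFrame(drops, columns=["feature_id", "reason"])


def ttest_screen(
    wide: pd.DataFrame, labels: pd.Series, welch: bool = False
) -> pd.DataFrame:
    """Two-sample t-test per feature (pooled-variance Student by default).

    Returns a DataFrame indexed by feature_id with t_statistic and p_value;
    zero-pooled-variance features get NaN (flagged inoperable downstream).
    """
    labels = labels.reindex(wide.index)
    if labels.isna().any():
        raise ValueError("labels missing for some cases")
    a = wide[labels == "extra"].to_numpy(dtype=np.float64)
    b = wide[labels == "intra"].to_numpy(dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 cases per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    return pd.DataFrame(
        {"t_statistic": t, "p_value": p}, index=wide.columns.rename("feature_id")
    )


def bhattacharyya_coefficient(values_a, values_b) -> float | None:
    """Gaussian-closed-form Bhattacharyya coefficient BC = exp(-D_B).

    D_B = (mu_a - mu_b)^2 / (4 (va + vb)) + 0.5 * ln(((va + vb)/2) / (sa*sb)).
    1 for identical distributions, -> 0 as the classes separate.  Returns
    None (inoperable) when either group has zero variance.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        return None
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 or vb <= 0:
        return None
    d = (a.mean() - b.mean()) ** 2 / (4.0 * (va + vb)) + 0.5 * np.log(
        ((va + vb) / 2.0) / np.sqrt(va * vb)
    )
    return float(np.exp(-d))


def screen_features(
    wide: pd.DataFrame, labels: pd.Series, config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Full screen: t-test plus Bhattacharyya coefficient per feature.

    Returns a DataFrame indexed by feature_id with columns t_statistic,
    p_value, bhattacharyya_coefficient, significant_05 (p < alpha_screen) and
    significant_final (p < final_p), all using strict inequality.
    """
    config = config or SelectionConfig()
    labels = labels.reindex(wide.index)
    res = ttest_screen(wide, labels, welch=config.welch)
    a = wide[labels == "extra"]
    b = wide[labels == "intra"]
    res["bhattacharyya_coefficient"] = [
        bhattacharyya_coefficient(a[c], b[c]) for c in wide.columns
    ]
    res["significant_05"] = res["p_value"] < config.alpha_screen
    res["significant_final"] = res["p_value"] < config.final_p
    return res


def reduce_redundancy(
    wide: pd.DataFrame,
    r_threshold: float = 0.95,
    order_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Greedy correlation pruning: walk features in priority order and drop
    any feature with |Pearson r| > r_threshold against an already-retained
    one.  ``order_by`` gives the priority (ascending, e.g. screening p);
    default is variance-descending.
    """
    if order_by is not None:
        cols = list(order_by.reindex(wide.columns).sort_values(kind="stable").index)
    else:
        var = wide.var(ddof=1)
        cols = list(var.sort_values(ascending=False, kind="stable").index)
    corr = wide[cols].corr().abs()
    kept: list[str] = []
    for col in cols:
        if all(corr.loc[col, k] <= r_threshold or np.isnan(corr.loc[col, k]) for k in kept):
            kept.append(col)
    return wide[[c for c in wide.columns if c in set(kept)]]


def manhattan_data(screening: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready table: feature index, -log10 p, significance flag.

    Deterministic ordering by feature_id; p == alpha sits on the threshold
    line and is flagged non-significant (strict inequality convention).
    """
    df = screening.sort_index().reset_index()
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_value"])
    df["significant"] = df["p_value"] < alpha
    df["feature_index"] = np.arange(len(df))
    df["threshold"] = -np.log10(alpha)
    return df[
        ["feature_index", "feature_id", "p_value", "neg_log10_p", "significant", "threshold"]
    ]


def plot_manhattan(data: pd.DataFrame, path: str) -> None:
    """Render the screening Manhattan plot to ``path`` (optional figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    colors = np.where(data["significant"], "#c0392b", "#7f8c8d")
    ax.scatter(data["feature_index"], data["neg_log10_p"], s=6, c=colors)
    ax.axhline(float(data["threshold"].iloc[0]), color="red", lw=1)
    ax.set_xlabel("feature index")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _base_name(feature_id_str: str) -> str:
    parts = feature_id_str.split("|")
    return "|".join(parts[:2])  # family|feature


def dedup_parameter_variants(
    significant: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Keep one record per (family, base feature), chosen uniformly at random
    among its parameter variants under ``seed``; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    df = significant.sort_index()
    bases = df.index.to_series().map(_base_name)
    kept_rows = []
    for _, group in df.groupby(bases, sort=True):
        kept_rows.append(group.index[rng.integers(len(group))])
    return df.loc[sorted(kept_rows)]


def match_count_by_pvalue(
    deduped: pd.DataFrame, k_target: int
) -> tuple[pd.DataFrame, float]:
    """The k_target smallest-p features and the implied p threshold.

    Boundary ties break by feature-id lexicographic order.  When fewer than
    k_target features are available the whole list is returned with a
    warning.
    """
    if k_target < 1:
        raise ValueError("k_target must be >= 1")
    ordered = deduped.assign(_fid=deduped.index).sort_values(
        ["p_value", "_fid"], kind="stable"
    ).drop(columns="_fid")
    if len(ordered) < k_target:
        import warnings

        warnings.warn(
            f"only {len(ordered)} features available for k_target={k_target}",
            stacklevel=2,
        )
        final = ordered
    else:
        final = ordered.iloc[:k_target]
    threshold = float(final["p_value"].max()) if len(final) else float("nan")
    return final, threshold
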