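"""Genomic analysis: NB Wald differential expression, DEG intersection,
single-sample gene set enrichment (ssGSEA) and stage-trend testing.

The differential test is a deliberately simplified negative-binomial Wald
test: median-of-ratios size factors, per-gene method-of-moments dispersion
(no shrinkage, no outlier replacement, no independent filtering), a Wald
statistic on the log2 fold change referred to a t distribution with pooled
degrees of freedom, and Benjamini-Hochberg adjustment across genes.  The positive class throughout
is the extra-vesical (high-stage) group, so ``log2fc > 0`` means higher
expression in high-stage samples (direction ``up_in_high``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STAGE_STARS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Bucket a p-value into the conventional star annotation."""
    for cut, stars in STAGE_STARS:
        if p < cut:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (genes x samples input).

    s_j = median over all-positive genes g of K_gj / geometric-mean_g(K_g.).
    Falls back, with a warning, to the genes positive in sample j when no
    gene is positive in every sample.
    """
    k = counts.to_numpy(dtype=np.float64)
    all_pos = (k > 0).all(axis=1)
    factors = np.empty(k.shape[1])
    if all_pos.any():
        sub = k[all_pos]
        log_geo = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene has positive counts in every sample; "
            "using per-sample positive-gene medians",
            stacklevel=2,
        )
        with np.errstate(divide="ignore"):
            logk = np.where(k > 0, np.log(k), np.nan)
        log_geo = np.nanmean(logk, axis=1)
        for j in range(k.shape[1]):
            r = logk[:, j] - log_geo
            factors[j] = np.exp(np.nanmedian(r))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_log_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-normalized, log1p-transformed counts (ssGSEA input)."""
    s = size_factors(counts)
    return np.log1p(counts / s)


# ---------------------------------------------------------------------------
# differential expression


def nb_wald_de(
    counts: pd.DataFrame, labels: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene NB Wald test of extra- vs intra-vesical expression.

    Parameters
    ----------
    counts : DataFrame, genes x samples, non-negative integers.
    labels : Series indexed by sample id with values "intra"/"extra".
    alpha : BH-FDR significance level recorded in the ``significant`` column.

    Returns a DataFrame indexed by gene with columns base_mean, log2fc,
    dispersion, se_log2fc, wald_stat, p_value, adj_p, direction, significant,
    and ``skipped`` for genes with zero counts in both groups.
    """
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    grp = labels.to_numpy()
    for cls in ("intra", "extra"):
        if (grp == cls).sum() < 2:
            raise ValueError(f"need >= 2 samples per class, {cls} has {(grp == cls).sum()}")

    s = size_factors(counts).to_numpy()
    y = counts.to_numpy(dtype=np.float64) / s  # normalized counts
    hi = grp == "extra"
    lo = ~hi
    n1, n0 = int(hi.sum()), int(lo.sum())

    m1 = y[:, hi].mean(axis=1)
    m0 = y[:, lo].mean(axis=1)
    v1 = y[:, hi].var(axis=1, ddof=1)
    v0 = y[:, lo].var(axis=1, ddof=1)

    # method-of-moments dispersion from within-group variance:
    # Var(K/s) ~ mu * E[1/s] + alpha_g * mu^2
    inv_s1 = (1.0 / s[hi]).mean()
    inv_s0 = (1.0 / s[lo]).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, (v1 - m1 * inv_s1) / m1**2, np.nan)
        a0 = np.where(m0 > 0, (v0 - m0 * inv_s0) / m0**2, np.nan)
    disp = np.nanmean(np.stack([a1, a0]), axis=0)
    disp = np.clip(np.nan_to_num(disp, nan=0.0), 0.0, None)

    skipped = (m1 == 0) & (m0 == 0)
    pc = 0.5  # pseudocount on the normalized scale for zero-mean groups
    m1p = np.where(m1 > 0, m1, pc)
    m0p = np.where(m0 > 0, m0, pc)
    log2fc = np.log2(m1p / m0p)

    # delta-method variance of log(mean) under NB sampling
    var_ln1 = (1.0 / n1) * (inv_s1 / m1p + disp)
    var_ln0 = (1.0 / n0) * (inv_s0 / m0p + disp)
    se_log2 = np.sqrt(var_ln1 + var_ln0) / np.log(2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se_log2 > 0, log2fc / se_log2, 0.0)
    # t reference with pooled df: the SE is estimated from n1 + n2 samples,
    # and a normal reference is visibly anticonservative at cohort sizes
    # like 10 + 10
    p = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n0 - 2)
    p = np.where(skipped, np.nan, p)

    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]

    res = pd.DataFrame(
        {
            "base_mean": y.mean(axis=1),
            "log2fc": np.where(skipped, np.nan, log2fc),
            "dispersion": disp,
            "se_log2fc": se_log2,
            "wald_stat": np.where(skipped, np.nan, wald),
            "p_value": p,
            "adj_p": adj,
            "direction": np.where(log2fc > 0, "up_in_high", "up_in_low"),
            "significant": (adj < alpha) & ok,
            "skipped": skipped,
        },
        index=counts.index,
    )
    res.loc[skipped, "direction"] = ""
    return res


def intersect_degs(
    results: list[pd.DataFrame], alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Genes significant in every dataset with a consistent direction.

    Returns (up_in_high, up_in_low) gene lists, each sorted; commutative and
    associative in the datasets.
    """
    if len(results) < 2:
        raise ValueError("need results from at least two datasets")
    ups, downs = [], []
    for res in results:
        sig = res[(res["adj_p"] < alpha) & ~res["skipped"]]
        ups.append(set(sig.index[sig["direction"] == "up_in_high"]))
        downs.append(set(sig.index[sig["direction"] == "up_in_low"]))
    up_common = set.intersection(*ups)
    down_common = set.intersection(*downs)
    return sorted(up_common), sorted(down_common)


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea_scores(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha_weight: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample enrichment scores (gene sets x samples).

    Per sample, genes are ranked by expression descending (average ranks on
    ties).  With in-set weighted rank CDF P_in and out-of-set uniform CDF
    P_out, the score is sum_i [P_in(i) - P_out(i)] over all gene positions.
    A set with no member present in ``expr`` scores NaN.  ``normalize``
    rescales all scores by the overall score range (GSVA-style), off by
    default.
    """
    genes = expr.index
    n = len(genes)
    memberships = {}
    for name, members in gene_sets.items():
        present = np.asarray(genes.isin(set(members)))
        memberships[name] = present if present.any() else None
        if present.all():
            raise ValueError(f"gene set {name!r} covers every gene in expr")

    scores = pd.DataFrame(
        np.nan, index=list(gene_sets), columns=expr.columns, dtype=np.float64
    )
    x = expr.to_numpy(dtype=np.float64)
    for j, sample in enumerate(expr.columns):
        # average ranks, descending: top gene has rank n
        r = stats.rankdata(x[:, j], method="average")
        order = np.argsort(-r, kind="stable")  # descending rank positions
        ranked_r = r[order]
        w = ranked_r**alpha_weight
        for name, present in memberships.items():
            if present is None:
                continue
            in_set = present[order]
            n_in = int(in_set.sum())
            w_in = np.where(in_set, w, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_set) / (n - n_in)
            scores.loc[name, sample] = float(np.sum(p_in - p_out))
    if normalize:
        rng_all = np.nanmax(scores.to_numpy()) - np.nanmin(scores.to_numpy())
        if rng_all > 0:
            scores = scores / rng_all
    return scores


def signature_stage_test(
    scores: pd.DataFrame, group_labels: pd.Series
) -> pd.DataFrame:
    """Kruskal-Wallis test of each signature's scores across >= 2 groups.

    Returns a DataFrame indexed by signature with H statistic, two-sided p,
    and star buckets at 0.05 / 0.01 / 0.001 / 0.0001.
    """
    group_labels = group_labels.reindex(scores.columns)
    if group_labels.isna().any():
        raise ValueError("group labels missing for some samples")
    groups = sorted(group_labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    masks = [(group_labels == g).to_numpy() for g in groups]
    if any(m.sum() < 1 for m in masks):
        raise ValueError("every group needs at least one sample")

    rows = []
    for sig in scores.index:
        vals = scores.loc[sig].to_numpy(dtype=np.float64)
        if np.isnan(vals).any():
            rows.append({"signature": sig, "h_stat": np.nan, "p_value": np.nan, "stars": "ns"})
            continue
        samples = [vals[m] for m in masks]
        if np.ptp(vals) == 0:  # all scores identical: no evidence of trend
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append(
            {"signature": sig, "h_stat": float(h), "p_value": float(p), "stars": significance_stars(float(p))}
        )
    return pd.DataFrame(rows).set_index("signature")
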