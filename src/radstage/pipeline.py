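"""End-to-end orchestration: simulate -> radiomics -> genomics -> select ->
train -> evaluate, with a manifest that makes runs diffable.

Every stage writes its outputs before the next stage starts, all randomness
flows from the single configured seed, and rerunning the same configuration
reproduces every output file checksum-for-checksum (the manifest's timestamp
is the only non-reproducible field, and it is excluded from the checksum
map).
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from . import __version__
from .genomics import (
    nb_wald_de,
    normalized_log_expression,
    signature_stage_test,
    ssgsea_scores,
)
from .io import (
    sha256_of,
    write_counts,
    write_feature_table,
    write_gmt,
    write_json,
    write_labels,
    write_nifti_pair,
)
from .radiomics import ParamGrid, extract_cohort
from .selection import (
    SelectionConfig,
    clean_features,
    dedup_parameter_variants,
    long_to_wide,
    manhattan_data,
    match_count_by_pvalue,
    reduce_redundancy,
    screen_features,
)
from .staging import StagingConfig, compare_models, evaluate, train_rfe
from .synthetic import CohortConfig, generate_cohort

# moderate default sweep for the orchestrated pipeline; the full 8x5x4 grid
# is available through ParamGrid() for dedicated extraction runs
PIPELINE_GRID = ParamGrid(bin_exponents=(2, 3, 4), kernels=(1, 2), angles=(0, 45, 90, 135))


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end synthetic-cohort run."""

    out_dir: str = "radstage_run"
    seed: int = 0
    train: CohortConfig | None = None
    test: CohortConfig | None = None
    grid: ParamGrid = field(default_factory=lambda: PIPELINE_GRID)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    families: tuple[str, ...] = ("NB", "SVM", "KNN", "LR", "DT")
    compare_family: str = "NB"
    de_alpha: float = 0.05
    signature_alpha: float = 0.05

    def resolved(self) -> "PipelineConfig":
        train = self.train or CohortConfig(seed=self.seed)
        test = self.test or replace(train, n_intra=6, n_extra=6, seed=self.seed + 1)
        return replace(self, train=train, test=test)


def _write_cohort(cohort, root: Path) -> list[Path]:
    root.mkdir(parents=True, exist_ok=True)
    (root / "images").mkdir(exist_ok=True)
    written = []
    for vol, msk in zip(cohort.volumes, cohort.masks):
        # uncompressed NIfTI: gzip headers embed timestamps, which would
        # break the rerun-checksum identity the manifest promises
        vp = root / "images" / f"{vol.case_id}_volume.nii"
        mp = root / "images" / f"{vol.case_id}_mask.nii"
        write_nifti_pair(vol, msk, vp, mp)
        written += [vp, mp]
    write_counts(cohort.counts, root / "counts.tsv")
    write_labels(cohort.labels, root / "labels.csv")
    write_gmt(cohort.truth["gene_sets"], root / "gene_sets.gmt")
    truth = {k: v for k, v in cohort.truth.items() if k != "gene_sets"}
    write_json(truth, root / "truth.json")
    written += [
        root / "counts.tsv",
        root / "labels.csv",
        root / "gene_sets.gmt",
        root / "truth.json",
    ]
    return written


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    Stages run strictly in order and each stage's outputs are written before
    the next starts, so a failure leaves a diagnosable partial run.
    """
    config = config.resolved()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stages_done: list[str] = []

    # --- simulate -----------------------------------------------------------
    train_cohort = generate_cohort(config.train)
    test_cohort = generate_cohort(config.test)
    outputs += _write_cohort(train_cohort, out / "simulated" / "train")
    outputs += _write_cohort(test_cohort, out / "simulated" / "test")
    stages_done.append("simulate")

    # --- radiomics ----------------------------------------------------------
    feats_train = extract_cohort(train_cohort.volumes, train_cohort.masks, grid=config.grid)
    feats_test = extract_cohort(test_cohort.volumes, test_cohort.masks, grid=config.grid)
    write_feature_table(feats_train, out / "features_train.csv")
    write_feature_table(feats_test, out / "features_test.csv")
    outputs += [out / "features_train.csv", out / "features_test.csv"]
    stages_done.append("radiomics")

    # --- genomics -----------------------------------------------------------
    de = nb_wald_de(train_cohort.counts, train_cohort.labels, alpha=config.de_alpha)
    de.to_csv(out / "de_results.csv", index_label="gene")
    sets = train_cohort.truth["gene_sets"]
    expr_train = normalized_log_expression(train_cohort.counts)
    expr_test = normalized_log_expression(test_cohort.counts)
    scores_train = ssgsea_scores(expr_train, sets)
    scores_test = ssgsea_scores(expr_test, sets)
    scores_train.to_csv(out / "ssgsea_train.csv", index_label="signature")
    scores_test.to_csv(out / "ssgsea_test.csv", index_label="signature")
    stage_test = signature_stage_test(scores_train, train_cohort.labels)
    stage_test.to_csv(out / "stage_test.csv")
    outputs += [
        out / "de_results.csv",
        out / "ssgsea_train.csv",
        out / "ssgsea_test.csv",
        out / "stage_test.csv",
    ]
    stages_done.append("genomics")

    sig_signatures = list(
        stage_test.index[stage_test["p_value"] < config.signature_alpha]
    )
    if not sig_signatures:  # degenerate null run: keep the pipeline going
        sig_signatures = list(stage_test.sort_values("p_value").index[:2])

    # --- select -------------------------------------------------------------
    wide_train = long_to_wide(feats_train)
    clean, drops = clean_features(wide_train)
    drops.to_csv(out / "dropped_features.csv", index=False)
    screening_all = screen_features(clean, train_cohort.labels, config.selection)
    pruned = reduce_redundancy(
        clean,
        r_threshold=config.selection.redundancy_r_threshold,
        order_by=screening_all["p_value"],
    )
    screening = screening_all.loc[pruned.columns].sort_index()
    screening.to_csv(out / "screening.csv")
    manhattan = manhattan_data(screening, alpha=config.selection.alpha_screen)
    manhattan.to_csv(out / "manhattan.csv", index=False)
    significant = screening[screening["significant_05"]]
    deduped = dedup_parameter_variants(significant, seed=config.selection.seed)
    k_target = max(1, len(sig_signatures))
    final, threshold = match_count_by_pvalue(deduped, k_target)
    write_json(
        {
            "k_target": k_target,
            "implied_p_threshold": threshold,
            "selected_features": list(final.index),
            "significant_signatures": sig_signatures,
        },
        out / "final_features.json",
    )
    outputs += [
        out / "dropped_features.csv",
        out / "screening.csv",
        out / "manhattan.csv",
        out / "final_features.json",
    ]
    stages_done.append("select")

    # --- train --------------------------------------------------------------
    genomic_train = scores_train.loc[sig_signatures].T
    radiomic_train = clean[list(final.index)]
    genomic_test = scores_test.loc[sig_signatures].T
    wide_test = long_to_wide(feats_test)
    radiomic_test = wide_test.reindex(columns=list(final.index))

    metrics_rows = []
    results_by_family = {}
    for family in config.families:
        cfg = StagingConfig(family=family, seed=config.seed)
        res = train_rfe(genomic_train, radiomic_train, train_cohort.labels, family, cfg)
        results_by_family[family] = res
        pred = res.predict(genomic=genomic_test, radiomic=radiomic_test)
        m = evaluate(pred.to_numpy(), test_cohort.labels.reindex(pred.index).to_numpy())
        metrics_rows.append(
            {
                "classifier": family,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy": m.accuracy,
                "cv_sensitivity": res.cv_sensitivity,
                "cv_accuracy": res.cv_accuracy,
                "selected_genomic": res.selected_genomic,
                "selected_radiomic": res.selected_radiomic,
            }
        )
    write_json({"rows": metrics_rows, "seed": config.seed}, out / "metrics.json")
    outputs.append(out / "metrics.json")
    stages_done.append("train")

    # --- evaluate: integrated vs single-omics baselines ----------------------
    fam = config.compare_family
    cfg = StagingConfig(family=fam, seed=config.seed)
    res_rgs = results_by_family[fam]
    res_gs = train_rfe(genomic_train, None, train_cohort.labels, fam, cfg)
    res_rs = train_rfe(None, radiomic_train, train_cohort.labels, fam, cfg)
    truth_test = test_cohort.labels
    m_rgs = evaluate(
        res_rgs.predict(genomic=genomic_test, radiomic=radiomic_test).to_numpy(),
        truth_test.to_numpy(),
    )
    m_gs = evaluate(res_gs.predict(genomic=genomic_test).to_numpy(), truth_test.to_numpy())
    m_rs = evaluate(res_rs.predict(radiomic=radiomic_test).to_numpy(), truth_test.to_numpy())
    deltas = compare_models({"RGs": m_rgs, "Gs": m_gs, "Rs": m_rs})
    write_json(
        {
            "metrics": {
                "RGs": m_rgs.as_dict(),
                "Gs": m_gs.as_dict(),
                "Rs": m_rs.as_dict(),
            },
            "deltas": deltas.to_dict(orient="records"),
        },
        out / "model_comparison.json",
    )
    outputs.append(out / "model_comparison.json")
    stages_done.append("evaluate")

    # --- manifest -----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": stages_done,
        "config": {
            "train": asdict(config.train),
            "test": asdict(config.test),
            "grid": asdict(config.grid),
            "selection": asdict(config.selection),
            "families": list(config.families),
        },
        "checksums": {
            str(p.relative_to(out)): sha256_of(p) for p in sorted(outputs)
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
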