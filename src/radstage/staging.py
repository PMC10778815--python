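"""Integrated radiogenomic staging classifier with capped recursive feature
elimination.

The model is organised statsmodels-style: :class:`RadiogenomicStagingModel`
is built from training data (a genomic feature block, a radiomic feature
block, and per-case stage labels); ``fit()`` runs backward feature
elimination scored by stratified cross-validated sensitivity (ties broken by
accuracy, then by smaller feature count) and returns a
:class:`StagingResults` carrying the selected predictors, their
cross-validation scores and the refitted classifier, with ``predict()`` and
``summary()``.  At most ``cap`` features may be retained from each of the
two categories; elimination candidates are pooled across categories with
equal weight.  The positive class is the extra-vesical (high) stage: the
clinical cost asymmetry makes a missed extra-vesical tumor (false negative)
worse than a false alarm, hence sensitivity-first selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

POSITIVE = "extra"
NEGATIVE = "intra"
CLASSIFIER_FAMILIES = ("NB", "SVM", "KNN", "LR", "DT")


@dataclass
class StagingConfig:
    """Hyperparameters of the staging model.

    family : one of NB / SVM / KNN / LR / DT.
    cap : maximum retained features per category (genomic, radiomic).
    cv_folds : stratified folds used to score candidate feature subsets.
    seed : controls fold assignment and any stochastic classifier state.
    """

    family: str = "NB"
    cap: int = 8
    cv_folds: int = 5
    seed: int = 0
    knn_k: int = 3
    svm_c: float = 1.0
    lr_c: float = 1.0
    tree_depth: int = 3
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"family must be one of {CLASSIFIER_FAMILIES}, got {self.family!r}"
            )
        if self.cap < 1:
            raise ValueError("cap must be >= 1")


def make_classifier(config: StagingConfig):
    """Standard formulation of each of the five classifier families."""
    if config.family == "NB":
        return GaussianNB()
    if config.family == "SVM":
        return SVC(kernel="linear", C=config.svm_c, random_state=config.seed)
    if config.family == "KNN":
        return KNeighborsClassifier(n_neighbors=config.knn_k)
    if config.family == "LR":
        return LogisticRegression(C=config.lr_c, max_iter=1000)  # L2 default
    return DecisionTreeClassifier(max_depth=config.tree_depth, random_state=config.seed)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationMetrics:
    """Confusion counts and the derived rates; positive = extra-vesical."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def evaluate(predictions, truth) -> EvaluationMetrics:
    """Confusion metrics of aligned prediction and truth label sequences."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth differ in length")
    tp = int(np.sum((pred == POSITIVE) & (true == POSITIVE)))
    fn = int(np.sum((pred == NEGATIVE) & (true == POSITIVE)))
    tn = int(np.sum((pred == NEGATIVE) & (true == NEGATIVE)))
    fp = int(np.sum((pred == POSITIVE) & (true == NEGATIVE)))
    return EvaluationMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


def compare_models(metrics: dict[str, EvaluationMetrics]) -> pd.DataFrame:
    """Pairwise percentage-point deltas per metric between named models.

    All metrics must come from the same evaluation set (checked through the
    confusion totals).
    """
    totals = {k: m.tp + m.fn + m.tn + m.fp for k, m in metrics.items()}
    if len(set(totals.values())) > 1:
        raise ValueError(f"metrics computed on different evaluation sets: {totals}")
    rows = []
    names = list(metrics)
    for a in names:
        for b in names:
            if a == b:
                continue
            row = {"model": a, "reference": b}
            for attr in ("sensitivity", "specificity", "accuracy"):
                va, vb = getattr(metrics[a], attr), getattr(metrics[b], attr)
                row[f"delta_{attr}_pp"] = (
                    None if va is None or vb is None else round(100 * (va - vb), 10)
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the model


class MissingFeatureError(KeyError):
    """A prediction case does not provide every selected feature."""


def _fold_indices(y: np.ndarray, config: StagingConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold assignment, fixed for the whole elimination."""
    n_min = min(int((y == 1).sum()), int((y == 0).sum()))
    folds = max(2, min(config.cv_folds, n_min))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def _zscore(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _nb_predict(xtr: np.ndarray, ytr: np.ndarray, xte: np.ndarray) -> np.ndarray:
    """Vectorized Gaussian naive Bayes (matches GaussianNB's decisions).

    The Gaussian class-conditional likelihood ratio is invariant to
    per-feature affine scaling, so the z-score step is redundant here.
    """
    preds = np.empty((2, len(xte)))
    eps = 1e-9 * float(xtr.var(axis=0).max() or 1.0)
    for cls in (0, 1):
        sub = xtr[ytr == cls]
        mu = sub.mean(axis=0)
        var = sub.var(axis=0) + eps
        log_lik = -0.5 * np.sum(
            np.log(2 * np.pi * var) + (xte - mu) ** 2 / var, axis=1
        )
        preds[cls] = log_lik + np.log(len(sub) / len(xtr))
    return (preds[1] > preds[0]).astype(int)


def _cv_confusion(
    X: np.ndarray,
    y: np.ndarray,
    config: StagingConfig,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[int, int, int, int]:
    """Pooled out-of-fold confusion counts; z-scoring fitted on train folds."""
    if config.family == "NB":
        tp = fn = tn = fp = 0
        for train, test in folds:
            pred = _nb_predict(X[train], y[train], X[test])
            tp += int(np.sum((pred == 1) & (y[test] == 1)))
            fn += int(np.sum((pred == 0) & (y[test] == 1)))
            tn += int(np.sum((pred == 0) & (y[test] == 0)))
            fp += int(np.sum((pred == 1) & (y[test] == 0)))
        return tp, fn, tn, fp
    tp = fn = tn = fp = 0
    for train, test in folds:
        xtr, xte = _zscore(X[train], X[test])
        clf = make_classifier(config)
        clf.fit(xtr, y[train])
        pred = clf.predict(xte)
        tp += int(np.sum((pred == 1) & (y[test] == 1)))
        fn += int(np.sum((pred == 0) & (y[test] == 1)))
        tn += int(np.sum((pred == 0) & (y[test] == 0)))
        fp += int(np.sum((pred == 1) & (y[test] == 0)))
    return tp, fn, tn, fp


def _score(conf: tuple[int, int, int, int]) -> tuple[float, float]:
    tp, fn, tn, fp = conf
    sens = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / (tp + fn + tn + fp)
    return sens, acc


class RadiogenomicStagingModel:
    """Binary intra-/extra-vesical staging model over two feature categories.

    Parameters
    ----------
    genomic : DataFrame (cases x genomic features) or None for a
        radiomic-only baseline.
    radiomic : DataFrame (cases x radiomic features) or None for a
        genomic-only baseline.
    labels : Series of "intra"/"extra" indexed like the feature blocks.
    """

    def __init__(
        self,
        genomic: pd.DataFrame | None,
        radiomic: pd.DataFrame | None,
        labels: pd.Series,
    ) -> None:
        blocks = []
        self.categories: dict[str, str] = {}
        for name, block in (("genomic", genomic), ("radiomic", radiomic)):
            if block is None or block.shape[1] == 0:
                continue
            if block.columns.duplicated().any():
                raise ValueError(f"duplicate {name} feature names")
            blocks.append(block)
            for col in block.columns:
                if col in self.categories:
                    raise ValueError(f"feature {col!r} appears in both categories")
                self.categories[col] = name
        if not blocks:
            raise ValueError("at least one feature category must be non-empty")
        self.X = pd.concat(blocks, axis=1)
        self.labels = labels.reindex(self.X.index)
        if self.labels.isna().any():
            raise ValueError("labels missing for some cases")
        self.y = (self.labels == POSITIVE).to_numpy(dtype=int)
        for cls in (0, 1):
            if (self.y == cls).sum() < 4:
                raise ValueError("need >= 4 cases per class for CV-scored RFE")

    def _caps_ok(self, feats: list[str], cap: int) -> bool:
        counts: dict[str, int] = {}
        for f in feats:
            counts[self.categories[f]] = counts.get(self.categories[f], 0) + 1
        return all(v <= cap for v in counts.values())

    def fit(self, config: StagingConfig | None = None) -> "StagingResults":
        """Backward elimination over the pooled feature set, CV scored.

        At each step the feature whose removal gives the best remaining-set
        score is dropped; of every cap-respecting subset encountered, the one
        maximizing (sensitivity, accuracy, -n_features) is refitted on the
        full training data and returned.
        """
        config = config or StagingConfig()
        current = list(self.X.columns)
        best: tuple | None = None  # (sens, acc, -len, feats, conf)
        trace = []
        folds = _fold_indices(self.y, config)
        x_all = self.X.to_numpy()
        col_pos = {c: i for i, c in enumerate(self.X.columns)}

        def consider(feats: list[str]) -> tuple[float, float]:
            cols = [col_pos[f] for f in feats]
            conf = _cv_confusion(x_all[:, cols], self.y, config, folds)
            sens, acc = _score(conf)
            nonlocal best
            if self._caps_ok(feats, config.cap):
                key = (sens, acc, -len(feats))
                if best is None or key > (best[0], best[1], best[2]):
                    best = (sens, acc, -len(feats), list(feats), conf)
            return sens, acc

        sens, acc = consider(current)
        trace.append({"n_features": len(current), "cv_sensitivity": sens, "cv_accuracy": acc})
        while len(current) > 1:
            scored = []
            for f in current:
                remaining = [g for g in current if g != f]
                s, a = consider(remaining)
                scored.append((s, a, f))
            # drop the feature whose removal leaves the strongest subset;
            # deterministic tie-break on feature name
            s, a, drop = max(scored, key=lambda t: (t[0], t[1], t[2]))
            current.remove(drop)
            trace.append(
                {"n_features": len(current), "dropped": drop, "cv_sensitivity": s, "cv_accuracy": a}
            )

        assert best is not None
        _, _, _, feats, conf = best
        estimator = Pipeline(
            [("scale", StandardScaler()), ("clf", make_classifier(config))]
        )
        estimator.fit(self.X[feats].to_numpy(), self.y)
        return StagingResults(
            model=self,
            config=config,
            selected=feats,
            cv_confusion=conf,
            estimator=estimator,
            trace=pd.DataFrame(trace),
        )


@dataclass
class StagingResults:
    """Fitted staging model: selected predictors, CV scores, estimator."""

    model: RadiogenomicStagingModel
    config: StagingConfig
    selected: list[str]
    cv_confusion: tuple[int, int, int, int]
    estimator: Pipeline
    trace: pd.DataFrame = field(repr=False, default=None)

    @property
    def selected_genomic(self) -> list[str]:
        return [f for f in self.selected if self.model.categories[f] == "genomic"]

    @property
    def selected_radiomic(self) -> list[str]:
        return [f for f in self.selected if self.model.categories[f] == "radiomic"]

    @property
    def cv_sensitivity(self) -> float:
        return _score(self.cv_confusion)[0]

    @property
    def cv_accuracy(self) -> float:
        return _score(self.cv_confusion)[1]

    def _design(self, genomic: pd.DataFrame | None, radiomic: pd.DataFrame | None) -> pd.DataFrame:
        blocks = [b for b in (genomic, radiomic) if b is not None and b.shape[1] > 0]
        if not blocks:
            raise ValueError("no features provided")
        X = pd.concat(blocks, axis=1)
        missing = [f for f in self.selected if f not in X.columns]
        if missing:
            raise MissingFeatureError(
                f"prediction cases lack selected features: {missing}"
            )
        if X[self.selected].isna().any().any():
            raise MissingFeatureError("selected features contain missing values")
        return X[self.selected]

    def predict(
        self,
        genomic: pd.DataFrame | None = None,
        radiomic: pd.DataFrame | None = None,
    ) -> pd.Series:
        """Stage labels for new cases; features are matched by name."""
        X = self._design(genomic, radiomic)
        yhat = self.estimator.predict(X.to_numpy())
        return pd.Series(
            np.where(yhat == 1, POSITIVE, NEGATIVE), index=X.index, name="stage"
        )

    def predict_score(
        self,
        genomic: pd.DataFrame | None = None,
        radiomic: pd.DataFrame | None = None,
    ) -> pd.Series:
        """Positive-class score where the family provides one (probability
        for NB/KNN/LR/DT, signed margin for SVM)."""
        X = self._design(genomic, radiomic)
        clf = self.estimator
        if hasattr(clf, "predict_proba") and self.config.family != "SVM":
            score = clf.predict_proba(X.to_numpy())[:, 1]
        else:
            score = clf.decision_function(X.to_numpy())
        return pd.Series(score, index=X.index, name="score")

    def summary(self) -> str:
        lines = [
            "Radiogenomic staging model",
            "==========================",
            f"classifier family : {self.config.family}",
            f"per-category cap  : {self.config.cap}",
            f"CV folds / seed   : {self.config.cv_folds} / {self.config.seed}",
            f"CV sensitivity    : {self.cv_sensitivity:.3f}",
            f"CV accuracy       : {self.cv_accuracy:.3f}",
            f"genomic selected  ({len(self.selected_genomic)}):",
        ]
        lines += [f"  - {f}" for f in self.selected_genomic] or ["  (none)"]
        lines.append(f"radiomic selected ({len(self.selected_radiomic)}):")
        lines += [f"  - {f}" for f in self.selected_radiomic] or ["  (none)"]
        return "\n".join(lines)


def train_rfe(
    genomic: pd.DataFrame | None,
    radiomic: pd.DataFrame | None,
    labels: pd.Series,
    family: str = "NB",
    config: StagingConfig | None = None,
) -> StagingResults:
    """Convenience wrapper: build the model and fit with capped RFE."""
    if config is None:
        config = StagingConfig(family=family)
    elif config.family != family:
        raise ValueError("family argument disagrees with config.family")
    return RadiogenomicStagingModel(genomic, radiomic, labels).fit(config)


def train_single_omics(
    features: pd.DataFrame,
    labels: pd.Series,
    family: str = "NB",
    config: StagingConfig | None = None,
    category: str = "genomic",
) -> StagingResults:
    """Single-category baseline (the G_S / R_S models)."""
    if category == "genomic":
        return train_rfe(features, None, labels, family=family, config=config)
    return train_rfe(None, features, labels, family=family, config=config)
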