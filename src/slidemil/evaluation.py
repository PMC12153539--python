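"""Case-level cross-validation, classification metrics and bootstrap CIs.

Splitting is always at the *case* (patient) level: all slides of a case
fall into the same partition, which is what prevents leakage between
training, validation and test data when a patient contributes several
slides.  Five stratified folds yield a 60-20-20 train–validation–test
split per fold (three folds train, one validates for early stopping, one
tests), with every case tested exactly once across the five folds.  The
out-of-fold test predictions are pooled into the cross-validation metric
estimates; hold-out slides are scored by averaging the probability
vectors of the five fold models (ensembling).

Metrics: accuracy, balanced accuracy (mean of the two class recalls),
AUROC (Mann–Whitney formulation, ties half-credited) and F1, plus
per-class precision/sensitivity/specificity.  Uncertainty is quantified
with a percentile bootstrap over slides: resample the cohort with
replacement, recompute the metric, and report the replicate mean and the
2.5/97.5 percentiles.  Degenerate replicates (a single class drawn, which
leaves AUROC or balanced accuracy undefined) are redrawn a bounded number
of times rather than silently scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureBag
from .model import (
    AbmilParams,
    TrainConfig,
    default_hidden,
    ensemble_predict,
    init_params,
    predict_slide,
    train,
)
from .slide import LABELS

POSITIVE = LABELS[1]  # "metastatic"


# ---------------------------------------------------------------------------
# fold construction


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint case-id sets of one cross-validation fold."""

    fold: int
    train_cases: frozenset
    val_cases: frozenset
    test_cases: frozenset

    def __post_init__(self) -> None:
        sets = (self.train_cases, self.val_cases, self.test_cases)
        if sum(len(s) for s in sets) != len(frozenset().union(*sets)):
            raise ValueError(f"fold {self.fold}: case sets overlap")

    def role_of(self, case_id) -> str:
        for role, s in (
            ("train", self.train_cases),
            ("val", self.val_cases),
            ("test", self.test_cases),
        ):
            if case_id in s:
                return role
        raise KeyError(case_id)


def case_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Collapse a slide manifest to one row per case with its label.

    Raises if a case carries slides with conflicting labels (a synthetic
    case is benign or metastatic as a whole).
    """
    grouped = manifest.groupby("case_id")["label"].agg(["nunique", "first"])
    if (grouped["nunique"] > 1).any():
        bad = grouped.index[grouped["nunique"] > 1].tolist()
        raise ValueError(f"cases with mixed slide labels: {bad}")
    return pd.DataFrame(
        {"case_id": grouped.index, "label": grouped["first"].to_numpy()}
    ).reset_index(drop=True)


def make_stratified_case_folds(
    manifest: pd.DataFrame, k: int = 5, seed: int = 0
) -> list[FoldSplit]:
    """Stratified k-fold case partition with rotating validation fold.

    Cases are split into k label-stratified folds; fold *i* tests on fold
    i, validates on fold (i+1) mod k, and trains on the remaining k-2
    folds — for k=5 this is the 60-20-20 split.  Each case is tested
    exactly once across the k folds; class proportions per fold are within
    one case of the global proportions (a StratifiedKFold guarantee).
    """
    cases = case_table(manifest)
    counts = cases["label"].value_counts()
    for label in LABELS:
        if counts.get(label, 0) < k:
            raise ValueError(
                f"need at least {k} cases of class {label!r}, have "
                f"{counts.get(label, 0)}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_cases = [
        frozenset(cases["case_id"].iloc[test_idx])
        for _, test_idx in skf.split(cases["case_id"], cases["label"])
    ]
    splits = []
    for i in range(k):
        test = fold_cases[i]
        val = fold_cases[(i + 1) % k]
        tr = frozenset().union(
            *(fold_cases[j] for j in range(k) if j not in (i, (i + 1) % k))
        )
        splits.append(FoldSplit(i, tr, val, test))
    return splits


def folds_to_frame(splits: list[FoldSplit]) -> pd.DataFrame:
    """Tidy fold-assignment table: case_id, fold, role."""
    rows = [
        {"case_id": c, "fold": s.fold, "role": role}
        for s in splits
        for role, cs in (
            ("train", s.train_cases),
            ("val", s.val_cases),
            ("test", s.test_cases),
        )
        for c in sorted(cs)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics


def confusion(y_true, y_pred) -> np.ndarray:
    """2x2 confusion counts, rows = true class, columns = predicted class,
    in the order (benign, metastatic)."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    bad = set(y_true) | set(y_pred) - set(LABELS)
    bad -= set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return confusion_matrix(y_true, y_pred, labels=list(LABELS))


def _binary_counts(counts: np.ndarray, positive_class: str) -> tuple[int, int, int, int]:
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise ValueError("counts must be a 2x2 matrix")
    p = LABELS.index(positive_class)
    n = 1 - p
    return int(counts[p, p]), int(counts[n, p]), int(counts[n, n]), int(counts[p, n])


def _ratio(num: float, den: float) -> float:
    """0/0 is reported as NaN (undefined), never silently 0."""
    return float(num) / float(den) if den > 0 else float("nan")


def class_metrics(counts: np.ndarray, positive_class: str) -> dict[str, float]:
    """Precision, sensitivity, specificity and F1 for one positive class.

    F1 is the harmonic mean of precision and sensitivity; any 0/0 ratio
    yields NaN.
    """
    tp, fp, tn, fn = _binary_counts(counts, positive_class)
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    f1 = (
        _ratio(2 * precision * sensitivity, precision + sensitivity)
        if np.isfinite(precision) and np.isfinite(sensitivity)
        else float("nan")
    )
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
    }


def accuracy_metrics(counts: np.ndarray) -> dict[str, float]:
    """Overall accuracy and balanced accuracy (mean of class recalls)."""
    counts = np.asarray(counts)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    recalls = [
        _ratio(counts[i, i], counts[i].sum()) for i in range(counts.shape[0])
    ]
    return {
        "accuracy": float(np.trace(counts) / total),
        "balanced_accuracy": float(np.mean(recalls)),
    }


def auroc(y_true, score_metastatic) -> float:
    """Probability that a random metastatic slide outranks a random benign
    slide (ties half-credited).  NaN when only one class is present."""
    y = np.asarray([1 if t == POSITIVE else 0 for t in y_true])
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, np.asarray(score_metastatic, dtype=np.float64)))


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapCI:
    """Percentile bootstrap summary of one metric."""

    mean: float
    low: float
    high: float
    sd: float
    n_undefined: int


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    y_true,
    predictions,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    max_redraws: int = 100,
) -> BootstrapCI:
    """Percentile bootstrap of ``metric(y_true, predictions)`` over slides.

    Slides are resampled with replacement ``n_bootstrap`` times; a
    replicate on which the metric is undefined (NaN — e.g. a single-class
    draw for AUROC) is redrawn up to ``max_redraws`` times.  Raises if
    more than half of the replicates remain undefined.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    y_true = np.asarray(y_true)
    predictions = np.asarray(predictions)
    n = len(y_true)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    n_undef = 0
    for b in range(n_bootstrap):
        value = float("nan")
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            value = float(metric(y_true[idx], predictions[idx]))
            if np.isfinite(value):
                break
        if not np.isfinite(value):
            n_undef += 1
        reps[b] = value
    if n_undef > n_bootstrap / 2:
        raise ValueError(
            f"metric undefined on {n_undef}/{n_bootstrap} bootstrap replicates"
        )
    return BootstrapCI(
        mean=float(np.nanmean(reps)),
        low=float(np.nanpercentile(reps, 2.5)),
        high=float(np.nanpercentile(reps, 97.5)),
        sd=float(np.nanstd(reps)),
        n_undefined=n_undef,
    )


# ---------------------------------------------------------------------------
# report


@dataclass
class MetricWithCI:
    point: float
    boot_mean: float
    ci_low: float
    ci_high: float


@dataclass
class MetricsReport:
    """Point estimates plus bootstrap summaries for one prediction set.

    ``f1`` is the per-class F1 of the metastatic class; ``f1_macro`` (the
    unweighted mean of the two per-class F1s) is also reported because the
    averaging convention is ambiguous in parts of the literature.
    """

    counts: list
    n_slides: int
    accuracy: MetricWithCI
    balanced_accuracy: MetricWithCI
    auroc: MetricWithCI
    f1: MetricWithCI
    f1_macro: float
    per_class: dict
    n_bootstrap: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def _acc_metric(y, pred):
    return float(np.mean(y == pred))


def _balacc_metric(y, pred):
    recalls = []
    for label in LABELS:
        m = y == label
        if not m.any():
            return float("nan")
        recalls.append(float(np.mean(pred[m] == label)))
    return float(np.mean(recalls))


def _f1_metric(y, pred):
    c = confusion(y, pred)
    return class_metrics(c, POSITIVE)["f1"]


def compute_metrics_report(
    y_true,
    pred_labels,
    score_metastatic,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> MetricsReport:
    """Full metric report with percentile-bootstrap uncertainty."""
    y = np.asarray(list(y_true))
    pred = np.asarray(list(pred_labels))
    scores = np.asarray(score_metastatic, dtype=np.float64)
    c = confusion(y, pred)
    acc = accuracy_metrics(c)
    per_class = {label: class_metrics(c, label) for label in LABELS}

    def ci(metric, predictions, offset):
        return bootstrap_ci(
            metric, y, predictions, n_bootstrap=n_bootstrap, seed=seed + offset
        )

    b_acc = ci(_acc_metric, pred, 0)
    b_bal = ci(_balacc_metric, pred, 1)
    b_auc = ci(auroc, scores, 2)
    b_f1 = ci(_f1_metric, pred, 3)
    mk = lambda point, b: MetricWithCI(float(point), b.mean, b.low, b.high)
    f1s = [per_class[label]["f1"] for label in LABELS]
    return MetricsReport(
        counts=c.tolist(),
        n_slides=int(len(y)),
        accuracy=mk(acc["accuracy"], b_acc),
        balanced_accuracy=mk(acc["balanced_accuracy"], b_bal),
        auroc=mk(auroc(y, scores), b_auc),
        f1=mk(per_class[POSITIVE]["f1"], b_f1),
        f1_macro=float(np.mean(f1s)),
        per_class=per_class,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cross-validation / hold-out drivers


@dataclass
class CVResult:
    """Trained fold models plus pooled out-of-fold predictions."""

    models: list[AbmilParams]
    splits: list[FoldSplit]
    predictions: pd.DataFrame
    report: MetricsReport
    train_case_ids: frozenset
    histories: list[list[dict]] = field(default_factory=list)


def _predictions_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "slide_id",
            "prob_benign",
            "prob_metastatic",
            "pred_label",
            "fold",
            "label",
        ],
    )


def run_cross_validation(
    manifest: pd.DataFrame,
    bags: dict[str, FeatureBag],
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    hidden: tuple[int, int] | None = None,
    n_bootstrap: int = 10_000,
) -> CVResult:
    """Stratified case-level k-fold cross-validation.

    Trains one ABMIL model per fold (early-stopped on that fold's
    validation cases) and pools the out-of-fold test predictions — every
    slide is predicted exactly once — into a bootstrap metric report.
    """
    cfg = train_config or TrainConfig()
    missing = set(manifest["slide_id"]) - set(bags)
    if missing:
        raise ValueError(f"no feature bag for slides: {sorted(missing)[:5]} ...")
    splits = make_stratified_case_folds(manifest, k=k, seed=seed)
    feature_dim = next(iter(bags.values())).feature_dim

    models, histories, rows = [], [], []
    for split in splits:
        sub = {
            role: manifest[manifest["case_id"].isin(getattr(split, f"{role}_cases"))]
            for role in ("train", "val", "test")
        }
        params = init_params(
            feature_dim, hidden=hidden, seed=seed + 1000 + split.fold
        )
        fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + split.fold})
        fitted, hist = train(
            params,
            [bags[s] for s in sub["train"]["slide_id"]],
            list(sub["train"]["label"]),
            fold_cfg,
            [bags[s] for s in sub["val"]["slide_id"]],
            list(sub["val"]["label"]),
            case_ids=list(sub["train"]["case_id"]),
        )
        models.append(fitted)
        histories.append(hist)
        for _, row in sub["test"].iterrows():
            pred = predict_slide(fitted, bags[row["slide_id"]])
            rows.append(
                {
                    "slide_id": row["slide_id"],
                    "prob_benign": float(pred.probs[0]),
                    "prob_metastatic": float(pred.probs[1]),
                    "pred_label": pred.predicted_label,
                    "fold": split.fold,
                    "label": row["label"],
                }
            )
    preds = _predictions_frame(rows)
    assert len(preds) == len(manifest)
    report = compute_metrics_report(
        preds["label"],
        preds["pred_label"],
        preds["prob_metastatic"],
        n_bootstrap=n_bootstrap,
        seed=seed + 7,
    )
    return CVResult(
        models=models,
        splits=splits,
        predictions=preds,
        report=report,
        train_case_ids=frozenset(manifest["case_id"]),
        histories=histories,
    )


def run_holdout(
    members: list[AbmilParams],
    holdout_manifest: pd.DataFrame,
    bags: dict[str, FeatureBag],
    train_case_ids,
    n_bootstrap: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, MetricsReport]:
    """Ensembled hold-out evaluation with a hard leakage guard.

    Every hold-out slide is scored by the element-wise mean of the member
    probability vectors.  Any overlap between hold-out cases and the
    training cases is an error, never a warning.
    """
    overlap = set(holdout_manifest["case_id"]) & set(train_case_ids)
    if overlap:
        raise ValueError(
            f"hold-out cases also present in training data: {sorted(overlap)[:5]}"
        )
    rows = []
    for _, row in holdout_manifest.iterrows():
        pred = ensemble_predict(members, bags[row["slide_id"]])
        rows.append(
            {
                "slide_id": row["slide_id"],
                "prob_benign": float(pred.probs[0]),
                "prob_metastatic": float(pred.probs[1]),
                "pred_label": pred.predicted_label,
                "fold": -1,
                "label": row["label"],
            }
        )
    preds = _predictions_frame(rows)
    report = compute_metrics_report(
        preds["label"],
        preds["pred_label"],
        preds["prob_metastatic"],
        n_bootstrap=n_bootstrap,
        seed=seed + 13,
    )
    return preds, report
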