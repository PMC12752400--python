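"""Transfer-scenario evaluation: teacher/student plus trees on deep features.

Four source→target configurations are supported (single or aggregated
cohorts on either side). The pipeline per scenario:

1. harmonise all named cohorts on shared rsIDs;
2. split source and target 80/20 (stratified); balance the training
   partitions (two-stage over/undersampling);
3. impute with training-fit per-SNP means (train statistics applied to the
   held-out parts — the target test split never influences any fit);
4. optionally select the top-n SNPs by F-score on the balanced source
   training data;
5. train the Wide-Deep teacher on source train (early stopping on the
   source held-out split);
6. distill the student on the target training split (optionally tuning
   alpha by stratified k-fold on that split);
7. extract teacher hidden-layer features for source train and target test
   and fit GB / DT / RF / XGBoost on the source-train features;
8. evaluate all six models on the target test split.

A leakage audit record lists the sample ids that entered every fitting
step so the disjointness from the target test set can be asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.tree import DecisionTreeClassifier

from gwaskd import io_preprocess as iop
from gwaskd import select as sel
from gwaskd.distill import DistillationConfig, train_student, tune_alpha
from gwaskd.models import (
    AttentionConfig,
    DeepConfig,
    StudentReduction,
    TeacherModel,
    WideConfig,
    build_student,
    extract_features,
    train_teacher,
)
from gwaskd.simulate import CohortDataset

__all__ = [
    "TransferScenario",
    "EvaluationReport",
    "ScenarioResult",
    "ModelSpec",
    "compute_metrics",
    "train_downstream",
    "run_scenario",
    "run_ablation",
    "reports_to_frame",
]

SCENARIO_IDS = (
    "exp1_single_to_single",
    "exp2_aggregated_to_single",
    "exp3_single_to_aggregated",
    "exp4_aggregated_to_aggregated",
)

DOWNSTREAM_KINDS = ("gb", "dt", "rf", "xgboost")


@dataclass
class TransferScenario:
    """One source→target cohort configuration."""

    id: str
    source_cohorts: list[str]
    target_cohorts: list[str]

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario id {self.id!r}")
        if not self.source_cohorts or not self.target_cohorts:
            raise ValueError("source and target cohort lists must be non-empty")
        overlap = set(self.source_cohorts) & set(self.target_cohorts)
        if overlap:
            raise ValueError(f"source/target cohorts overlap: {sorted(overlap)}")


@dataclass
class EvaluationReport:
    """All reported metrics for one (source, target, model) cell."""

    model_name: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auc: float | None
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    roc_points: list[tuple[float, float]]

    def recompute_from_confusion(self) -> dict[str, float]:
        """Re-derive threshold metrics from the stored confusion matrix."""
        (tn, fp), (fn, tp) = self.confusion
        n = tn + fp + fn + tp
        acc = (tn + tp) / n
        prec1 = tp / (tp + fp) if tp + fp else 0.0
        rec1 = tp / (tp + fn) if tp + fn else 0.0
        prec0 = tn / (tn + fn) if tn + fn else 0.0
        rec0 = tn / (tn + fp) if tn + fp else 0.0
        f1_1 = 2 * prec1 * rec1 / (prec1 + rec1) if prec1 + rec1 else 0.0
        f1_0 = 2 * prec0 * rec0 / (prec0 + rec0) if prec0 + rec0 else 0.0
        return {
            "accuracy": acc,
            "precision": (prec0 + prec1) / 2,
            "recall": (rec0 + rec1) / 2,
            "f1": (f1_0 + f1_1) / 2,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        }


def compute_metrics(
    labels: np.ndarray,
    predictions: np.ndarray,
    scores: np.ndarray,
    model_name: str = "model",
) -> EvaluationReport:
    """Accuracy, macro precision/recall/F1, specificity, rank-statistic AUC.

    Precision/recall/F1 are macro-averaged over the two classes;
    specificity is TN/(TN+FP); AUC is the Mann-Whitney rank statistic with
    ties credited 0.5 (so constant scores give AUC 0.5). If only one class
    is present in ``labels`` the AUC is None with a warning.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (labels.size == predictions.size == scores.size):
        raise ValueError("labels/predictions/scores length mismatch")

    tn = int(((labels == 0) & (predictions == 0)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    tp = int(((labels == 1) & (predictions == 1)).sum())
    confusion = np.array([[tn, fp], [fn, tp]])

    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUC undefined")
        auc = None
        roc_points = []
    else:
        # rank-statistic AUC with 0.5 tie credit
        auc = float(roc_auc_score(labels, scores))
        fpr, tpr, _ = roc_curve(labels, scores)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))

    report = EvaluationReport(
        model_name=model_name,
        accuracy=0.0,
        precision=0.0,
        recall=0.0,
        f1=0.0,
        specificity=0.0,
        auc=auc,
        confusion=confusion,
        roc_points=roc_points,
    )
    derived = report.recompute_from_confusion()
    report.accuracy = derived["accuracy"]
    report.precision = derived["precision"]
    report.recall = derived["recall"]
    report.f1 = derived["f1"]
    report.specificity = derived["specificity"]
    return report


def train_downstream(
    features: np.ndarray, labels: np.ndarray, kind: str, seed: int = 0
):
    """Fit a tree-family classifier on (deep or raw) feature vectors."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    if not np.isfinite(features).all():
        raise ValueError("non-finite feature values")
    if kind == "gb":
        clf = GradientBoostingClassifier(random_state=seed)
    elif kind == "dt":
        clf = DecisionTreeClassifier(random_state=seed)
    elif kind == "rf":
        clf = RandomForestClassifier(random_state=seed)
    elif kind == "xgboost":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss"
        )
    else:
        raise ValueError(f"unknown downstream kind {kind!r}")
    clf.fit(features, labels)
    return clf


@dataclass
class ModelSpec:
    """Teacher/student architecture knobs for a scenario run."""

    wide: WideConfig = field(default_factory=WideConfig)
    deep: DeepConfig = field(default_factory=DeepConfig)
    attention: AttentionConfig | None = field(default_factory=AttentionConfig)
    student_reduction: StudentReduction = field(default_factory=StudentReduction)
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 0.01
    patience: int = 10
    #: layer fed to the downstream tree classifiers; the fusion
    #: representation carries both the deep activations and the wide score
    feature_layer: str | None = "fusion"
    n_cross_pairs: int = 10  # wide path: pairs among the top-n F-score SNPs


@dataclass
class ScenarioResult:
    """Per-model reports plus the leakage-audit record and seeds."""

    scenario: TransferScenario
    reports: dict[str, EvaluationReport]
    audit: dict[str, set]
    seeds: dict[str, int]
    selected_rsids: list[str] | None = None
    alpha: float | None = None
    alpha_scores: list[dict] | None = None
    teacher: TeacherModel | None = None
    student: object | None = None


def _balanced_train(
    split: iop.SplitPair, seed: int, balance: bool
) -> CohortDataset:
    return iop.balance_classes(split.train, seed=seed) if balance else split.train


def run_scenario(
    scenario: TransferScenario,
    cohorts: dict[str, CohortDataset],
    model_config: ModelSpec | None = None,
    distill_config: DistillationConfig | None = None,
    seed: int = 0,
    n_features: int | None = None,
    tune: bool = False,
    tune_folds: int = 5,
    balance_eval: bool = False,
    eval_full_target: bool = False,
    keep_models: bool = False,
) -> ScenarioResult:
    """Execute one transfer scenario end to end; see the module docstring.

    With ``tune=True`` the distillation weight alpha is selected over
    ``distill_config.alpha_grid`` by stratified k-fold on the target
    training split (validation macro-F1, ties to smaller alpha); otherwise
    ``distill_config.alpha`` is used directly. ``eval_full_target``
    evaluates on the whole target cohort instead of its held-out split
    (the target training split then overlaps evaluation data; the leakage
    audit is skipped for that reading).
    """
    mc = model_config or ModelSpec()
    dc = distill_config or DistillationConfig()
    missing = [
        c
        for c in scenario.source_cohorts + scenario.target_cohorts
        if c not in cohorts
    ]
    if missing:
        raise ValueError(f"cohorts not provided: {missing}")

    names = scenario.source_cohorts + scenario.target_cohorts
    if len(names) >= 2:
        harmonised = iop.harmonise_cohorts([cohorts[c] for c in names])
        byname = dict(zip(names, harmonised))
    else:
        byname = {c: cohorts[c] for c in names}

    source = iop.concatenate_cohorts(
        [byname[c] for c in scenario.source_cohorts], name="source"
    )
    target = iop.concatenate_cohorts(
        [byname[c] for c in scenario.target_cohorts], name="target"
    )

    src_split = iop.stratified_split(source, 0.2, seed=seed)
    tgt_split = iop.stratified_split(target, 0.2, seed=seed + 1)

    src_train = _balanced_train(src_split, seed + 2, balance=True)
    tgt_train = _balanced_train(tgt_split, seed + 3, balance=True)

    # impute with training-fit means; held-out parts get the train means
    src_means = iop.fit_imputer_means(src_train)
    tgt_means = iop.fit_imputer_means(tgt_train)
    src_train = iop.apply_imputer_means(src_train, src_means)
    src_test = iop.apply_imputer_means(src_split.test, src_means)
    tgt_train = iop.apply_imputer_means(tgt_train, tgt_means)
    tgt_eval_src = target if eval_full_target else tgt_split.test
    tgt_eval = iop.apply_imputer_means(tgt_eval_src, tgt_means)
    if balance_eval:
        tgt_eval = iop.balance_classes(tgt_eval, seed=seed + 4)

    audit: dict[str, set] = {
        "target_test_ids": set(tgt_split.test.sample_ids),
        "selection_fit_ids": set(),
        "imputation_fit_ids": set(src_train.sample_ids)
        | set(tgt_train.sample_ids),
        "teacher_fit_ids": set(src_train.sample_ids)
        | set(src_test.sample_ids),
        "student_fit_ids": set(tgt_train.sample_ids),
        "downstream_fit_ids": set(src_train.sample_ids),
        "balancing_input_ids": set(src_split.train.sample_ids)
        | set(tgt_split.train.sample_ids),
    }

    selected = None
    if n_features is not None:
        if n_features <= 0:
            raise ValueError("n_features must be positive")
        ranking = sel.f_score(src_train)
        audit["selection_fit_ids"] = set(src_train.sample_ids)
        selected = ranking.top(min(n_features, src_train.n_snps))
        cols = [src_train.rsids.index(r) for r in selected]
        src_train = iop.subset_snps(src_train, cols)
        src_test = iop.subset_snps(src_test, cols)
        tgt_train = iop.subset_snps(tgt_train, cols)
        tgt_eval = iop.subset_snps(tgt_eval, cols)

    n_snps = src_train.n_snps
    wide = mc.wide
    if not wide.cross_product_pairs and mc.n_cross_pairs > 0:
        # pairs among the top F-score SNPs of the (balanced) source train
        top = sel.f_score(src_train).top(min(mc.n_cross_pairs, n_snps))
        idx = [src_train.rsids.index(r) for r in top]
        pairs = [
            (idx[i], idx[j])
            for i in range(len(idx))
            for j in range(i + 1, len(idx))
        ]
        wide = WideConfig(cross_product_pairs=pairs, include_raw=wide.include_raw)
        audit["selection_fit_ids"] |= set(src_train.sample_ids)

    teacher = TeacherModel(
        n_snps, wide=wide, deep=mc.deep, attention=mc.attention, seed=seed + 10
    )
    train_teacher(
        teacher,
        src_train.genotypes,
        src_train.labels,
        epochs=mc.epochs,
        batch_size=mc.batch_size,
        learning_rate=mc.learning_rate,
        seed=seed + 11,
        X_val=src_test.genotypes,
        y_val=src_test.labels,
        patience=mc.patience,
    )

    def fresh_student(s: int):
        return build_student(teacher, mc.student_reduction, seed=s + 12)

    alpha, alpha_scores = dc.alpha, None
    if tune:
        folds = iop.kfold_indices(tgt_train, k=tune_folds, seed=seed + 13)
        per_alpha = {a: [] for a in dc.alpha_grid}
        for tr_idx, va_idx in folds:
            tr = iop.subset_samples(tgt_train, tr_idx)
            va = iop.subset_samples(tgt_train, va_idx)
            _, scores = tune_alpha(
                teacher,
                fresh_student,
                (tr.genotypes, tr.labels),
                (va.genotypes, va.labels),
                dc,
            )
            for row in scores:
                per_alpha[row["alpha"]].append(row["val_f1"])
        alpha_scores = [
            {"alpha": a, "val_f1": float(np.mean(v))}
            for a, v in per_alpha.items()
        ]
        best = max(
            alpha_scores, key=lambda r: (round(r["val_f1"], 12), -r["alpha"])
        )
        alpha = best["alpha"]

    dc_run = DistillationConfig(
        temperature=dc.temperature,
        alpha=alpha,
        alpha_grid=dc.alpha_grid,
        epochs=dc.epochs,
        batch_size=dc.batch_size,
        learning_rate=dc.learning_rate,
        seed=dc.seed + seed,
        patience=dc.patience,
    )
    student = fresh_student(seed)
    student, _hist = train_student(
        teacher,
        student,
        (tgt_train.genotypes, tgt_train.labels),
        None,
        dc_run,
    )

    feats_train = extract_features(
        teacher, src_train.genotypes, layer=mc.feature_layer
    )
    feats_eval = extract_features(
        teacher, tgt_eval.genotypes, layer=mc.feature_layer
    )

    reports: dict[str, EvaluationReport] = {}
    y_eval = tgt_eval.labels
    for name, model in (("teacher", teacher), ("student", student)):
        probs = model.predict_proba(tgt_eval.genotypes)
        reports[name] = compute_metrics(
            y_eval, (probs >= 0.5).astype(int), probs, model_name=name
        )
    for kind in DOWNSTREAM_KINDS:
        clf = train_downstream(feats_train, src_train.labels, kind, seed=seed + 20)
        probs = clf.predict_proba(feats_eval)[:, 1]
        reports[kind] = compute_metrics(
            y_eval, (probs >= 0.5).astype(int), probs, model_name=kind
        )

    # internal consistency audit: metrics reproduce from the confusion matrix
    for rep in reports.values():
        derived = rep.recompute_from_confusion()
        for key, val in derived.items():
            if abs(getattr(rep, key) - val) > 1e-9:
                raise AssertionError(
                    f"metric {key} inconsistent with confusion matrix"
                )

    result = ScenarioResult(
        scenario=scenario,
        reports=reports,
        audit=audit,
        seeds={
            "base": seed,
            "source_split": seed,
            "target_split": seed + 1,
            "source_balance": seed + 2,
            "target_balance": seed + 3,
            "teacher_init": seed + 10,
            "teacher_train": seed + 11,
            "student_init": seed + 12,
            "downstream": seed + 20,
        },
        selected_rsids=selected,
        alpha=alpha,
        alpha_scores=alpha_scores,
    )
    if keep_models:
        result.teacher = teacher
        result.student = student
    return result


def run_ablation(
    scenario: TransferScenario,
    cohorts: dict[str, CohortDataset],
    subset_sizes: Sequence[int],
    attention_flags: Sequence[bool],
    model_config: ModelSpec | None = None,
    distill_config: DistillationConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Sweep feature-subset size x attention on/off over the scenario.

    For each (size, flag) cell the full scenario pipeline is re-run with
    the top-``size`` F-score SNPs (ranked on the balanced source training
    split) and attention toggled on both teacher and student. Returns a
    tidy frame (size, attention, model, metric, value) plus the raw
    reports keyed by cell.
    """
    if any(s <= 0 for s in subset_sizes):
        raise ValueError("subset sizes must be positive")
    mc = model_config or ModelSpec()
    rows = []
    cells: dict[tuple[int, bool], dict[str, EvaluationReport]] = {}
    for size in subset_sizes:
        for flag in attention_flags:
            cell_mc = ModelSpec(
                wide=mc.wide,
                deep=mc.deep,
                attention=(mc.attention or AttentionConfig()) if flag else None,
                student_reduction=mc.student_reduction,
                epochs=mc.epochs,
                batch_size=mc.batch_size,
                learning_rate=mc.learning_rate,
                patience=mc.patience,
                feature_layer=mc.feature_layer,
                n_cross_pairs=mc.n_cross_pairs,
            )
            result = run_scenario(
                scenario,
                cohorts,
                model_config=cell_mc,
                distill_config=distill_config,
                seed=seed,
                n_features=size,
            )
            cells[(size, flag)] = result.reports
            for model, rep in result.reports.items():
                for metric in (
                    "accuracy", "precision", "recall", "f1", "specificity",
                ):
                    rows.append(
                        {
                            "size": size,
                            "attention": flag,
                            "model": model,
                            "metric": metric,
                            "value": getattr(rep, metric),
                        }
                    )
                rows.append(
                    {
                        "size": size,
                        "attention": flag,
                        "model": model,
                        "metric": "auc",
                        "value": rep.auc,
                    }
                )
    return pd.DataFrame(rows), cells


def reports_to_frame(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """One row per model, mirroring the Acc/Prec/Rec/F1/Spec table layout."""
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "Model": name,
                "Acc": rep.accuracy,
                "Prec": rep.precision,
                "Rec": rep.recall,
                "F1": rep.f1,
                "Spec": rep.specificity,
                "AUC": rep.auc,
            }
        )
    return pd.DataFrame(rows)
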