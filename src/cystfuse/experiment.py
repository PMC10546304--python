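"""Patient-level cross-validated evaluation of a fusion model.

For every fold the model is trained on the training-fold slice packs and
scored on the validation-fold slices. Slice-level metrics are computed for
the fused (main) output, for each modality's secondary output (single-
modality evaluation), and for the modality-majority vote ("AR"). Slice
scores are then aggregated to one diagnosis per patient (majority vote or
SVM over slice-score summaries; the SVM and its standardization see only
training-fold patients). Per-fold metrics are aggregated into
mean ± sd [min, max] reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DECISION_THRESHOLD, MODALITIES, NEGATIVE_LABEL, POSITIVE_LABEL
from .errors import ConfigurationError, ValidationError
from .eval_metrics import (
    FoldAssignment,
    MetricReport,
    aggregate_folds,
    confusion,
    make_folds,
    roc_auc,
    sens_spec_acc,
)
from .fusion_net import ModelConfig
from .patient_level import (
    PatientSliceScores,
    build_patient_feature,
    patient_vote,
    svm_patient_fit,
)
from .preprocess import AugmentSpec, WindowSpec, expand_training_packs, preprocess_series
from .training import FusionModel, LossWeights, TrainConfig
from .volume_io import PatientSeries

logger = logging.getLogger(__name__)


def _slice_metrics(scores: np.ndarray, labels: Sequence[str]) -> dict[str, Optional[float]]:
    preds = [POSITIVE_LABEL if s >= DECISION_THRESHOLD else NEGATIVE_LABEL for s in scores]
    sens, spec, acc = sens_spec_acc(confusion(preds, labels))
    try:
        auc = roc_auc(scores, labels)
    except ValidationError:
        auc = None
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc, "auc": auc}


@dataclass
class ExperimentResult:
    """All outputs of one cross-validated run."""

    fold_assignment: FoldAssignment
    slice_scores: pd.DataFrame  # per validation slice, all output channels
    patient_scores: pd.DataFrame  # per patient: prediction + continuous score
    reports: dict[str, MetricReport]  # row name -> per-fold metric report
    loss_traces: pd.DataFrame  # per fold loss trace
    leakage_audit: pd.DataFrame  # per fold: train/val patient sets, overlap size

    def results_frame(self) -> pd.DataFrame:
        """Long-form results: one row per (row name, fold) + aggregates."""
        rows = []
        for name, report in self.reports.items():
            for fold, r in report.per_fold.iterrows():
                rows.append(dict(row=name, fold=fold, **{k: r[k] for k in r.index}))
            agg = report.aggregate()
            for stat in ("mean", "sd", "min", "max"):
                rows.append(
                    dict(row=name, fold=stat, **{m: agg.loc[m, stat] for m in agg.index})
                )
        return pd.DataFrame(rows)

    def markdown_report(self) -> str:
        """Render the evaluation as Markdown tables (single-modality,
        fusion, patient-level)."""
        def fmt(report: MetricReport) -> str:
            agg = report.aggregate()
            cells = []
            for m in ("sensitivity", "specificity", "accuracy", "auc"):
                if m in agg.index and np.isfinite(agg.loc[m, "mean"]):
                    cells.append(
                        f"{agg.loc[m, 'mean']:.2f} ± {agg.loc[m, 'sd']:.2f} "
                        f"[{agg.loc[m, 'min']:.2f}, {agg.loc[m, 'max']:.2f}]"
                    )
                else:
                    cells.append("–")
            return " | ".join(cells)

        header = "| row | sensitivity | specificity | accuracy | AUC |\n|---|---|---|---|---|"
        single = [f"| {m} | {fmt(self.reports[m])} |" for m in MODALITIES if m in self.reports]
        if "AR" in self.reports:
            single.append(f"| AR | {fmt(self.reports['AR'])} |")
        other = [
            f"| {name} | {fmt(rep)} |"
            for name, rep in self.reports.items()
            if name not in MODALITIES and name != "AR"
        ]
        parts = ["## Single-modality results (secondary outputs)", header, *single,
                 "", "## Fusion and patient-level results", header, *other]
        return "\n".join(parts)


def cohort_to_packs(
    cohort: Sequence[PatientSeries],
    k_slices: int = 27,
    window: Optional[WindowSpec] = None,
):
    """Preprocess every patient of a cohort into labeled slice packs."""
    packs = []
    for series in cohort:
        packs.extend(preprocess_series(series, window=window, k_slices=k_slices))
    return packs


def run_experiment(
    cohort: Sequence[PatientSeries],
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    k: int = 4,
    seed: int = 0,
    *,
    loss_weights: LossWeights = LossWeights(),
    k_slices: int = 3,
    n_aug: int = 0,
    augment_spec: AugmentSpec = AugmentSpec(),
    patient_method: str = "svm",
    window: Optional[WindowSpec] = None,
) -> ExperimentResult:
    """Stratified patient-level k-fold evaluation of one fusion configuration."""
    if patient_method not in ("vote", "svm"):
        raise ConfigurationError("patient_method must be 'vote' or 'svm'")
    if any(s.label is None for s in cohort):
        raise ValidationError("all cohort patients must be labeled")

    patients = [s.patient_id for s in cohort]
    labels = [s.label for s in cohort]
    label_of = dict(zip(patients, labels))
    folds = make_folds(patients, labels, k=k, seed=seed)

    packs_by_patient = {}
    for series in cohort:
        packs_by_patient[series.patient_id] = preprocess_series(
            series, window=window, k_slices=k_slices
        )

    has_secondary = model_config.method != "IMG-F"
    fold_rows: dict[str, list[dict]] = {}
    slice_rows, patient_rows, trace_rows, audit_rows = [], [], [], []

    for fold in range(k):
        val_patients = set(folds.fold_patients(fold))
        train_patients = [p for p in patients if p not in val_patients]
        overlap = val_patients.intersection(train_patients)
        audit_rows.append(
            dict(fold=fold, n_train=len(train_patients), n_val=len(val_patients),
                 overlap=len(overlap))
        )
        if overlap:  # pragma: no cover - make_folds guarantees disjointness
            raise ValidationError(f"fold {fold}: leakage between train and validation")

        train_packs = [p for pid in train_patients for p in packs_by_patient[pid]]
        if n_aug > 0:
            train_packs = expand_training_packs(
                train_packs, n_aug=n_aug, seed=seed * 1000 + fold, spec=augment_spec
            )
        val_packs = [p for pid in sorted(val_patients) for p in packs_by_patient[pid]]

        model = FusionModel(train_packs, model_config, train_config, loss_weights)
        fit = model.fit(seed=train_config.seed + fold)
        trace = fit.loss_trace.copy()
        trace.insert(0, "fold", fold)
        trace_rows.append(trace)

        val_scores = fit.score_slices(val_packs)
        val_scores.insert(0, "fold", fold)
        val_labels = [p.label for p in val_packs]

        # Slice-level rows: fused main output, per-modality secondary, AR.
        metrics_of: dict[str, dict] = {}
        metrics_of[model_config.method] = _slice_metrics(
            val_scores["p_mcn"].to_numpy(), val_labels
        )
        if has_secondary:
            sec_cols = {m: val_scores[f"p_mcn_{m}"].to_numpy() for m in MODALITIES}
            for m in MODALITIES:
                metrics_of[m] = _slice_metrics(sec_cols[m], val_labels)
            # AR: majority vote across the seven modality outputs; the vote
            # fraction serves as the continuous score for ROC.
            votes = np.stack(
                [(sec_cols[m] >= DECISION_THRESHOLD) for m in MODALITIES]
            ).sum(axis=0)
            ar_score = votes / len(MODALITIES)
            ar_pred = [
                POSITIVE_LABEL if v > len(MODALITIES) // 2 else NEGATIVE_LABEL
                for v in votes
            ]
            sens, spec, acc = sens_spec_acc(confusion(ar_pred, val_labels))
            try:
                ar_auc = roc_auc(ar_score, val_labels)
            except ValidationError:
                ar_auc = None
            metrics_of["AR"] = {
                "sensitivity": sens, "specificity": spec, "accuracy": acc, "auc": ar_auc,
            }
            val_scores["ar_score"] = ar_score
        slice_rows.append(val_scores)

        # Patient-level aggregation on the main output.
        def patient_scores_from(df: pd.DataFrame) -> list[PatientSliceScores]:
            return [
                PatientSliceScores(
                    patient_id=pid, p_mcn=sub["p_mcn"].to_numpy(), label=label_of[pid]
                )
                for pid, sub in df.groupby("patient_id", sort=True)
            ]

        val_ps = patient_scores_from(val_scores)
        if patient_method == "svm":
            train_scores = fit.score_slices(
                [p for pid in train_patients for p in packs_by_patient[pid]]
            )
            train_ps = patient_scores_from(train_scores)
            aggregator = svm_patient_fit(
                np.stack([build_patient_feature(s) for s in train_ps]),
                [s.label for s in train_ps],
            )
            preds_scores = [
                aggregator.predict(build_patient_feature(s)) for s in val_ps
            ]
        else:
            preds_scores = [
                (patient_vote(s), float(s.p_mcn.mean())) for s in val_ps
            ]
        p_preds = [p for p, _ in preds_scores]
        p_scores = [s for _, s in preds_scores]
        p_labels = [s.label for s in val_ps]
        sens, spec, acc = sens_spec_acc(confusion(p_preds, p_labels))
        try:
            p_auc = roc_auc(p_scores, p_labels)
        except ValidationError:
            p_auc = None
        metrics_of[f"patient_{patient_method}"] = {
            "sensitivity": sens, "specificity": spec, "accuracy": acc, "auc": p_auc,
        }
        for s, pred, score in zip(val_ps, p_preds, p_scores):
            patient_rows.append(
                dict(fold=fold, patient_id=s.patient_id, label=s.label,
                     pred=pred, score=score, mean_p_mcn=float(s.p_mcn.mean()))
            )

        for name, m in metrics_of.items():
            fold_rows.setdefault(name, []).append(m)

    reports = {name: aggregate_folds(rows) for name, rows in fold_rows.items()}
    return ExperimentResult(
        fold_assignment=folds,
        slice_scores=pd.concat(slice_rows, ignore_index=True),
        patient_scores=pd.DataFrame(patient_rows),
        reports=reports,
        loss_traces=pd.concat(trace_rows, ignore_index=True),
        leakage_audit=pd.DataFrame(audit_rows),
    )
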