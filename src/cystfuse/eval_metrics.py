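"""Outcome measures, cross-validation and cohort summaries.

MCN is the positive class throughout: sensitivity = True-MCN / (True-MCN +
False-SCN), specificity = True-SCN / (True-SCN + False-MCN), accuracy =
(True-MCN + True-SCN) / all. The ROC is swept over all score thresholds and
AUC is its trapezoidal area, which equals the pairwise Mann-Whitney
statistic (ties counting one half).

Cross-validation is stratified at the patient level: all slices of a patient
stay in one fold and per-fold class counts differ from perfect
proportionality by at most one patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    DECISION_THRESHOLD,
    LABELS,
    MODALITIES,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "auc")


@dataclass
class ConfusionCounts:
    """Counts with MCN positive: (True-MCN, False-SCN, True-SCN, False-MCN)."""

    true_mcn: int
    false_scn: int
    true_scn: int
    false_mcn: int

    def __post_init__(self) -> None:
        for name in ("true_mcn", "false_scn", "true_scn", "false_mcn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.true_mcn + self.false_scn + self.true_scn + self.false_mcn


def confusion(preds: Sequence[str], labels: Sequence[str]) -> ConfusionCounts:
    """Tally predictions against labels (strings 'SCN'/'MCN')."""
    if len(preds) != len(labels):
        raise ValidationError(f"length mismatch: {len(preds)} preds vs {len(labels)} labels")
    tm = fs = ts = fm = 0
    for p, l in zip(preds, labels):
        if p not in LABELS or l not in LABELS:
            raise ValidationError(f"labels must be in {LABELS}, got ({p!r}, {l!r})")
        if l == POSITIVE_LABEL:
            if p == POSITIVE_LABEL:
                tm += 1
            else:
                fs += 1
        else:
            if p == NEGATIVE_LABEL:
                ts += 1
            else:
                fm += 1
    return ConfusionCounts(true_mcn=tm, false_scn=fs, true_scn=ts, false_mcn=fm)


def sens_spec_acc(c: ConfusionCounts) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Sensitivity, specificity, accuracy; undefined metrics come back None."""
    n_pos = c.true_mcn + c.false_scn
    n_neg = c.true_scn + c.false_mcn
    sens = c.true_mcn / n_pos if n_pos > 0 else None
    spec = c.true_scn / n_neg if n_neg > 0 else None
    if sens is None:
        logger.warning("sensitivity undefined: no MCN cases")
    if spec is None:
        logger.warning("specificity undefined: no SCN cases")
    acc = (c.true_mcn + c.true_scn) / c.total if c.total > 0 else None
    return sens, spec, acc


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """AUC by full threshold sweep + trapezoidal integration.

    Numerically identical (to ~1e-15) to the pairwise statistic
    ``(#[s_pos > s_neg] + 0.5 #[s_pos = s_neg]) / (P * N)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if l == POSITIVE_LABEL else 0 for l in labels])
    if len(scores) != len(y):
        raise ValidationError("scores and labels must have equal length")
    P, N = int(y.sum()), int((1 - y).sum())
    if P == 0 or N == 0:
        raise ValidationError("roc_auc needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], y[order]
    # Working points at each distinct threshold value.
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])
    tp = np.concatenate([[0], np.cumsum(y_sorted)[cut]])
    fp = np.concatenate([[0], np.cumsum(1 - y_sorted)[cut]])
    return float(np.trapezoid(tp / P, fp / N))


@dataclass
class FoldAssignment:
    """Patient -> fold mapping from a stratified patient-level split."""

    assignment: Mapping[str, int]
    k: int

    def fold_patients(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]

    def folds(self) -> list[list[str]]:
        return [self.fold_patients(f) for f in range(self.k)]


def make_folds(
    patients: Sequence[str], labels: Sequence[str], k: int = 4, seed: int = 0
) -> FoldAssignment:
    """Seeded stratified patient-level k-fold split.

    Within each class, patients are shuffled and dealt round-robin so per-fold
    class counts differ from perfect proportionality by at most 1.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if len(patients) != len(labels) or len(set(patients)) != len(patients):
        raise ValidationError("patients must be unique and match labels in length")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in LABELS:
        members = [p for p, l in zip(patients, labels) if l == cls]
        if len(members) < k:
            raise ValidationError(
                f"class {cls!r} has {len(members)} patients; need at least k={k}"
            )
        order = rng.permutation(len(members))
        for i, j in enumerate(order):
            assignment[members[j]] = i % k
    assignment = {p: assignment[p] for p in patients}
    return FoldAssignment(assignment=assignment, k=k)


@dataclass
class MetricReport:
    """Per-fold metrics plus mean, sample sd, min and max across folds."""

    per_fold: pd.DataFrame  # one row per fold, columns = metric names

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for col in self.per_fold.columns:
            vals = self.per_fold[col].dropna().to_numpy(dtype=float)
            n_missing = int(self.per_fold[col].isna().sum())
            if n_missing:
                logger.warning("metric %s missing in %d fold(s); excluded from mean", col, n_missing)
            if len(vals) == 0:
                rows.append(dict(metric=col, mean=np.nan, sd=np.nan, min=np.nan, max=np.nan))
                continue
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                dict(metric=col, mean=float(vals.mean()), sd=sd,
                     min=float(vals.min()), max=float(vals.max()))
            )
        return pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        agg = self.aggregate()
        lines = []
        for metric, row in agg.iterrows():
            lines.append(
                f"{metric}: {row['mean']:.3f} ± {row['sd']:.3f} "
                f"[{row['min']:.3f}, {row['max']:.3f}]"
            )
        return "\n".join(lines)


def aggregate_folds(per_fold_metrics: Sequence[Mapping[str, Optional[float]]]) -> MetricReport:
    """Build a MetricReport from a list of per-fold metric dicts."""
    if len(per_fold_metrics) == 0:
        raise ValidationError("need at least one fold")
    df = pd.DataFrame(list(per_fold_metrics), dtype=float)
    df.index.name = "fold"
    return MetricReport(per_fold=df)


@dataclass
class CohortSummary:
    per_class: pd.DataFrame
    tests: pd.DataFrame

    def summary(self) -> str:
        return (
            "Cohort characteristics\n======================\n"
            + self.per_class.to_string()
            + "\n\nBetween-class tests (package defaults, not prescribed):\n"
            + self.tests.to_string(index=False)
        )


def cohort_summary(patient_table: pd.DataFrame) -> CohortSummary:
    """Per-class descriptive statistics and between-class tests.

    Expects columns ``label`` (required), ``sex`` ('M'/'F'), ``age`` and
    ``tumor_size`` (optional). Test choices — Welch t (age), chi-square with
    continuity correction (sex), Mann-Whitney U (size) — are package defaults
    and flagged as such in the output.
    """
    if "label" not in patient_table.columns:
        raise ValidationError("patient table must have a 'label' column")
    rows = {}
    for cls in LABELS:
        sub = patient_table[patient_table["label"] == cls]
        row: dict[str, object] = {"n": len(sub)}
        if "sex" in sub.columns:
            males = int((sub["sex"] == "M").sum())
            females = int((sub["sex"] == "F").sum())
            row["males"] = males
            row["females"] = females
            row["male_to_female"] = round(males / females, 2) if females else np.nan
        if "age" in sub.columns:
            row["age_mean"] = float(sub["age"].mean())
            row["age_sd"] = float(sub["age"].std(ddof=1))
        if "tumor_size" in sub.columns:
            row["size_median"] = float(sub["tumor_size"].median())
            row["size_q25"] = float(sub["tumor_size"].quantile(0.25))
            row["size_q75"] = float(sub["tumor_size"].quantile(0.75))
        rows[cls] = row
    per_class = pd.DataFrame(rows).T

    tests = []
    scn = patient_table[patient_table["label"] == NEGATIVE_LABEL]
    mcn = patient_table[patient_table["label"] == POSITIVE_LABEL]
    if "age" in patient_table.columns and len(scn) > 1 and len(mcn) > 1:
        t = stats.ttest_ind(scn["age"], mcn["age"], equal_var=False)
        tests.append(dict(variable="age", test="Welch t-test", p_value=float(t.pvalue)))
    if "sex" in patient_table.columns:
        table = pd.crosstab(patient_table["label"], patient_table["sex"])
        if table.shape == (2, 2):
            chi2 = stats.chi2_contingency(table.to_numpy(), correction=True)
            tests.append(
                dict(variable="sex", test="chi-square (continuity-corrected)",
                     p_value=float(chi2.pvalue))
            )
    if "tumor_size" in patient_table.columns and len(scn) > 0 and len(mcn) > 0:
        u = stats.mannwhitneyu(scn["tumor_size"], mcn["tumor_size"], alternative="two-sided")
        tests.append(dict(variable="tumor_size", test="Mann-Whitney U", p_value=float(u.pvalue)))
    tests_df = pd.DataFrame(tests, columns=["variable", "test", "p_value"])
    return CohortSummary(per_class=per_class, tests=tests_df)
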