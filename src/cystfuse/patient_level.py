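"""Slice-to-patient and modality-to-result aggregation.

A trained network scores individual axial slices; clinical use needs one
diagnosis per patient. Three aggregators are provided:

* modality majority voting over the seven secondary outputs of one slice
  ("average results", a result-level modality fusion);
* slice majority voting at threshold 0.5 (mean-probability tie-break,
  exact 0.5 mapping to MCN — the malignant-leaning class);
* an RBF-kernel SVM over a 9-dimensional summary of a patient's slice
  probabilities, fitted on training-fold patients only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .constants import DECISION_THRESHOLD, LABELS, NEGATIVE_LABEL, POSITIVE_LABEL
from .errors import ValidationError
from .fusion_net import DiagnosisProb

N_MOD = 7
FEATURE_NAMES = (
    "mean", "sd", "min", "max", "median", "q25", "q75", "frac_above_half", "log1p_n",
)


@dataclass
class PatientSliceScores:
    """All slice-level p(MCN) values of one patient."""

    patient_id: str
    p_mcn: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.p_mcn = np.asarray(self.p_mcn, dtype=float).ravel()
        if self.p_mcn.size == 0:
            raise ValidationError(f"patient {self.patient_id!r} has no slice scores")
        if self.p_mcn.min() < 0 or self.p_mcn.max() > 1:
            raise ValidationError("slice probabilities must lie in [0, 1]")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"invalid label {self.label!r}")


def modality_majority_vote(secondary: Sequence[DiagnosisProb]) -> str:
    """Majority vote of the seven per-modality outputs of one slice.

    Each modality votes MCN iff its p(MCN) >= 0.5; with seven voters a tie is
    impossible.
    """
    if len(secondary) != N_MOD:
        raise ValidationError(f"expected exactly {N_MOD} modality outputs, got {len(secondary)}")
    votes = sum(1 for s in secondary if s.p_mcn >= DECISION_THRESHOLD)
    return POSITIVE_LABEL if votes > N_MOD // 2 else NEGATIVE_LABEL


def patient_vote(scores: PatientSliceScores) -> str:
    """Majority vote over a patient's slice predictions.

    On an exact vote tie the mean p(MCN) decides, with exactly 0.5 mapping to
    MCN.
    """
    votes_mcn = int((scores.p_mcn >= DECISION_THRESHOLD).sum())
    votes_scn = scores.p_mcn.size - votes_mcn
    if votes_mcn > votes_scn:
        return POSITIVE_LABEL
    if votes_mcn < votes_scn:
        return NEGATIVE_LABEL
    return POSITIVE_LABEL if scores.p_mcn.mean() >= DECISION_THRESHOLD else NEGATIVE_LABEL


def build_patient_feature(scores: PatientSliceScores) -> np.ndarray:
    """9-vector summary of a patient's slice probabilities (see FEATURE_NAMES)."""
    p = scores.p_mcn
    return np.array(
        [
            p.mean(),
            p.std(ddof=0),
            p.min(),
            p.max(),
            np.median(p),
            np.quantile(p, 0.25),
            np.quantile(p, 0.75),
            float((p > DECISION_THRESHOLD).mean()),
            np.log1p(p.size),
        ]
    )


class SvmAggregator:
    """RBF-SVM over standardized patient features.

    Standardization parameters and the SVM itself are learned only from the
    training-fold patients handed to :meth:`fit`; the decision-function score
    is oriented so larger values favour MCN.
    """

    def __init__(self, C: float = 1.0, gamma: str | float = "scale") -> None:
        self._pipe = Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(kernel="rbf", C=C, gamma=gamma))]
        )
        self.fitted = False

    def fit(self, features: np.ndarray, labels: Sequence[str]) -> "SvmAggregator":
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or len(features) != len(labels):
            raise ValidationError("features must be (n_patients, n_features) matching labels")
        if len(features) < 2:
            raise ValidationError("need at least 2 training patients")
        y = np.array([1 if l == POSITIVE_LABEL else 0 for l in labels])
        if len(np.unique(y)) < 2:
            raise ValidationError("training set must contain both classes")
        self._pipe.fit(features, y)
        self.fitted = True
        return self

    def predict(self, feature: np.ndarray) -> tuple[str, float]:
        """Predict one patient; returns (label, continuous score for ROC)."""
        if not self.fitted:
            raise ValidationError("aggregator is not fitted")
        feature = np.atleast_2d(np.asarray(feature, dtype=float))
        score = float(self._pipe.decision_function(feature)[0])
        label = POSITIVE_LABEL if score >= 0 else NEGATIVE_LABEL
        return label, score


def svm_patient_fit(
    train_features: np.ndarray, train_labels: Sequence[str], C: float = 1.0,
    gamma: str | float = "scale",
) -> SvmAggregator:
    return SvmAggregator(C=C, gamma=gamma).fit(train_features, train_labels)


def svm_patient_predict(aggregator: SvmAggregator, feature: np.ndarray) -> tuple[str, float]:
    return aggregator.predict(feature)
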