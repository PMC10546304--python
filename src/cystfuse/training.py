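"""Losses and end-to-end training.

The training objective for one slice pack is::

    L = CE(main, y)
        + lambda_aux        * sum_m CE(secondary_m, y)
        + lambda_content    * L_content
        + lambda_appearance * L_appearance

where CE is the two-class cross-entropy (MCN is the positive class) and the
last two terms are the feature-disentanglement constraints:

* **content consistency** pulls the shared content parts of the seven
  modality features together: the mean squared deviation of each content
  vector from the across-modality mean, normalized by ``7 * (D - L_a)`` so
  it is comparable across feature sizes; zero iff all content vectors agree.
* **appearance separation** pushes the modality-specific appearance parts
  apart: the mean squared cosine similarity over the 21 unordered modality
  pairs (zero-vector pairs count 0), bounded in [0, 1] and minimized by
  pairwise orthogonality.

:class:`FusionModel` packages data plus configuration; ``fit()`` returns a
:class:`FusionFitResults` carrying the trained network, the per-epoch loss
trace and prediction helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import nn
from .constants import LABELS, MODALITIES, POSITIVE_LABEL
from .errors import ConfigurationError, ValidationError
from .fusion_net import DiagnosisProb, FeatureSet, FusionNetwork, ModelConfig
from .preprocess import SlicePack

logger = logging.getLogger(__name__)

N_MOD = len(MODALITIES)
_EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    lambda_aux: float = 1.0
    lambda_content: float = 0.1
    lambda_appearance: float = 0.1

    def __post_init__(self) -> None:
        if min(self.lambda_aux, self.lambda_content, self.lambda_appearance) < 0:
            raise ConfigurationError("loss weights must be nonnegative")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError("optimizer must be 'adam' or 'sgd'")


def _as_matrix(fs: Union[FeatureSet, np.ndarray], L_a: Optional[int]) -> tuple[np.ndarray, int]:
    if isinstance(fs, FeatureSet):
        return np.asarray(fs.features, dtype=np.float64), fs.L_a if L_a is None else L_a
    m = np.asarray(fs, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValidationError(f"expected (M>=2, D) feature matrix, got shape {m.shape}")
    if L_a is None:
        raise ValidationError("L_a required when passing a raw feature matrix")
    return m, L_a


def content_consistency_loss(fs: Union[FeatureSet, np.ndarray], L_a: Optional[int] = None) -> float:
    """Variance-to-mean penalty on the shared content parts.

    ``L_c = (1 / (M * Dc)) * sum_m ||c_m - c_bar||^2`` with ``Dc = D - L_a``;
    zero iff all content vectors are equal. Returns 0 with a warning when the
    content part is empty (``L_a = D``).
    """
    f, L_a = _as_matrix(fs, L_a)
    M, D = f.shape
    if L_a >= D:
        logger.warning("content_consistency_loss: empty content part (L_a = D); returning 0")
        return 0.0
    c = f[:, L_a:]
    cbar = c.mean(axis=0)
    return float(((c - cbar) ** 2).sum() / (M * (D - L_a)))


def content_consistency_grad(feats: np.ndarray, L_a: int) -> np.ndarray:
    """Gradient of the content loss w.r.t. a (B, 7, D) feature batch (mean over B)."""
    B, M, D = feats.shape
    g = np.zeros_like(feats, dtype=np.float64)
    if L_a >= D:
        return g
    c = feats[:, :, L_a:].astype(np.float64)
    cbar = c.mean(axis=1, keepdims=True)
    g[:, :, L_a:] = 2.0 * (c - cbar) / (M * (D - L_a)) / B
    return g


def appearance_separation_loss(fs: Union[FeatureSet, np.ndarray], L_a: Optional[int] = None) -> float:
    """Mean squared cosine similarity over the 21 unordered modality pairs.

    Bounded in [0, 1]; zero when all appearance vectors are pairwise
    orthogonal (or zero), one when they are all parallel. Returns 0 with a
    warning when the appearance part is empty (``L_a = 0``).
    """
    f, L_a = _as_matrix(fs, L_a)
    M = f.shape[0]
    if L_a <= 0:
        logger.warning("appearance_separation_loss: empty appearance part (L_a = 0); returning 0")
        return 0.0
    a = f[:, :L_a]
    norms = np.linalg.norm(a, axis=1)
    total = 0.0
    n_pairs = M * (M - 1) // 2
    for i in range(M):
        for j in range(i + 1, M):
            if norms[i] < _EPS or norms[j] < _EPS:
                continue
            cos = float(a[i] @ a[j] / (norms[i] * norms[j]))
            total += cos * cos
    return total / n_pairs


def appearance_separation_grad(feats: np.ndarray, L_a: int) -> np.ndarray:
    """Gradient of the appearance loss w.r.t. a (B, 7, D) feature batch (mean over B)."""
    B, M, D = feats.shape
    g = np.zeros_like(feats, dtype=np.float64)
    if L_a <= 0:
        return g
    n_pairs = M * (M - 1) // 2
    a = feats[:, :, :L_a].astype(np.float64)
    norms = np.linalg.norm(a, axis=2)  # (B, M)
    for i in range(M):
        for j in range(i + 1, M):
            ni, nj = norms[:, i], norms[:, j]
            ok = (ni > _EPS) & (nj > _EPS)
            if not ok.any():
                continue
            dot = (a[:, i] * a[:, j]).sum(axis=1)
            inv = np.zeros(B)
            inv[ok] = 1.0 / (ni[ok] ** 2 * nj[ok] ** 2)
            # d(cos^2)/da_i = 2 dot / (|a_i|^2 |a_j|^2) * (a_j - dot * a_i / |a_i|^2)
            coef = 2.0 * dot * inv
            with np.errstate(invalid="ignore", divide="ignore"):
                ai_term = np.where(ok[:, None], (dot / np.maximum(ni**2, _EPS))[:, None] * a[:, i], 0.0)
            gi = coef[:, None] * (a[:, j] - ai_term)
            gj = coef[:, None] * (a[:, i] - np.where(ok[:, None], (dot / np.maximum(nj**2, _EPS))[:, None] * a[:, j], 0.0))
            gi[~ok] = 0.0
            gj[~ok] = 0.0
            g[:, i, :L_a] += gi
            g[:, j, :L_a] += gj
    return g / (n_pairs * B)


def _label_index(label: str) -> int:
    if label not in LABELS:
        raise ValidationError(f"invalid label {label!r}; expected one of {LABELS}")
    return 1 if label == POSITIVE_LABEL else 0


def cross_entropy(prob: Union[DiagnosisProb, Sequence[float]], label: str) -> float:
    """Two-class cross-entropy with probability clamping at 1e-12."""
    idx = _label_index(label)
    if isinstance(prob, DiagnosisProb):
        p = (prob.p_scn, prob.p_mcn)
    else:
        p = tuple(float(v) for v in prob)
    return float(-np.log(max(p[idx], _EPS)))


def total_loss(
    main: DiagnosisProb,
    secondary: Optional[Sequence[DiagnosisProb]],
    label: str,
    fs: Optional[FeatureSet],
    L_a: int,
    w: LossWeights,
) -> float:
    """Composite training loss for one slice pack (see module docstring)."""
    loss = cross_entropy(main, label)
    if secondary is not None and w.lambda_aux > 0:
        loss += w.lambda_aux * sum(cross_entropy(s, label) for s in secondary)
    if fs is not None:
        if w.lambda_content > 0:
            loss += w.lambda_content * content_consistency_loss(fs, L_a)
        if w.lambda_appearance > 0:
            loss += w.lambda_appearance * appearance_separation_loss(fs, L_a)
    return loss


def packs_to_arrays(packs: Sequence[SlicePack]) -> tuple[np.ndarray, np.ndarray]:
    """Stack labeled slice packs into (X (N,7,80,80) float32, y (N,) int)."""
    if any(p.label is None for p in packs):
        raise ValidationError("all training packs must carry a label")
    X = np.stack([p.slices for p in packs]).astype(np.float32)
    y = np.array([_label_index(p.label) for p in packs], dtype=np.int64)
    return X, y


class FusionModel:
    """A fusion classifier bound to a set of labeled slice packs.

    Parameters
    ----------
    packs : labeled SlicePacks (the training set)
    model_config : architecture settings
    train_config : optimisation settings
    loss_weights : weighting of the auxiliary and constraint terms
    """

    def __init__(
        self,
        packs: Sequence[SlicePack],
        model_config: ModelConfig = ModelConfig(),
        train_config: TrainConfig = TrainConfig(),
        loss_weights: LossWeights = LossWeights(),
    ) -> None:
        if len(packs) == 0:
            raise ValidationError("training set must be nonempty")
        self.X, self.y = packs_to_arrays(packs)
        self.model_config = model_config
        self.train_config = train_config
        self.loss_weights = loss_weights

    # -- loss evaluation -------------------------------------------------------

    def _batch_losses(self, net: FusionNetwork, X: np.ndarray, y: np.ndarray) -> dict[str, float]:
        state = net.forward(X)
        w = self.loss_weights
        c = self.model_config
        main_ce, _ = nn.cross_entropy_from_logits(state.main_logits, y)
        parts = {"main_ce": main_ce, "aux_ce": 0.0, "content": 0.0, "appearance": 0.0}
        if state.sec_logits is not None and w.lambda_aux > 0:
            aux = 0.0
            for m in range(N_MOD):
                ce, _ = nn.cross_entropy_from_logits(state.sec_logits[:, m], y)
                aux += ce
            parts["aux_ce"] = aux
        if state.features is not None and c.method == "DIS":
            if w.lambda_content > 0:
                parts["content"] = float(
                    np.mean(
                        [content_consistency_loss(f, c.L_a) for f in state.features]
                    )
                )
            if w.lambda_appearance > 0:
                parts["appearance"] = float(
                    np.mean(
                        [appearance_separation_loss(f, c.L_a) for f in state.features]
                    )
                )
        parts["total"] = (
            parts["main_ce"]
            + w.lambda_aux * parts["aux_ce"]
            + w.lambda_content * parts["content"]
            + w.lambda_appearance * parts["appearance"]
        )
        return parts

    def _dataset_loss(self, net: FusionNetwork, batch_size: int = 64) -> dict[str, float]:
        n = len(self.y)
        acc: dict[str, float] = {}
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            parts = self._batch_losses(net, self.X[sl], self.y[sl])
            wgt = (sl.stop - sl.start) / n
            for k, v in parts.items():
                acc[k] = acc.get(k, 0.0) + v * wgt
        return acc

    # -- fitting ---------------------------------------------------------------

    def fit(self, seed: Optional[int] = None) -> "FusionFitResults":
        """Train the network; returns results with the per-epoch loss trace."""
        tc = self.train_config
        seed = tc.seed if seed is None else seed
        net = FusionNetwork(self.model_config, seed=seed)
        refs = net.param_refs()
        if tc.optimizer == "adam":
            opt: Union[nn.Adam, nn.SGD] = nn.Adam(refs, lr=tc.learning_rate)
        else:
            opt = nn.SGD(refs, lr=tc.learning_rate)
        rng = np.random.default_rng(seed + 1)
        w = self.loss_weights
        c = self.model_config
        n = len(self.y)

        trace_rows = [dict(epoch=0, **self._dataset_loss(net))]
        for epoch in range(1, tc.epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                Xb, yb = self.X[idx], self.y[idx]
                net.zero_grad()
                state = net.forward(Xb)
                _, d_main = nn.cross_entropy_from_logits(state.main_logits, yb)
                d_sec = None
                if state.sec_logits is not None and w.lambda_aux > 0:
                    d_sec = np.zeros_like(state.sec_logits, dtype=np.float32)
                    for m in range(N_MOD):
                        _, g = nn.cross_entropy_from_logits(state.sec_logits[:, m], yb)
                        d_sec[:, m] = w.lambda_aux * g
                d_feat = None
                if state.features is not None and c.method == "DIS":
                    d_feat = np.zeros_like(state.features, dtype=np.float64)
                    if w.lambda_content > 0:
                        d_feat += w.lambda_content * content_consistency_grad(
                            state.features, c.L_a
                        )
                    if w.lambda_appearance > 0:
                        d_feat += w.lambda_appearance * appearance_separation_grad(
                            state.features, c.L_a
                        )
                    d_feat = d_feat.astype(np.float32)
                net.backward(state, d_main, d_sec, d_feat)
                opt.step()
            trace_rows.append(dict(epoch=epoch, **self._dataset_loss(net)))

        trace = pd.DataFrame(trace_rows)
        return FusionFitResults(model=self, network=net, loss_trace=trace)


@dataclass
class FusionFitResults:
    """Outcome of :meth:`FusionModel.fit`."""

    model: FusionModel
    network: FusionNetwork
    loss_trace: pd.DataFrame

    @property
    def final_loss(self) -> float:
        return float(self.loss_trace["total"].iloc[-1])

    def predict_proba(self, packs: Sequence[SlicePack]) -> tuple[np.ndarray, Optional[np.ndarray]]:
        """Main and secondary MCN-vs-SCN probabilities for a list of packs."""
        X = np.stack([p.slices for p in packs]).astype(np.float32)
        return self.network.predict_proba(X)

    def score_slices(self, packs: Sequence[SlicePack]) -> pd.DataFrame:
        """Per-slice p(MCN) table: main output plus one column per modality."""
        main, sec = self.predict_proba(packs)
        rows = {
            "patient_id": [p.patient_id for p in packs],
            "z_index": [p.z_index for p in packs],
            "label": [p.label for p in packs],
            "p_mcn": main[:, 1],
        }
        if sec is not None:
            for m, name in enumerate(MODALITIES):
                rows[f"p_mcn_{name}"] = sec[:, m, 1]
        return pd.DataFrame(rows)

    def training_accuracy(self) -> float:
        main, _ = self.network.predict_proba(self.model.X)
        pred = (main[:, 1] >= 0.5).astype(int)
        return float((pred == self.model.y).mean())

    def summary(self) -> str:
        c = self.model.model_config
        t = self.model.train_config
        lines = [
            "Fusion model fit",
            "================",
            f"method: {c.method} (backbone={c.backbone}, D={c.D}, L_a={c.L_a})",
            f"training slices: {len(self.model.y)}  "
            f"(MCN {int(self.model.y.sum())} / SCN {int((1 - self.model.y).sum())})",
            f"epochs: {t.epochs}  batch: {t.batch_size}  lr: {t.learning_rate}  "
            f"optimizer: {t.optimizer}",
            f"initial loss: {self.loss_trace['total'].iloc[0]:.4f}  "
            f"final loss: {self.final_loss:.4f}",
            f"training accuracy: {self.training_accuracy():.3f}",
            "",
            "loss trace (per epoch):",
            self.loss_trace.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def train_model(
    cohort_packs: Sequence[SlicePack],
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    loss_weights: LossWeights = LossWeights(),
) -> tuple[FusionNetwork, pd.DataFrame]:
    """Convenience wrapper: fit a model and return (network, loss trace)."""
    results = FusionModel(cohort_packs, model_config, train_config, loss_weights).fit()
    return results.network, results.loss_trace
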