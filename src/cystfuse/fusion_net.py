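"""Multi-branch fusion network.

One convolutional backbone per modality produces a D-dimensional feature
vector per slice; a fusion block combines the seven vectors; a two-layer
fully-connected classifier yields the diagnosis probabilities. Per-modality
secondary heads classify each modality's feature alone — they supervise the
branches during training and provide single-modality evaluation.

Fusion strategies over feature vectors ``f_1..f_7`` (canonical order):

* ``SUM`` — elementwise sum, length D.
* ``MAX`` — elementwise max, length D.
* ``CAT`` — concatenation, length 7 D.
* ``DIS`` — feature disentanglement: the first ``L_a`` coordinates of each
  vector form the modality-specific *appearance* part (concatenated), the
  remaining ``D - L_a`` the shared *content* part (summed); length
  ``7 L_a + (D - L_a)``. ``L_a = 0`` reduces exactly to SUM, ``L_a = D`` to CAT.
* ``IMG-F`` — image-level (early) fusion: the seven slices are stacked into a
  7-channel image fed to a single backbone; no secondary outputs exist.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .constants import CROP_SIZE, MODALITIES
from .errors import ConfigurationError, ValidationError
from .preprocess import SlicePack

FUSION_METHODS = ("SUM", "MAX", "CAT", "DIS", "IMG-F")
N_MOD = len(MODALITIES)
_CHECKPOINT_VERSION = 1


@dataclass
class FeatureSet:
    """Seven per-modality feature vectors with the DIS partition.

    ``features`` has shape (7, D); rows follow the canonical modality order.
    The first ``L_a`` columns are the appearance part, the rest the content
    part.
    """

    features: np.ndarray
    L_a: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.ndim != 2 or self.features.shape[0] != N_MOD:
            raise ValidationError(
                f"features must have shape (7, D), got {self.features.shape}"
            )
        if not (0 <= self.L_a <= self.D):
            raise ValidationError(f"L_a must be in [0, {self.D}], got {self.L_a}")

    @property
    def D(self) -> int:
        return self.features.shape[1]

    @property
    def appearance(self) -> np.ndarray:
        return self.features[:, : self.L_a]

    @property
    def content(self) -> np.ndarray:
        return self.features[:, self.L_a :]


@dataclass
class DiagnosisProb:
    """Normalized two-class diagnosis probabilities."""

    p_scn: float
    p_mcn: float

    def __post_init__(self) -> None:
        for p in (self.p_scn, self.p_mcn):
            if not (-1e-6 <= p <= 1.0 + 1e-6):
                raise ValidationError(f"probability out of range: {p}")
        if abs(self.p_scn + self.p_mcn - 1.0) > 1e-6:
            raise ValidationError(
                f"probabilities must sum to 1, got {self.p_scn + self.p_mcn}"
            )


def diagnosis_from_logits(logits: Sequence[float]) -> DiagnosisProb:
    """Two-way softmax over (SCN, MCN) logits."""
    p = nn.softmax(np.asarray(logits, dtype=np.float64))
    return DiagnosisProb(p_scn=float(p[0]), p_mcn=float(p[1]))


def fused_length(method: str, D: int, L_a: int = 0) -> int:
    if method in ("SUM", "MAX", "IMG-F"):
        return D
    if method == "CAT":
        return N_MOD * D
    if method == "DIS":
        return N_MOD * L_a + (D - L_a)
    raise ConfigurationError(f"unknown fusion method {method!r}")


def _check(fs: FeatureSet) -> FeatureSet:
    if not isinstance(fs, FeatureSet):
        fs = FeatureSet(np.asarray(fs))
    return fs


def fuse_sum(fs: FeatureSet) -> np.ndarray:
    """Elementwise sum over the seven modality vectors."""
    return _check(fs).features.sum(axis=0)


def fuse_max(fs: FeatureSet) -> np.ndarray:
    """Elementwise maximum over the seven modality vectors."""
    return _check(fs).features.max(axis=0)


def fuse_cat(fs: FeatureSet) -> np.ndarray:
    """Concatenation in canonical modality order."""
    return _check(fs).features.reshape(-1)


def fuse_dis(fs: FeatureSet, L_a: Optional[int] = None) -> np.ndarray:
    """Disentangled fusion: concatenated appearance parts + summed content."""
    fs = _check(fs)
    if L_a is None:
        L_a = fs.L_a
    if not (0 <= L_a <= fs.D):
        raise ValidationError(f"L_a must be in [0, {fs.D}], got {L_a}")
    appearance = fs.features[:, :L_a].reshape(-1)
    content = fs.features[:, L_a:].sum(axis=0)
    return np.concatenate([appearance, content])


@dataclass(frozen=True)
class ModelConfig:
    """Architecture settings.

    ``backbone``: "tiny" (three small conv blocks on the native 80x80 slice,
    feature size ``D`` configurable) or "alexnet-conv" (the five-conv-block
    AlexNet body on a 224x224 resize of the slice replicated to 3 channels,
    global average pooling to D=256). ``pretrained_weights`` optionally names
    an ``.npz`` checkpoint to initialise from (off by default).
    """

    backbone: str = "tiny"
    D: int = 16
    method: str = "DIS"
    L_a: int = 8
    hidden: int = 32
    shared_backbone: bool = False
    shared_secondary_heads: bool = False
    content_agg: str = "sum"  # or "mean"
    pretrained_weights: Optional[str] = None

    def __post_init__(self) -> None:
        if self.method not in FUSION_METHODS:
            raise ConfigurationError(f"method must be one of {FUSION_METHODS}")
        if self.backbone not in ("tiny", "alexnet-conv"):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")
        if self.backbone == "alexnet-conv" and self.D != 256:
            raise ConfigurationError("alexnet-conv backbone produces D=256")
        if not (0 <= self.L_a <= self.D):
            raise ConfigurationError(f"L_a must be in [0, {self.D}]")
        if self.content_agg not in ("sum", "mean"):
            raise ConfigurationError("content_agg must be 'sum' or 'mean'")

    @property
    def fused_len(self) -> int:
        return fused_length(self.method, self.D, self.L_a)


def build_tiny_backbone(rng: np.random.Generator, in_ch: int, D: int) -> nn.Sequential:
    return nn.Sequential(
        [
            nn.Conv2d(in_ch, 8, 3, stride=2, pad=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(8, 16, 3, stride=2, pad=1, rng=rng),
            nn.ReLU(),
            nn.MaxPool2d(2),
            nn.Conv2d(16, D, 3, stride=2, pad=1, rng=rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
        ]
    )


def build_alexnet_conv(rng: np.random.Generator, in_ch: int) -> nn.Sequential:
    """The AlexNet convolutional body with global average pooling to 256."""
    return nn.Sequential(
        [
            nn.Conv2d(in_ch, 64, 11, stride=4, pad=2, rng=rng),
            nn.ReLU(),
            nn.MaxPool2d(3, 2),
            nn.Conv2d(64, 192, 5, stride=1, pad=2, rng=rng),
            nn.ReLU(),
            nn.MaxPool2d(3, 2),
            nn.Conv2d(192, 384, 3, stride=1, pad=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(384, 256, 3, stride=1, pad=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(256, 256, 3, stride=1, pad=1, rng=rng),
            nn.ReLU(),
            nn.MaxPool2d(3, 2),
            nn.GlobalAvgPool(),
        ]
    )


def _build_head(rng: np.random.Generator, n_in: int, hidden: int) -> nn.Sequential:
    return nn.Sequential(
        [nn.Linear(n_in, hidden, rng=rng), nn.ReLU(), nn.Linear(hidden, 2, rng=rng)]
    )


@dataclass
class ForwardState:
    """Cached activations of one forward pass (consumed by ``backward``)."""

    features: Optional[np.ndarray]  # (B, 7, D); None for IMG-F
    fused: np.ndarray  # (B, fused_len)
    main_logits: np.ndarray  # (B, 2)
    sec_logits: Optional[np.ndarray]  # (B, 7, 2); None for IMG-F
    _max_idx: Optional[np.ndarray] = None


class FusionNetwork:
    """The end-to-end slice classifier for one fusion method."""

    ALEXNET_INPUT = 224

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        if c.method == "IMG-F":
            in_ch = N_MOD
            if c.backbone == "tiny":
                self.backbones = [build_tiny_backbone(rng, in_ch, c.D)]
            else:
                self.backbones = [build_alexnet_conv(rng, in_ch)]
        else:
            per_mod_in = 1 if c.backbone == "tiny" else 3
            n_bb = 1 if c.shared_backbone else N_MOD
            builder = (
                (lambda: build_tiny_backbone(rng, per_mod_in, c.D))
                if c.backbone == "tiny"
                else (lambda: build_alexnet_conv(rng, per_mod_in))
            )
            self.backbones = [builder() for _ in range(n_bb)]
        self.main_head = _build_head(rng, c.fused_len, c.hidden)
        if c.method == "IMG-F":
            self.secondary_heads: Optional[list[nn.Sequential]] = None
        else:
            n_heads = 1 if c.shared_secondary_heads else N_MOD
            self.secondary_heads = [_build_head(rng, c.D, c.hidden) for _ in range(n_heads)]
        if c.pretrained_weights:
            self.load_weights(c.pretrained_weights)

    # -- parameter bookkeeping -------------------------------------------------

    def _modules(self) -> list[nn.Sequential]:
        mods = list(self.backbones) + [self.main_head]
        if self.secondary_heads is not None:
            mods += self.secondary_heads
        return mods

    def param_refs(self) -> list[nn.ParamRef]:
        refs: list[nn.ParamRef] = []
        for mod in self._modules():
            refs.extend(mod.param_refs())
        return refs

    def zero_grad(self) -> None:
        for mod in self._modules():
            mod.zero_grad()

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (layer, name) in enumerate(self.param_refs()):
            out[f"p{i:03d}_{name}"] = layer.params[name]
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, (layer, name) in enumerate(self.param_refs()):
            layer.params[name] = np.array(weights[f"p{i:03d}_{name}"], dtype=np.float32)

    def save_weights(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps({"version": _CHECKPOINT_VERSION, "config": asdict(self.config)})
        np.savez(path, __meta__=np.array(meta), **self.get_weights())
        return path

    def load_weights(self, path: str | Path) -> None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"checkpoint not found: {path}")
        data = np.load(path, allow_pickle=False)
        self.set_weights({k: data[k] for k in data.files if k != "__meta__"})

    # -- forward / backward ----------------------------------------------------

    def _backbone_input(self, x: np.ndarray) -> np.ndarray:
        """Adapt (B, C, 80, 80) slices to the backbone's native input."""
        if self.config.backbone == "tiny":
            return x
        s = self.ALEXNET_INPUT
        zoom = (1.0, 1.0, s / x.shape[2], s / x.shape[3])
        x = ndimage.zoom(x, zoom, order=1, grid_mode=True, mode="nearest")
        if x.shape[1] == 1:  # grayscale slice replicated to RGB
            x = np.repeat(x, 3, axis=1)
        return np.ascontiguousarray(x, dtype=np.float32)

    def forward(self, x: np.ndarray) -> ForwardState:
        """Run a batch of slice packs ``x`` of shape (B, 7, 80, 80)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != N_MOD:
            raise ValidationError(f"expected (B, 7, H, W) input, got {x.shape}")
        c = self.config
        if c.method == "IMG-F":
            fused = self.backbones[0].forward(self._backbone_input(x))
            main_logits = self.main_head.forward(fused)
            return ForwardState(features=None, fused=fused,
                                main_logits=main_logits, sec_logits=None)

        b = x.shape[0]
        if c.shared_backbone:
            flat = x.reshape(b * N_MOD, 1, x.shape[2], x.shape[3])
            feats = self.backbones[0].forward(self._backbone_input(flat))
            feats = feats.reshape(b, N_MOD, c.D)
        else:
            cols = []
            for m in range(N_MOD):
                cols.append(
                    self.backbones[m].forward(self._backbone_input(x[:, m : m + 1]))
                )
            feats = np.stack(cols, axis=1)  # (B, 7, D)

        max_idx = None
        if c.method == "SUM":
            fused = feats.sum(axis=1)
        elif c.method == "MAX":
            max_idx = feats.argmax(axis=1)  # (B, D)
            fused = np.take_along_axis(feats, max_idx[:, None, :], axis=1)[:, 0]
        elif c.method == "CAT":
            fused = feats.reshape(b, N_MOD * c.D)
        elif c.method == "DIS":
            app = feats[:, :, : c.L_a].reshape(b, N_MOD * c.L_a)
            content = feats[:, :, c.L_a :]
            agg = content.sum(axis=1) if c.content_agg == "sum" else content.mean(axis=1)
            fused = np.concatenate([app, agg], axis=1)
        else:  # pragma: no cover - guarded by config validation
            raise ConfigurationError(c.method)

        main_logits = self.main_head.forward(fused)
        sec_list = []
        for m in range(N_MOD):
            head = self.secondary_heads[0 if c.shared_secondary_heads else m]
            sec_list.append(head.forward(feats[:, m]))
        sec_logits = np.stack(sec_list, axis=1)
        return ForwardState(features=feats, fused=fused, main_logits=main_logits,
                            sec_logits=sec_logits, _max_idx=max_idx)

    def backward(
        self,
        state: ForwardState,
        d_main_logits: np.ndarray,
        d_sec_logits: Optional[np.ndarray] = None,
        d_features: Optional[np.ndarray] = None,
    ) -> None:
        """Accumulate parameter gradients for one forward pass.

        ``d_features`` carries extra gradients on the per-modality features
        (from the disentanglement constraint losses). Shared-backbone and
        shared-head modes accumulate across branches naturally because every
        branch was evaluated in a single batched forward call.

        Note: with shared modules the layer activation caches hold the batched
        evaluation, so backward must be called exactly once per forward.
        """
        c = self.config
        dfused = self.main_head.backward(d_main_logits.astype(np.float32))
        if c.method == "IMG-F":
            self.backbones[0].backward(dfused)
            return

        b, D = state.features.shape[0], c.D
        dfeats = np.zeros_like(state.features)
        if c.method == "SUM":
            dfeats += dfused[:, None, :]
        elif c.method == "MAX":
            np.put_along_axis(dfeats, state._max_idx[:, None, :], dfused[:, None, :], axis=1)
        elif c.method == "CAT":
            dfeats += dfused.reshape(b, N_MOD, D)
        elif c.method == "DIS":
            La = c.L_a
            dfeats[:, :, :La] += dfused[:, : N_MOD * La].reshape(b, N_MOD, La)
            dcontent = dfused[:, N_MOD * La :]
            if c.content_agg == "mean":
                dcontent = dcontent / N_MOD
            dfeats[:, :, La:] += dcontent[:, None, :]

        if d_sec_logits is not None:
            # Secondary heads were forwarded per modality in order; for a
            # shared head the caches are stale for all but the last modality,
            # so re-forward before each backward.
            for m in range(N_MOD):
                head = self.secondary_heads[0 if c.shared_secondary_heads else m]
                if c.shared_secondary_heads:
                    head.forward(state.features[:, m])
                dfeats[:, m] += head.backward(d_sec_logits[:, m].astype(np.float32))

        if d_features is not None:
            dfeats += d_features

        if c.shared_backbone:
            flat = dfeats.reshape(b * N_MOD, D)
            self.backbones[0].backward(flat)
        else:
            for m in range(N_MOD):
                self.backbones[m].backward(dfeats[:, m])

    # -- inference helpers -----------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> tuple[np.ndarray, Optional[np.ndarray]]:
        """Return (main probs (B, 2), secondary probs (B, 7, 2) or None)."""
        state = self.forward(x)
        main = nn.softmax(state.main_logits.astype(np.float64))
        sec = (
            nn.softmax(state.sec_logits.astype(np.float64))
            if state.sec_logits is not None
            else None
        )
        return main, sec


def backbone_features(slice_2d: np.ndarray, modality: str, network: FusionNetwork) -> np.ndarray:
    """Feature vector of one 80x80 slice through the given modality's branch."""
    slice_2d = np.asarray(slice_2d, dtype=np.float32)
    if slice_2d.shape != (CROP_SIZE, CROP_SIZE):
        raise ValidationError(f"slice must be {CROP_SIZE}x{CROP_SIZE}, got {slice_2d.shape}")
    if modality not in MODALITIES:
        raise ValidationError(f"unknown modality {modality!r}")
    if network.config.method == "IMG-F":
        raise ConfigurationError("IMG-F models have no per-modality branches")
    m = MODALITIES.index(modality)
    bb = network.backbones[0 if network.config.shared_backbone else m]
    x = network._backbone_input(slice_2d[None, None])
    return bb.forward(x)[0]


def classify(fused: np.ndarray, head: nn.Sequential) -> DiagnosisProb:
    """Two-layer fully-connected classifier + softmax on a fused feature."""
    fused = np.asarray(fused, dtype=np.float32)
    logits = head.forward(fused[None])
    return diagnosis_from_logits(logits[0])


def forward_slice(
    pack: SlicePack, network: FusionNetwork
) -> tuple[DiagnosisProb, Optional[tuple[DiagnosisProb, ...]]]:
    """Classify one slice pack; returns (main, per-modality secondary or None)."""
    main, sec = network.predict_proba(pack.slices[None])
    main_p = DiagnosisProb(p_scn=float(main[0, 0]), p_mcn=float(main[0, 1]))
    if sec is None:
        return main_p, None
    sec_p = tuple(
        DiagnosisProb(p_scn=float(sec[0, m, 0]), p_mcn=float(sec[0, m, 1]))
        for m in range(N_MOD)
    )
    return main_p, sec_p
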