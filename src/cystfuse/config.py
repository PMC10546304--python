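"""Run configuration: one YAML document driving the end-to-end workflow."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .errors import ConfigurationError
from .fusion_net import ModelConfig
from .phantoms import PhantomConfig
from .training import LossWeights, TrainConfig


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for ``run_all`` / the ``run-all`` CLI command."""

    out_dir: str = "cystfuse-run"
    n_scn: int = 8
    n_mcn: int = 8
    seed: int = 0
    k_folds: int = 2
    k_slices: int = 3
    n_aug: int = 0
    patient_method: str = "svm"
    log_level: str = "INFO"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.n_scn < 0 or self.n_mcn < 0:
            raise ConfigurationError("cohort counts must be nonnegative")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if self.patient_method not in ("vote", "svm"):
            raise ConfigurationError("patient_method must be 'vote' or 'svm'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML
        return yaml.safe_load(yaml.safe_dump(d))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)

        def build(key, klass, tuple_fields=()):
            if key in d and d[key] is not None:
                sub = dict(d[key])
                for tf in tuple_fields:
                    if tf in sub and isinstance(sub[tf], list):
                        sub[tf] = tuple(sub[tf])
                d[key] = klass(**sub)

        build("phantom", PhantomConfig,
              ("grid_dims", "spacing_mm", "n_cysts_scn", "cyst_radius_scn_mm",
               "mcn_radius_mm", "wall_thickness_mcn_vox", "nodule_count_mcn",
               "septation_count_mcn"))
        if isinstance(d.get("phantom"), PhantomConfig) and isinstance(
            d["phantom"].enhancement_slopes, dict
        ):
            slopes = {k: tuple(v) for k, v in d["phantom"].enhancement_slopes.items()}
            d["phantom"] = dataclasses.replace(d["phantom"], enhancement_slopes=slopes)
        build("model", ModelConfig)
        build("train", TrainConfig)
        build("loss_weights", LossWeights)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})
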