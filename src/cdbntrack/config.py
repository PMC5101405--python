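"""Run configuration with the reference defaults baked in.

The defaults are the tracking configuration used throughout the package:
1,000 particles, 32x32 patches, a long-term buffer of 25 frames, 500
fine-tuning epochs per frame at learning rate 0.1 and momentum 0.5,
layer sparsity targets 0.003 / 0.005. A YAML file may override any
subset; unknown keys and non-positive values are rejected with the field
named.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # architecture
    preset: str = "full"              # "full" | "reduced" | "tiny"
    input_size: int = 32
    channels: int = 1
    # supervised training
    epochs: int = 500                 # fine-tuning epochs (per frame)
    learning_rate: float = 0.1
    momentum: float = 0.5
    batch_size: int = 64
    # greedy CRBM stage
    crbm_epochs: int = 30
    crbm_learning_rate: float = 0.05
    sparsity_weight: float = 50.0
    head_epochs: int = 500
    # tracker
    n_particles: int = 1000
    buffer_size: int = 25             # T, long-term FIFO cap
    n_short_term: int = 10
    n_negatives: int = 100
    sigma_xy: float = 6.0
    scale_sigma_frac: float = 0.02
    ess_fraction: float = 0.5
    update_every: int = 1
    freeze_features: bool = False
    confidence_floor: float = 0.2
    lost_after: int = 5
    # reproducibility / paths
    seed: int = 0
    model_path: str | None = None
    output_dir: str | None = None

    _positive = (
        "input_size", "channels", "epochs", "learning_rate", "momentum",
        "batch_size", "crbm_epochs", "crbm_learning_rate", "head_epochs",
        "n_particles", "buffer_size", "n_short_term", "n_negatives",
        "sigma_xy", "ess_fraction", "update_every", "lost_after",
    )

    def validate(self) -> "RunConfig":
        for name in self._positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive, "
                                 f"got {getattr(self, name)}")
        if self.preset not in ("full", "reduced", "tiny"):
            raise ValueError(f"unknown preset {self.preset!r}")
        return self

    def tracker_kwargs(self) -> dict:
        return dict(
            n_particles=self.n_particles, buffer_size=self.buffer_size,
            n_short_term=self.n_short_term, n_negatives=self.n_negatives,
            epochs_per_frame=self.epochs, learning_rate=self.learning_rate,
            momentum=self.momentum, batch_size=self.batch_size,
            sigma_xy=self.sigma_xy, update_every=self.update_every,
            freeze_features=self.freeze_features,
            confidence_floor=self.confidence_floor, lost_after=self.lost_after,
        )

    def model_kwargs(self) -> dict:
        return dict(
            architecture=self.preset, input_size=self.input_size,
            channels=self.channels, crbm_epochs=self.crbm_epochs,
            crbm_learning_rate=self.crbm_learning_rate,
            sparsity_weight=self.sparsity_weight, head_epochs=self.head_epochs,
            learning_rate=self.learning_rate, momentum=self.momentum,
            batch_size=self.batch_size,
        )


def load_config(path) -> RunConfig:
    """Read a YAML config; unspecified fields keep the reference defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig) if not f.name.startswith("_")}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**raw).validate()
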