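"""Pipeline configuration: defaults, YAML loading, strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Flat configuration spanning synthesis, segmentation, RP rendering,
    the two network stages and training.  Unknown keys are rejected."""

    # synthesis
    synth_duration_s: float = 14.0
    synth_fs: float = 250.0
    synth_mean_hr_bpm: float = 70.0
    synth_noise_sd: float = 0.02
    synth_ectopic_rate: float = 0.15
    # segmentation
    window_s: float = 2.0
    stride_s: float | None = None
    majority_threshold: float = 2.0 / 3.0
    channel: int = 0
    # recurrence plots
    rp_size: int = 224
    rp_m: int = 1
    rp_tau: int = 1
    # networks
    stage1_depth: int = 18
    stage2_depth: int = 50
    stage1_base_width: int = 64
    stage2_base_width: int = 64
    # training
    lr_initial: float = 0.1
    lr_divisor: float = 10.0
    plateau_patience: int = 5
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 30
    horizontal_flip: bool = True
    translation_max_px: int = 16
    rgb_jitter_sd: float = 0.05
    # splits
    split_fractions: tuple = (0.70, 0.15, 0.15)
    cv_folds: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, and overrides.

    Raises ``ValueError`` on keys that are not config fields.
    """
    values: dict = {}
    if path:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path!r} must hold a mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(values) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "split_fractions" in values:
        values["split_fractions"] = tuple(values["split_fractions"])
    return PipelineConfig(**values)
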