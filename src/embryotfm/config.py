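"""Run configuration: a single YAML document with per-stage sections.

Reproducibility of the many parameters the imaging protocol leaves
unstated (PIV window, λ policy, peak prominence, thresholds) is the
pipeline's core discipline: every stage reads its parameters from one
``RunConfig`` whose hash is embedded in every output table.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, List, Optional, Union

import yaml

__all__ = ["RunConfig", "validate_config"]


@dataclass(frozen=True)
class RunConfig:
    # substrate
    youngs_modulus: float = 1000.0   # Pa
    poisson_ratio: float = 0.5
    thickness: float = 150.0         # μm

    # acquisition
    pixel_size: float = 0.5          # μm/px
    frame_interval: float = 5.0      # min between TFM frames
    migration_interval: float = 20.0  # min between migration frames
    expected_peak_period: Optional[float] = None  # min, if asserted a priori

    # registration
    reference_frame: int = 0
    template: Optional[List[int]] = None  # (x, y, w, h)
    score_floor: float = 0.2

    # displacement (PIV)
    window_size: int = 32            # px
    overlap: float = 0.75
    outlier_threshold: float = 3.0

    # traction (FTTC)
    lambda_strategy: str = "gcv"     # fixed | gcv | lcurve | noise
    lambda_value: Optional[float] = None
    filter_mode: str = "tikhonov"
    pad_factor: int = 1

    # dynamics
    peak_prominence_iqr_fraction: float = 0.2
    association_window: float = 5.0  # min

    # simulation / reproducibility
    seed: int = 0
    n_frames: int = 3

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_overrides(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def validate_config(config: RunConfig) -> List[str]:
    """Report out-of-range parameters and sampling (Nyquist) warnings.

    Returns a list of human-readable issues; an empty list means the
    configuration is clean.  Validation reports, it never mutates.
    """
    issues: List[str] = []
    if config.youngs_modulus <= 0:
        issues.append("youngs_modulus must be positive")
    if not 0.0 <= config.poisson_ratio <= 0.5:
        issues.append("poisson_ratio out of range [0, 0.5]")
    if config.pixel_size <= 0:
        issues.append("pixel_size must be positive")
    if config.window_size < 16:
        issues.append("window_size below the 16 px minimum")
    if not 0.0 <= config.overlap < 1.0:
        issues.append("overlap out of range [0, 1)")
    if config.lambda_strategy not in ("fixed", "gcv", "lcurve", "noise"):
        issues.append(f"unknown lambda_strategy {config.lambda_strategy!r}")
    if config.lambda_strategy == "fixed" and config.lambda_value is None:
        issues.append("fixed lambda_strategy requires lambda_value")
    if config.filter_mode not in ("tikhonov", "wiener"):
        issues.append(f"unknown filter_mode {config.filter_mode!r}")
    if config.frame_interval <= 0:
        issues.append("frame_interval must be positive")
    elif (config.expected_peak_period is not None
          and config.expected_peak_period < 3.0 * config.frame_interval):
        issues.append(
            f"Nyquist warning: expected peak period "
            f"({config.expected_peak_period:g} min) is below 3x the frame "
            f"interval ({config.frame_interval:g} min)"
        )
    return issues
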