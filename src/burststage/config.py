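"""Analysis configuration with YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigurationError
from .staging import DEFAULT_COFACTOR, DEFAULT_STAGE_BOUNDARIES


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs, serialisable round-trip stable.

    Units: thresholds and intensities in arbitrary units, times in minutes.
    """

    on_threshold: float = 350.0
    frame_interval: float = 2.5
    duration: float = 60.0
    threshold_sweep: list = field(default_factory=lambda: list(range(0, 1601, 100)))
    robustness_thresholds: list = field(default_factory=lambda: [250, 300, 350, 400, 450])
    stage_boundaries: list = field(default_factory=lambda: list(DEFAULT_STAGE_BOUNDARIES))
    curve_file: str | None = None
    cofactor: float = DEFAULT_COFACTOR
    bootstrap_subsample_n: int = 31
    bootstrap_resamples: int = 10_000
    classifier_span: float = 0.3
    classifier_score: str = "deviation"  # or "fano"
    n_cells_per_stage: int = 50
    marker_noise_cv: float = 0.2
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if self.on_threshold <= 0:
            raise ConfigurationError("on_threshold must be positive")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ConfigurationError("frame_interval and duration must be positive")
        if not 0 < self.classifier_span <= 1:
            raise ConfigurationError("classifier_span must lie in (0, 1]")
        if self.classifier_score not in ("deviation", "fano"):
            raise ConfigurationError("classifier_score must be 'deviation' or 'fano'")
        if len(self.stage_boundaries) != 5 or any(
            b2 <= b1 for b1, b2 in zip(self.stage_boundaries, self.stage_boundaries[1:])
        ):
            raise ConfigurationError("stage_boundaries must be 5 increasing cut points")
        if not self.threshold_sweep:
            raise ConfigurationError("threshold_sweep must be non-empty")
        if self.bootstrap_subsample_n < 1 or self.bootstrap_resamples < 1:
            raise ConfigurationError("bootstrap settings must be positive")
        if self.n_cells_per_stage < 0:
            raise ConfigurationError("n_cells_per_stage must be non-negative")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload).validate()

    def digest(self) -> str:
        """Stable hash of the configuration (identical config => identical hash)."""
        canon = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
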