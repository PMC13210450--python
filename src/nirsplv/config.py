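"""Run configuration: one human-readable file drives the whole pipeline.

Every tunable defaults to the study's stated value where one exists
(8.138 Hz acquisition, 2 Hz analysis rate, 0.005–0.05 Hz order-3
band-pass, epochs −1..61 s with −1..0 s baseline, q = 0.05, PLV
visualization threshold 0.7, 10 trials × 3 screens of 8 s, 0.5 s
introduction, 35 s rest, 3 cm optode separation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigValidationError

EFFECT_PRESETS = ("default", "null", "seed_effect", "activation_effect")


@dataclass
class RunConfig:
    mode: str = "simulate"
    out_dir: str = "runs/demo"
    seed: int = 1
    n_subjects: int = 44
    effects: str = "seed_effect"
    # acquisition / design
    rate_hz: float = 8.138
    n_trials: int = 10
    distance_cm: float = 3.0
    wavelengths_nm: list[float] = field(default_factory=lambda: [780.0, 850.0])
    dpf: list[float] = field(default_factory=lambda: [6.0, 6.0])
    extinction: list[list[float]] | None = field(
        default_factory=lambda: [[0.000735, 0.001105], [0.001058, 0.000691]]
    )
    # preprocessing
    target_hz: float = 2.0
    band_hz: list[float] = field(default_factory=lambda: [0.005, 0.05])
    filter_order: int = 3
    epoch_window_s: list[float] = field(default_factory=lambda: [-1.0, 61.0])
    baseline_window_s: list[float] = field(default_factory=lambda: [-1.0, 0.0])
    cv_max: float = 0.15
    # connectivity
    edge_trim_s: float = 50.0
    min_segment_s: float = 400.0
    binary_threshold: float = 0.7
    # inference
    q: float = 0.05
    summary_window_s: list[float] = field(default_factory=lambda: [0.0, 24.0])
    # outputs
    write_recordings: bool = False
    input_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        """Check invariants before any computation runs."""
        problems: list[str] = []
        if self.mode not in ("simulate", "files"):
            problems.append(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.seed < 0:
            problems.append("seed must be non-negative")
        if self.n_subjects < 2:
            problems.append("n_subjects must be >= 2")
        if self.effects not in EFFECT_PRESETS:
            problems.append(f"effects must be one of {EFFECT_PRESETS}")
        if self.extinction is None:
            problems.append("extinction table is required")
        else:
            ext = np.asarray(self.extinction, dtype=float)
            if ext.shape != (2, 2):
                problems.append("extinction table must be 2x2")
            elif abs(np.linalg.det(ext)) < 1e-12 * np.abs(ext).max() ** 2:
                problems.append("extinction table is singular")
        if not (0 < self.band_hz[0] < self.band_hz[1] < self.target_hz / 2):
            problems.append("band_hz must satisfy 0 < low < high < target Nyquist")
        if self.target_hz >= self.rate_hz:
            problems.append("target_hz must be below rate_hz")
        if not 0 <= self.binary_threshold <= 1:
            problems.append("binary_threshold must lie in [0, 1]")
        if not 0 < self.q < 1:
            problems.append("q must lie in (0, 1)")
        if self.n_trials < 1:
            problems.append("n_trials must be >= 1")
        if self.distance_cm <= 0:
            problems.append("distance_cm must be positive")
        if self.mode == "files" and not self.input_dir:
            problems.append("mode 'files' requires input_dir")
        if problems:
            raise ConfigValidationError("; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
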