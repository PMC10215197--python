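"""Run configuration: one validated record driving every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .constants import (
    DEFAULT_CLASS_BOUNDS,
    DEFAULT_CV_THRESHOLD,
    DEFAULT_FOLD_THRESHOLD,
    DEFAULT_MIN_DELTA,
    DEFAULT_RATIO_CAP,
    DEFAULT_SD_THRESHOLD,
)

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a simulate→quantify→aggregate→report run.

    The oxidant dose series is in mM; the endogenous-stress (inhibitor)
    arm is modeled as an effective dose on the same axis, since no
    quantitative dose exists for it — ``ama_dose_mM`` is a simulator knob.
    """

    seed: int = 0
    # simulation
    doses_mM: list[float] = field(default_factory=lambda: [1.0, 2.5, 5.0, 10.0])
    ama_dose_mM: float = 3.0
    peroxide_replicates: int = 2
    ama_replicates: int = 3
    oxicat_replicates: int = 3
    noise_cv: float = 0.2
    dropout_rate: float = 0.05
    n_proteins: int = 40
    protein_length: tuple[int, int] = (120, 300)
    mito_fraction: float = 0.8
    fasta: Optional[str] = None
    annotations: Optional[str] = None
    # thresholds
    ratio_cap: float = DEFAULT_RATIO_CAP
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    cv_threshold: float = DEFAULT_CV_THRESHOLD
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS
    min_delta: float = DEFAULT_MIN_DELTA
    # replicate-presence rules (required_k, of_n) per arm
    peroxide_presence: tuple[int, int] = (2, 2)
    ama_presence: tuple[int, int] = (2, 3)
    oxicat_presence: tuple[int, int] = (2, 3)

    def validate(self) -> "RunConfig":
        if not self.doses_mM:
            raise ValueError("dose series must not be empty")
        if any(d < 0 for d in self.doses_mM):
            raise ValueError("doses must be non-negative")
        if sorted(self.doses_mM) != list(self.doses_mM):
            raise ValueError("doses must be sorted ascending")
        for name in (
            "ratio_cap",
            "fold_threshold",
            "cv_threshold",
            "sd_threshold",
            "min_delta",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ratio_cap <= 1:
            raise ValueError("ratio_cap must exceed 1")
        lo, hi = self.class_bounds
        if not 0 < lo < hi:
            raise ValueError("class_bounds must satisfy 0 < lower < upper")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("peroxide_replicates", "ama_replicates", "oxicat_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("peroxide_presence", "ama_presence", "oxicat_presence"):
            k, n = getattr(self, name)
            if not 1 <= k <= n:
                raise ValueError(f"{name} must satisfy 1 <= required_k <= of_n")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("protein_length", "class_bounds", "peroxide_presence",
                    "ama_presence", "oxicat_presence"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def with_overrides(self, **kwargs) -> "RunConfig":
        overrides = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **overrides).validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @property
    def peroxide_conditions(self) -> dict[str, float]:
        def _fmt(d: float) -> str:
            return f"{d:g}"

        return {f"H2O2_{_fmt(d)}mM": d for d in self.doses_mM}
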