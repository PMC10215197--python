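"""Core domain types shared across the pipeline.

Everything downstream is keyed on :class:`CysteineSite` — one cysteine
residue on one protein, carried with the tryptic peptide that reports it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CysteineSite",
    "Peptide",
    "TruthRecord",
    "RatioObservation",
    "SiteSummary",
    "OxidationRecord",
    "AnnotationRecord",
    "EICTrace",
    "CoelutionResult",
    "SENSITIVITY_CLASSES",
]

SENSITIVITY_CLASSES = ("resistant", "moderate", "high")


@dataclass(frozen=True, order=True)
class CysteineSite:
    """A quantifiable cysteine: protein accession + 1-based residue index."""

    protein_id: str
    residue: int
    peptide: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError(f"residue index must be 1-based, got {self.residue}")

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}_C{self.residue}"


@dataclass(frozen=True)
class Peptide:
    """A tryptic digestion product located within its parent protein."""

    protein_id: str
    sequence: str
    start: int  # 1-based offset of sequence[0] in the protein
    missed_cleavages: int
    cys_positions: tuple[int, ...]  # 1-based protein residue indices

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("start must be 1-based")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be non-negative")
        for pos in self.cys_positions:
            local = pos - self.start
            if local < 0 or local >= len(self.sequence) or self.sequence[local] != "C":
                raise ValueError(
                    f"cys position {pos} does not map to a 'C' in peptide "
                    f"{self.sequence!r} starting at {self.start}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one site.

    The dose response of the reversibly oxidized fraction is a Hill curve
    with half-effect concentration ``K`` (mM) and maximal amplitude
    ``fmax_rev`` on top of a basal oxidized fraction. ``firr_frac`` is the
    share of total oxidation that is irreversible (invisible to
    differential-alkylation readout). ``detect_isotop``/``detect_oxicat``
    are per-platform detection probabilities.
    """

    site: CysteineSite
    fmax_rev: float
    K: float
    hill: float
    firr_frac: float
    detect_isotop: float
    detect_oxicat: float
    basal_ox: float
    sensitivity_class: str

    def __post_init__(self) -> None:
        for name in ("fmax_rev", "firr_frac", "detect_isotop", "detect_oxicat", "basal_ox"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.K <= 0:
            raise ValueError(f"half-effect concentration K must be positive, got {self.K}")
        if self.basal_ox + self.fmax_rev > 1.0 + 1e-12:
            raise ValueError(
                f"basal_ox + fmax_rev = {self.basal_ox + self.fmax_rev} exceeds 1"
            )
        if self.sensitivity_class not in SENSITIVITY_CLASSES:
            raise ValueError(f"unknown sensitivity class {self.sensitivity_class!r}")


@dataclass(frozen=True)
class RatioObservation:
    """One per-replicate light:heavy measurement for one site/condition."""

    site: CysteineSite
    condition: str
    replicate: int
    light_area: float
    heavy_area: float
    ratio_LH: float
    capped: bool = False

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.light_area < 0 or self.heavy_area < 0:
            raise ValueError("channel areas must be non-negative")
        if self.ratio_LH <= 0:
            raise ValueError("ratio_LH must be positive")


@dataclass(frozen=True)
class SiteSummary:
    """Replicate-aggregated ratio for one site under one condition."""

    site: CysteineSite
    condition: str
    n_present: int
    mean_ratio: Optional[float] = None
    cv: Optional[float] = None
    sensitivity_class: Optional[str] = None
    implied_oxidation_pct: Optional[float] = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mean_ratio is not None and self.mean_ratio <= 0:
            raise ValueError("mean_ratio must be positive")
        if self.cv is not None and self.cv < 0:
            raise ValueError("cv must be non-negative")

    @property
    def retained(self) -> bool:
        return not self.flags & {"PRESENCE_FAIL", "CV_FAIL"}


@dataclass(frozen=True)
class OxidationRecord:
    """Percent oxidation for one site under one condition, with dispersion."""

    site: CysteineSite
    condition: str
    replicate_pcts: tuple[float, ...]
    mean_pct: Optional[float] = None
    sd_pct: Optional[float] = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for p in self.replicate_pcts:
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"percent oxidation {p} outside [0, 100]")
        if self.mean_pct is not None and not 0.0 <= self.mean_pct <= 100.0:
            raise ValueError(f"mean_pct {self.mean_pct} outside [0, 100]")

    @property
    def retained(self) -> bool:
        return not self.flags & {"PRESENCE_FAIL", "DISPERSION_FAIL"}


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-protein localization, pathway bin, and known redox flags."""

    protein_id: str
    is_mitochondrial: bool
    pathway_bin: str = "other"
    known_redox_flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EICTrace:
    """Extracted-ion-chromatogram trace for one channel of one observation."""

    site: CysteineSite
    channel: str  # "LIGHT" or "HEAVY"
    times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intens)
        if self.channel not in ("LIGHT", "HEAVY"):
            raise ValueError(f"channel must be LIGHT or HEAVY, got {self.channel!r}")
        if times.size < 3:
            raise ValueError("trace needs at least 3 samples")
        if times.size != intens.size:
            raise ValueError("times and intensities must have the same length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(intens < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class CoelutionResult:
    """Outcome of pairing a light and a heavy trace."""

    passed: bool
    apex_offset_s: float
    correlation: float
    reason: str = ""
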