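"""Synthetic ground truth and noisy observation generator.

Builds cysteine proteomes from protein sequences (in-silico tryptic
digestion), assigns each site a latent dose-response truth, and emits
per-replicate observations for the two quantification platforms:

* competitive reactivity profiling — expected light:heavy ratio
  ``1 / (1 - f_total(c))``, where ``f_total`` is the total (reversible +
  irreversible) oxidized fraction at oxidant dose ``c``; fully oxidized
  sites are censored (never observed);
* differential alkylation — light channel proportional to the reduced
  fraction, heavy channel proportional to the *reversibly* oxidized
  fraction; irreversibly oxidized molecules take neither label.

All randomness flows through a single ``numpy`` generator seeded by the
caller, so identical seeds give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .constants import (
    ADDUCT_MASS_DIFF,
    CANONICAL_RESIDUES,
    DEFAULT_CLASS_BOUNDS,
    DEFAULT_RATIO_CAP,
    FULL_OXIDATION_CENSOR,
    IA_HEAVY_MASS,
    IA_LIGHT_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
)
from .model import (
    AnnotationRecord,
    CysteineSite,
    EICTrace,
    Peptide,
    RatioObservation,
    TruthRecord,
)
from .quantify import compute_ratio

__all__ = [
    "digest",
    "peptide_mass",
    "oxidized_fraction",
    "classify_truth",
    "sample_truths",
    "simulate_isotop",
    "simulate_oxicat",
    "simulate_chromatograms",
    "random_proteome",
    "build_sites",
    "sample_annotations",
]

LABELS = ("IA_LIGHT", "IA_HEAVY")
_ADDUCTS = {"IA_LIGHT": IA_LIGHT_MASS, "IA_HEAVY": IA_HEAVY_MASS, None: 0.0}

# ---------------------------------------------------------------------------
# digestion and mass


def _cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that a tryptic cut occurs after sequence[i]."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def digest(
    protein_sequence: str,
    max_missed: int = 2,
    min_len: int = 1,
    max_len: int = 50,
    protein_id: str = "",
) -> list[Peptide]:
    """In-silico tryptic digest: cleave after K/R unless followed by P.

    Returns all products with at most ``max_missed`` internal missed
    cleavage sites and length within ``[min_len, max_len]``, ordered by
    start position then length.
    """
    for i, aa in enumerate(protein_sequence):
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {i + 1} in protein "
                f"{protein_id or '<unnamed>'}"
            )
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 <= min_len <= max_len")

    cuts = _cleavage_sites(protein_sequence)
    # fragment boundaries: [start, end) in 0-based coordinates
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(protein_sequence)]
    n_frag = len(starts)

    peptides: list[Peptide] = []
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            start, end = starts[i], ends[j]
            seq = protein_sequence[start:end]
            if not (min_len <= len(seq) <= max_len):
                continue
            cys = tuple(start + 1 + k for k, aa in enumerate(seq) if aa == "C")
            peptides.append(
                Peptide(
                    protein_id=protein_id,
                    sequence=seq,
                    start=start + 1,
                    missed_cleavages=j - i,
                    cys_positions=cys,
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def peptide_mass(peptide: Peptide | str, label: Optional[str] = None) -> float:
    """Monoisotopic peptide mass in Da, optionally with one cysteine adduct
    per cysteine (``label`` in {"IA_LIGHT", "IA_HEAVY"})."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    if not seq:
        raise ValueError("cannot compute the mass of an empty peptide")
    if label is not None and label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    mass = WATER_MASS
    for i, aa in enumerate(seq):
        try:
            mass += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"non-canonical residue {aa!r} at position {i + 1}") from None
    n_cys = seq.count("C")
    if label is not None:
        if n_cys == 0:
            raise ValueError("label requested on a cysteine-free peptide")
        mass += n_cys * _ADDUCTS[label]
    return mass


# ---------------------------------------------------------------------------
# dose response and truth


def oxidized_fraction(truth: TruthRecord, concentration: float) -> float:
    """Total oxidized fraction at oxidant dose ``concentration`` (mM).

    Hill saturation on top of the basal fraction:
    ``f(c) = basal_ox + fmax_rev * c^h / (K^h + c^h)``.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if truth.K <= 0:
        raise ValueError("half-effect concentration K must be positive")
    if concentration == 0:
        return truth.basal_ox
    ch = concentration ** truth.hill
    return truth.basal_ox + truth.fmax_rev * ch / (truth.K ** truth.hill + ch)


def _expected_ratio(f_total: float, cap: float) -> float:
    if f_total >= 1.0:
        return cap
    return min(max(1.0 / (1.0 - f_total), 1.0 / cap), cap)


def classify_truth(
    fmax_rev: float,
    K: float,
    hill: float = 1.0,
    basal_ox: float = 0.0,
    reference_dose: float = 10.0,
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
) -> str:
    """Deterministic sensitivity class implied by the dose-response
    parameters: the class of the noiseless expected ratio at the top dose."""
    ch = reference_dose ** hill
    f = basal_ox + fmax_rev * ch / (K ** hill + ch)
    ratio = math.inf if f >= 1.0 else 1.0 / (1.0 - f)
    lo, hi = class_bounds
    if ratio >= hi:
        return "high"
    if ratio >= lo:
        return "moderate"
    return "resistant"


#: Per-class generative parameter ranges (uniform draws). Chosen so the
#: noiseless top-dose ratios of adjacent classes are well separated from
#: the 2x / 5x class boundaries.
CLASS_PARAM_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "resistant": {"fmax_rev": (0.05, 0.20), "K": (2.0, 8.0)},
    "moderate": {"fmax_rev": (0.80, 0.84), "K": (1.5, 2.0)},
    "high": {"fmax_rev": (0.93, 0.96), "K": (0.3, 0.7)},
}


def sample_truths(
    sites: Sequence[CysteineSite],
    seed: int | np.random.Generator = 0,
    class_probs: Mapping[str, float] | None = None,
    hill: float = 1.0,
    basal_range: tuple[float, float] = (0.0, 0.02),
    firr_range: tuple[float, float] = (0.0, 0.2),
    detect_isotop: float = 0.9,
    detect_oxicat: float = 0.8,
    reference_dose: float = 10.0,
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
) -> list[TruthRecord]:
    """Draw a ground-truth record for every site.

    Sites are assigned to sensitivity classes with ``class_probs``
    (default: 42% resistant / 50% moderate / 8% high, echoing the observed
    strata), then dose-response parameters are drawn uniformly from the
    per-class ranges. The stored class is recomputed from the drawn
    parameters via :func:`classify_truth`, so it is always consistent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = dict(class_probs or {"resistant": 0.42, "moderate": 0.50, "high": 0.08})
    names = list(probs)
    p = np.asarray([probs[n] for n in names], dtype=float)
    p = p / p.sum()
    truths = []
    for site in sites:
        cls = names[rng.choice(len(names), p=p)]
        ranges = CLASS_PARAM_RANGES[cls]
        fmax = rng.uniform(*ranges["fmax_rev"])
        K = rng.uniform(*ranges["K"])
        basal = rng.uniform(*basal_range)
        basal = min(basal, 1.0 - fmax)
        truths.append(
            TruthRecord(
                site=site,
                fmax_rev=fmax,
                K=K,
                hill=hill,
                firr_frac=rng.uniform(*firr_range),
                detect_isotop=detect_isotop,
                detect_oxicat=detect_oxicat,
                basal_ox=basal,
                sensitivity_class=classify_truth(
                    fmax, K, hill, basal, reference_dose, class_bounds
                ),
            )
        )
    return truths


# ---------------------------------------------------------------------------
# observation simulators


def _noise_factor(rng: np.random.Generator, sigma: float) -> float:
    """Mean-one multiplicative log-normal factor."""
    if sigma == 0.0:
        return 1.0
    return math.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma)


def _noise_sigma(noise_cv: float) -> float:
    return math.sqrt(math.log1p(noise_cv * noise_cv))


def simulate_isotop(
    truths: Sequence[TruthRecord],
    condition_doses: Mapping[str, float],
    n_replicates: int,
    noise_cv: float = 0.2,
    dropout_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    cap: float = DEFAULT_RATIO_CAP,
    censor_threshold: float = FULL_OXIDATION_CENSOR,
    base_intensity: float = 1e5,
) -> list[RatioObservation]:
    """Per-replicate competitive-profiling observations.

    For each site/condition the heavy (treated) channel is attenuated by
    ``1 - f_total``, so the noiseless ratio is ``1 / (1 - f_total)``.
    Sites with ``f_total >= censor_threshold`` are never emitted (fully
    oxidized cysteines escape the competitive readout). A site fails
    detection for a condition with probability ``1 - detect_isotop``;
    individual replicates additionally drop out at ``dropout_rate``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    for cond, dose in condition_doses.items():
        if dose < 0:
            raise ValueError(f"dose for condition {cond!r} must be non-negative")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = _noise_sigma(noise_cv)
    out: list[RatioObservation] = []
    for truth in truths:
        for cond, dose in condition_doses.items():
            f_total = oxidized_fraction(truth, dose)
            detected = rng.random() < truth.detect_isotop
            if f_total >= censor_threshold or not detected:
                continue
            for rep in range(1, n_replicates + 1):
                if dropout_rate > 0 and rng.random() < dropout_rate:
                    continue
                light = base_intensity * _noise_factor(rng, sigma)
                heavy = base_intensity * (1.0 - f_total) * _noise_factor(rng, sigma)
                result = compute_ratio(light, heavy, cap=cap)
                if result is None:
                    continue
                ratio, capped = result
                out.append(
                    RatioObservation(
                        site=truth.site,
                        condition=cond,
                        replicate=rep,
                        light_area=light,
                        heavy_area=heavy,
                        ratio_LH=ratio,
                        capped=capped,
                    )
                )
    return out


def simulate_oxicat(
    truths: Sequence[TruthRecord],
    condition_doses: Mapping[str, float],
    n_replicates: int,
    noise_cv: float = 0.2,
    seed: int | np.random.Generator = 0,
    cap: float = DEFAULT_RATIO_CAP,
    base_intensity: float = 1e5,
) -> list[RatioObservation]:
    """Per-replicate differential-alkylation observations.

    Light channel ∝ reduced fraction (``1 - f_rev - f_irr``), heavy
    channel ∝ reversibly oxidized fraction (``f_rev``); irreversibly
    oxidized molecules take neither label, so the heavy share estimates
    ``f_rev / (1 - f_irr)``. Detection is governed by ``detect_oxicat``,
    independent of the competitive platform's detectability.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = _noise_sigma(noise_cv)
    out: list[RatioObservation] = []
    for truth in truths:
        for cond, dose in condition_doses.items():
            f_total = oxidized_fraction(truth, dose)
            f_irr = truth.firr_frac * f_total
            f_rev = f_total - f_irr
            if f_rev + f_irr > 1.0 + 1e-12:
                raise ValueError(
                    f"reversible + irreversible fraction exceeds 1 for {truth.site.site_id}"
                )
            if not rng.random() < truth.detect_oxicat:
                continue
            for rep in range(1, n_replicates + 1):
                light = base_intensity * (1.0 - f_total) * _noise_factor(rng, sigma)
                heavy = base_intensity * f_rev * _noise_factor(rng, sigma)
                result = compute_ratio(light, heavy, cap=cap)
                if result is None:
                    continue
                ratio, capped = result
                out.append(
                    RatioObservation(
                        site=truth.site,
                        condition=cond,
                        replicate=rep,
                        light_area=light,
                        heavy_area=heavy,
                        ratio_LH=ratio,
                        capped=capped,
                    )
                )
    return out


def simulate_chromatograms(
    observations: Iterable[RatioObservation],
    peak_sigma: float = 2.0,
    sampling_interval: float = 0.05,
    seed: int | np.random.Generator = 0,
    baseline: float = 0.0,
    baseline_noise: float = 0.0,
    apex_window: tuple[float, float] = (60.0, 540.0),
    span_sigmas: float = 6.0,
) -> list[EICTrace]:
    """Gaussian elution traces for each observation's two channels.

    Both channels share an apex time (perfect co-elution); each channel's
    peak area equals its channel area, so trapezoidal re-integration
    recovers the generating quantities. Optional additive baseline noise
    is clipped at zero.
    """
    if peak_sigma <= 0:
        raise ValueError("peak_sigma must be positive")
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    if sampling_interval >= peak_sigma:
        raise ValueError(
            f"sampling interval {sampling_interval}s undersamples a peak of "
            f"sigma {peak_sigma}s"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traces: list[EICTrace] = []
    for obs in observations:
        apex = rng.uniform(*apex_window)
        t0 = apex - span_sigmas * peak_sigma
        n = int(round(2 * span_sigmas * peak_sigma / sampling_interval)) + 1
        times = t0 + sampling_interval * np.arange(n)
        for channel, area in (("LIGHT", obs.light_area), ("HEAVY", obs.heavy_area)):
            height = area / (peak_sigma * math.sqrt(2.0 * math.pi))
            intens = height * np.exp(-0.5 * ((times - apex) / peak_sigma) ** 2)
            intens = intens + baseline
            if baseline_noise > 0:
                intens = intens + rng.normal(0.0, baseline_noise, size=n)
            traces.append(
                EICTrace(
                    site=obs.site,
                    channel=channel,
                    times=times,
                    intensities=np.clip(intens, 0.0, None),
                    condition=obs.condition,
                    replicate=obs.replicate,
                )
            )
    return traces


# ---------------------------------------------------------------------------
# proteome scaffolding

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# Mildly tryptic-friendly composition: K/R/C upweighted so toy proteins
# yield enough quantifiable cysteine peptides.
_AA_WEIGHTS = np.array(
    [0.05, 0.05, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05, 0.08, 0.09,
     0.02, 0.04, 0.05, 0.04, 0.08, 0.07, 0.05, 0.06, 0.01, 0.02]
)


def random_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (120, 400),
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Random toy proteome keyed by synthetic accessions (P0001, ...)."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = _AA_WEIGHTS / _AA_WEIGHTS.sum()
    proteome = {}
    for i in range(1, n_proteins + 1):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(_AA_ALPHABET), size=length, p=weights))
        proteome[f"P{i:04d}"] = seq
    return proteome


def build_sites(
    proteome: Mapping[str, str],
    max_missed: int = 0,
    min_len: int = 6,
    max_len: int = 50,
) -> list[CysteineSite]:
    """Digest every protein and return one site per quantifiable cysteine.

    A cysteine is quantifiable when it falls on at least one fully cleaved
    peptide within the length window; the reporting peptide is that
    zero-missed-cleavage product.
    """
    sites: list[CysteineSite] = []
    for protein_id in sorted(proteome):
        peptides = digest(
            proteome[protein_id],
            max_missed=max_missed,
            min_len=min_len,
            max_len=max_len,
            protein_id=protein_id,
        )
        seen: set[int] = set()
        for pep in peptides:
            for pos in pep.cys_positions:
                if pos not in seen:
                    seen.add(pos)
                    sites.append(
                        CysteineSite(protein_id=protein_id, residue=pos, peptide=pep.sequence)
                    )
    sites.sort(key=lambda s: (s.protein_id, s.residue))
    return sites


def sample_annotations(
    protein_ids: Sequence[str],
    seed: int | np.random.Generator = 0,
    mito_fraction: float = 0.8,
    flag_rate: float = 0.1,
) -> list[AnnotationRecord]:
    """Toy per-protein annotation table: localization, pathway bin, flags.

    Proteins are mitochondrial with probability ``mito_fraction``;
    mitochondrial proteins get a uniform pathway bin from the fixed
    12-label vocabulary (non-mitochondrial ones go to "other"); known
    redox flags are sprinkled at ``flag_rate``.
    """
    from .annotate import PATHWAY_BINS  # local import avoids a cycle at module load

    if not 0.0 <= mito_fraction <= 1.0:
        raise ValueError("mito_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flag_vocab = ("disulfide", "metal_binding", "s_palmitoylation")
    records = []
    for pid in sorted(set(protein_ids)):
        is_mito = bool(rng.random() < mito_fraction)
        pathway = PATHWAY_BINS[rng.integers(len(PATHWAY_BINS))] if is_mito else "other"
        flags = frozenset(f for f in flag_vocab if rng.random() < flag_rate)
        records.append(
            AnnotationRecord(
                protein_id=pid,
                is_mitochondrial=is_mito,
                pathway_bin=pathway,
                known_redox_flags=flags,
            )
        )
    return records
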