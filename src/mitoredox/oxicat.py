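"""Percent-oxidation quantification from differential-alkylation ratios.

Channel semantics here are the reverse of the competitive platform: the
light channel tags reduced thiols and the heavy channel tags reversibly
oxidized thiols, so the heavy share of the signal IS the (reversible)
oxidized fraction. Ratios convert to percent oxidation via
``100·(1 − R/(R+1))`` for light:heavy input or ``100·R/(R+1)`` for
heavy:light input — the two orientations agree on reciprocal ratios.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .constants import DEFAULT_MIN_DELTA, DEFAULT_SD_THRESHOLD
from .model import CysteineSite, OxidationRecord, RatioObservation

__all__ = [
    "percent_oxidation",
    "observations_to_percents",
    "aggregate_oxidation",
    "delta_oxidation",
    "compare_conditions",
]


def percent_oxidation(ratio: float, orientation: str = "LH") -> float:
    """Convert an isotope-channel ratio to percent oxidation.

    orientation "LH": 100·(1 − R/(R+1));  "HL": 100·R/(R+1).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if orientation == "LH":
        return 100.0 * (1.0 - ratio / (ratio + 1.0))
    if orientation == "HL":
        return 100.0 * ratio / (ratio + 1.0)
    raise ValueError(f"orientation must be 'LH' or 'HL', got {orientation!r}")


def observations_to_percents(
    observations: Iterable[RatioObservation],
    orientation: str = "LH",
) -> list[tuple[CysteineSite, str, int, float]]:
    """Per-replicate (site, condition, replicate, percent) tuples."""
    return [
        (o.site, o.condition, o.replicate, percent_oxidation(o.ratio_LH, orientation))
        for o in observations
    ]


def aggregate_oxidation(
    percents: Iterable[tuple[CysteineSite, str, int, float]],
    presence_rule: tuple[int, int] = (2, 3),
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    dispersion: str = "sd",
) -> list[OxidationRecord]:
    """Aggregate per-replicate percent-oxidation values per site/condition.

    Presence is enforced as (required_k, of_n); records whose replicate
    dispersion exceeds ``sd_threshold`` are flagged DISPERSION_FAIL and
    excluded downstream. ``dispersion`` selects the reading of the filter
    statistic: "sd" (sample standard deviation, in percentage points —
    the default), "sem" (standard error of the mean), or "rsd" (relative
    SD as a fraction of the mean).
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    if dispersion not in ("sd", "sem", "rsd"):
        raise ValueError(f"unknown dispersion reading {dispersion!r}")
    required_k, of_n = presence_rule
    if not 1 <= required_k <= of_n:
        raise ValueError("presence rule must satisfy 1 <= required_k <= of_n")

    grouped: dict[tuple[CysteineSite, str], dict[int, float]] = defaultdict(dict)
    for site, condition, replicate, pct in percents:
        if not 0.0 <= pct <= 100.0:
            raise ValueError(
                f"percent oxidation {pct} outside [0, 100] for {site.site_id}"
            )
        key = (site, condition)
        if replicate in grouped[key]:
            raise ValueError(
                f"duplicate percent for {site.site_id} / {condition} / replicate {replicate}"
            )
        grouped[key][replicate] = pct

    records = []
    for (site, condition), reps in sorted(
        grouped.items(), key=lambda kv: (kv[0][0].protein_id, kv[0][0].residue, kv[0][1])
    ):
        pcts = tuple(reps[r] for r in sorted(reps))
        if len(pcts) < required_k:
            records.append(
                OxidationRecord(
                    site=site,
                    condition=condition,
                    replicate_pcts=pcts,
                    flags=frozenset({"PRESENCE_FAIL"}),
                )
            )
            continue
        arr = np.array(pcts)
        mean = float(arr.mean())
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        if dispersion == "sd":
            stat = sd
        elif dispersion == "sem":
            stat = sd / np.sqrt(arr.size)
        else:  # rsd
            stat = sd / mean if mean > 0 else 0.0
        flags = frozenset({"DISPERSION_FAIL"}) if stat > sd_threshold else frozenset()
        records.append(
            OxidationRecord(
                site=site,
                condition=condition,
                replicate_pcts=pcts,
                mean_pct=mean,
                sd_pct=sd,
                flags=flags,
            )
        )
    return records


def delta_oxidation(
    control: OxidationRecord,
    treated: OxidationRecord,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> tuple[float, str]:
    """Treated minus control mean percent oxidation, with a qualitative call.

    "increased" when the difference is at least ``min_delta`` percentage
    points, "decreased" when at most ``-min_delta``, else "unchanged".
    """
    if control.site != treated.site:
        raise ValueError(
            f"site mismatch: {control.site.site_id} vs {treated.site.site_id}"
        )
    if not (control.retained and treated.retained):
        raise ValueError("both records must be retained (unflagged)")
    if control.mean_pct is None or treated.mean_pct is None:
        raise ValueError("both records need a mean percent")
    delta = treated.mean_pct - control.mean_pct
    if delta >= min_delta:
        call = "increased"
    elif delta <= -min_delta:
        call = "decreased"
    else:
        call = "unchanged"
    return delta, call


def compare_conditions(
    records: Iterable[OxidationRecord],
    control_label: str,
    treated_label: str,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> pd.DataFrame:
    """Wide per-site table pairing control and treated percent oxidation.

    Only sites retained in both conditions are compared; the rest appear
    with missing deltas.
    """
    by_site: dict[CysteineSite, dict[str, OxidationRecord]] = defaultdict(dict)
    for rec in records:
        if rec.condition in (control_label, treated_label):
            by_site[rec.site][rec.condition] = rec
    rows = []
    for site in sorted(by_site, key=lambda s: (s.protein_id, s.residue)):
        pair = by_site[site]
        ctrl = pair.get(control_label)
        trt = pair.get(treated_label)
        row = {
            "protein_id": site.protein_id,
            "residue": site.residue,
            "site_id": site.site_id,
            "control_pct": ctrl.mean_pct if ctrl else None,
            "treated_pct": trt.mean_pct if trt else None,
            "delta_pct": None,
            "call": None,
        }
        if ctrl and trt and ctrl.retained and trt.retained:
            delta, call = delta_oxidation(ctrl, trt, min_delta)
            row["delta_pct"] = delta
            row["call"] = call
        rows.append(row)
    return pd.DataFrame(rows)
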