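"""Replicate aggregation, QC filtering, and dose-sensitivity classification
for competitive reactivity-profiling ratios.

The filter conventions follow the source workflow: ratios must be present
in a minimum number of replicates (2-of-2 for the dose series, 2-of-3 for
the inhibitor arm); sites whose mean ratio exceeds the fold threshold AND
whose replicate CV exceeds the CV threshold are removed; sensitivity
classes are assigned from the top-dose mean ratio at 2x/5x boundaries.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_CLASS_BOUNDS,
    DEFAULT_CV_THRESHOLD,
    DEFAULT_FOLD_THRESHOLD,
)
from .model import CysteineSite, RatioObservation, SiteSummary

__all__ = [
    "aggregate_replicates",
    "filter_changed",
    "classify_sensitivity",
    "implied_oxidation",
    "median_summary",
    "classify_dose_series",
]


def aggregate_replicates(
    observations: Iterable[RatioObservation],
    presence_rule: tuple[int, int] = (2, 2),
    log_space_cv: bool = False,
) -> list[SiteSummary]:
    """Collapse per-replicate ratios into one summary per (site, condition).

    ``presence_rule`` is (required_k, of_n): sites quantified in fewer than
    ``required_k`` replicates get a PRESENCE_FAIL flag and no mean.
    The CV is the sample standard deviation over the mean of the replicate
    ratios (on log ratios instead when ``log_space_cv``). Summaries are
    ordered by (protein, residue, condition).
    """
    required_k, of_n = presence_rule
    if not 1 <= required_k <= of_n:
        raise ValueError("presence rule must satisfy 1 <= required_k <= of_n")

    grouped: dict[tuple[CysteineSite, str], dict[int, RatioObservation]] = defaultdict(dict)
    for obs in observations:
        key = (obs.site, obs.condition)
        if obs.replicate in grouped[key]:
            raise ValueError(
                f"duplicate observation for {obs.site.site_id} / {obs.condition} "
                f"/ replicate {obs.replicate}"
            )
        grouped[key][obs.replicate] = obs

    summaries = []
    for (site, condition), reps in sorted(
        grouped.items(), key=lambda kv: (kv[0][0].protein_id, kv[0][0].residue, kv[0][1])
    ):
        n_present = len(reps)
        flags = set()
        if any(o.capped for o in reps.values()):
            flags.add("CAPPED")
        if n_present < required_k:
            summaries.append(
                SiteSummary(
                    site=site,
                    condition=condition,
                    n_present=n_present,
                    flags=frozenset(flags | {"PRESENCE_FAIL"}),
                )
            )
            continue
        ratios = np.array([reps[r].ratio_LH for r in sorted(reps)])
        mean = float(ratios.mean())
        if ratios.size > 1:
            if log_space_cv:
                cv = float(np.std(np.log(ratios), ddof=1))
            else:
                cv = float(np.std(ratios, ddof=1) / mean)
        else:
            cv = 0.0
        summaries.append(
            SiteSummary(
                site=site,
                condition=condition,
                n_present=n_present,
                mean_ratio=mean,
                cv=cv,
                flags=frozenset(flags),
            )
        )
    return summaries


def filter_changed(
    summaries: Iterable[SiteSummary],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    mode: str = "mean_and_cv",
) -> list[SiteSummary]:
    """Apply the reproducibility filter, flagging failures with CV_FAIL.

    Default ``mode="mean_and_cv"``: a summary is removed only when its
    mean ratio exceeds ``fold_threshold`` AND its CV exceeds
    ``cv_threshold`` — changed sites must be reproducibly changed;
    unchanged sites are kept regardless of CV. The alternative
    ``mode="cv_only"`` removes any summary with CV above the threshold.
    """
    if fold_threshold <= 0 or cv_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if mode not in ("mean_and_cv", "cv_only"):
        raise ValueError(f"unknown filter mode {mode!r}")
    out = []
    for s in summaries:
        if s.mean_ratio is None or s.cv is None:
            out.append(s)
            continue
        if mode == "mean_and_cv":
            fail = s.mean_ratio > fold_threshold and s.cv > cv_threshold
        else:
            fail = s.cv > cv_threshold
        if fail:
            out.append(
                SiteSummary(
                    site=s.site,
                    condition=s.condition,
                    n_present=s.n_present,
                    mean_ratio=s.mean_ratio,
                    cv=s.cv,
                    sensitivity_class=s.sensitivity_class,
                    implied_oxidation_pct=s.implied_oxidation_pct,
                    flags=frozenset(s.flags | {"CV_FAIL"}),
                )
            )
        else:
            out.append(s)
    return out


def classify_sensitivity(
    dose_ratios: Mapping[float, float],
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
) -> tuple[str, float]:
    """Sensitivity class from the top-dose mean ratio, plus the dose slope.

    high: top-dose ratio >= upper bound (default 5); moderate: >= lower
    bound (default 2); resistant otherwise. The slope is the least-squares
    slope of log2(ratio) on log2(dose) over all available doses — reported
    for ranking, not used for the class call.
    """
    if not dose_ratios:
        raise ValueError("no doses present")
    lo, hi = class_bounds
    if not 0 < lo < hi:
        raise ValueError("class bounds must satisfy 0 < lower < upper")
    top_dose = max(dose_ratios)
    top_ratio = dose_ratios[top_dose]
    if top_ratio >= hi:
        cls = "high"
    elif top_ratio >= lo:
        cls = "moderate"
    else:
        cls = "resistant"
    positive = {d: r for d, r in dose_ratios.items() if d > 0 and r > 0}
    if len(positive) >= 2:
        x = np.log2(np.array(sorted(positive)))
        y = np.log2(np.array([positive[d] for d in sorted(positive)]))
        slope = float(np.polyfit(x, y, 1)[0])
    else:
        slope = float("nan")
    return cls, slope


def implied_oxidation(mean_ratio: float) -> float:
    """Percent oxidation implied by a competitive ratio: 100·(1 − 1/R).

    Exact inverse of the generative model R = 1/(1 − f). Ratios below 1
    (apparent reactivity gain) clamp to 0.
    """
    if mean_ratio <= 0:
        raise ValueError("ratio must be positive")
    return max(0.0, 100.0 * (1.0 - 1.0 / mean_ratio))


def classify_dose_series(
    summaries: Iterable[SiteSummary],
    condition_doses: Mapping[str, float],
    class_bounds: tuple[float, float] = DEFAULT_CLASS_BOUNDS,
) -> pd.DataFrame:
    """Per-site classification across a dose series of retained summaries.

    Returns one row per site with the top-dose ratio, class, log-log
    slope, and implied oxidation at the top dose. Sites missing the
    highest dose they were observed at are classified on what is present.
    """
    per_site: dict[CysteineSite, dict[float, float]] = defaultdict(dict)
    for s in summaries:
        if not s.retained or s.mean_ratio is None:
            continue
        if s.condition not in condition_doses:
            continue
        per_site[s.site][condition_doses[s.condition]] = s.mean_ratio
    rows = []
    for site in sorted(per_site, key=lambda s: (s.protein_id, s.residue)):
        ratios = per_site[site]
        cls, slope = classify_sensitivity(ratios, class_bounds)
        top_dose = max(ratios)
        rows.append(
            {
                "protein_id": site.protein_id,
                "residue": site.residue,
                "site_id": site.site_id,
                "top_dose_mM": top_dose,
                "top_dose_ratio": ratios[top_dose],
                "sensitivity_class": cls,
                "log2_slope": slope,
                "implied_oxidation_pct": implied_oxidation(ratios[top_dose]),
            }
        )
    return pd.DataFrame(rows)


def median_summary(summaries: Iterable[SiteSummary]) -> pd.DataFrame:
    """Per-condition median and quartiles of retained mean ratios."""
    by_condition: dict[str, list[float]] = defaultdict(list)
    for s in summaries:
        if s.retained and s.mean_ratio is not None:
            by_condition[s.condition].append(s.mean_ratio)
    if not by_condition:
        raise ValueError("no retained summaries in any condition")
    rows = []
    for condition in sorted(by_condition):
        vals = np.array(by_condition[condition])
        rows.append(
            {
                "condition": condition,
                "n": vals.size,
                "median_ratio": float(np.median(vals)),
                "q1_ratio": float(np.percentile(vals, 25)),
                "q3_ratio": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(rows)
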