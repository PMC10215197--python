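"""Chromatogram integration, co-elution QC, and ratio computation.

Turns paired light/heavy extracted-ion-chromatogram traces into
per-replicate light:heavy ratios — the substrate every downstream number
is built from.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_APEX_LIMIT_S,
    DEFAULT_CORR_LIMIT,
    DEFAULT_RATIO_CAP,
)
from .model import CoelutionResult, EICTrace, RatioObservation

__all__ = [
    "estimate_baseline",
    "integrate_eic",
    "coelution_qc",
    "compute_ratio",
    "quantify_traces",
]


def estimate_baseline(intensities: np.ndarray) -> float:
    """Baseline level: median of the lowest decile of intensities."""
    intens = np.asarray(intensities, dtype=float)
    k = max(1, intens.size // 10)
    return float(np.median(np.sort(intens)[:k]))


def integrate_eic(
    trace: EICTrace,
    window: Optional[tuple[float, float]] = None,
    subtract_baseline: bool = True,
) -> float:
    """Trapezoidal peak area over ``window`` (default: full trace).

    The baseline estimate (median of the lowest intensity decile) is
    subtracted before integration; the result is clamped at zero.
    """
    times, intens = trace.times, trace.intensities
    if window is not None:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("window end must exceed window start")
        mask = (times >= t0) & (times <= t1)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{t0}, {t1}] does not overlap the trace domain "
                f"[{times[0]}, {times[-1]}]"
            )
        times, intens = times[mask], intens[mask]
    if subtract_baseline:
        intens = intens - estimate_baseline(trace.intensities)
    area = float(np.trapezoid(intens, times))
    return max(area, 0.0)


def coelution_qc(
    light: EICTrace,
    heavy: EICTrace,
    apex_limit_s: float = DEFAULT_APEX_LIMIT_S,
    corr_limit: float = DEFAULT_CORR_LIMIT,
) -> CoelutionResult:
    """Check that the light/heavy pair co-elutes.

    Passes when the apex-time offset is within ``apex_limit_s`` and the
    Pearson correlation of the two traces — linearly resampled onto the
    union time grid over their overlap — is at least ``corr_limit``.
    Constant traces have undefined correlation and fail with a reason code.
    """
    apex_offset = float(
        light.times[np.argmax(light.intensities)]
        - heavy.times[np.argmax(heavy.intensities)]
    )
    lo = max(light.times[0], heavy.times[0])
    hi = min(light.times[-1], heavy.times[-1])
    if hi <= lo:
        return CoelutionResult(False, apex_offset, float("nan"), "no time overlap")
    grid = np.union1d(light.times, heavy.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    li = np.interp(grid, light.times, light.intensities)
    hi_i = np.interp(grid, heavy.times, heavy.intensities)
    if np.ptp(li) == 0 or np.ptp(hi_i) == 0:
        return CoelutionResult(False, apex_offset, float("nan"), "degenerate trace")
    corr = float(np.corrcoef(li, hi_i)[0, 1])
    if abs(apex_offset) > apex_limit_s:
        return CoelutionResult(False, apex_offset, corr, "apex offset")
    if corr < corr_limit:
        return CoelutionResult(False, apex_offset, corr, "low shape correlation")
    return CoelutionResult(True, apex_offset, corr)


def compute_ratio(
    light_area: float,
    heavy_area: float,
    cap: float = DEFAULT_RATIO_CAP,
) -> Optional[tuple[float, bool]]:
    """Light:heavy ratio clamped to ``[1/cap, cap]``.

    Returns ``(ratio, capped)``; ``capped`` is set when clamping occurred
    (including a zero heavy channel). Both areas zero → ``None`` (the
    site-replicate is missing).
    """
    if light_area < 0 or heavy_area < 0:
        raise ValueError("areas must be non-negative")
    if cap <= 1:
        raise ValueError("cap must exceed 1")
    if light_area == 0 and heavy_area == 0:
        return None
    if heavy_area == 0:
        return cap, True
    if light_area == 0:
        return 1.0 / cap, True
    ratio = light_area / heavy_area
    if ratio > cap:
        return cap, True
    if ratio < 1.0 / cap:
        return 1.0 / cap, True
    return ratio, False


def quantify_traces(
    traces: Iterable[EICTrace],
    cap: float = DEFAULT_RATIO_CAP,
    apex_limit_s: float = DEFAULT_APEX_LIMIT_S,
    corr_limit: float = DEFAULT_CORR_LIMIT,
    subtract_baseline: bool = True,
    require_qc: bool = False,
) -> tuple[list[RatioObservation], pd.DataFrame]:
    """Integrate paired traces into per-replicate observations.

    Traces are grouped by (site, condition, replicate); each group must
    contain one LIGHT and one HEAVY trace. Returns the observations and a
    QC table (one row per pair, including failures). With ``require_qc``
    the observations of failing pairs are suppressed.
    """
    groups: dict[tuple, dict[str, EICTrace]] = {}
    for tr in traces:
        key = (tr.site, tr.condition, tr.replicate)
        groups.setdefault(key, {})[tr.channel] = tr

    observations: list[RatioObservation] = []
    qc_rows = []
    for (site, condition, replicate), pair in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        if set(pair) != {"LIGHT", "HEAVY"}:
            raise ValueError(
                f"incomplete channel pair for {site.site_id}/{condition}/rep{replicate}"
            )
        light, heavy = pair["LIGHT"], pair["HEAVY"]
        qc = coelution_qc(light, heavy, apex_limit_s, corr_limit)
        l_area = integrate_eic(light, subtract_baseline=subtract_baseline)
        h_area = integrate_eic(heavy, subtract_baseline=subtract_baseline)
        result = compute_ratio(l_area, h_area, cap=cap)
        qc_rows.append(
            {
                "site_id": site.site_id,
                "condition": condition,
                "replicate": replicate,
                "coelution_pass": qc.passed,
                "apex_offset_s": qc.apex_offset_s,
                "shape_correlation": qc.correlation,
                "reason": qc.reason,
                "light_area": l_area,
                "heavy_area": h_area,
            }
        )
        if result is None or (require_qc and not qc.passed):
            continue
        ratio, capped = result
        observations.append(
            RatioObservation(
                site=site,
                condition=condition,
                replicate=replicate,
                light_area=l_area,
                heavy_area=h_area,
                ratio_LH=ratio,
                capped=capped,
            )
        )
    return observations, pd.DataFrame(qc_rows)
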