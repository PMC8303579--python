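"""Chromatographic peak suitability metrics and condition screening.

For each library compound a mass trace (XIC) is extracted from the MS1 scans,
the most intense peak is located, and quality metrics are computed at the
half-height crossings: full width at 50% height, left/right half-width
symmetry, tailing factor at 5% height, and a flat-top overload flag.  A
column/mobile-phase run is screened by counting compounds whose main peak
passes the symmetry (> 90%, strict) and width (1.8-3.6 s, inclusive)
criteria; candidate conditions are then ranked preferring those that perform
well in BOTH polarities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .library_model import Compound, default_precursor_mz

__all__ = [
    "Trace",
    "ChromPeak",
    "SuitabilityCriteria",
    "CompoundScreen",
    "ScreenResult",
    "MS1Run",
    "extract_trace",
    "detect_main_peak",
    "screen_condition",
    "rank_conditions",
]


class MS1Run(Protocol):
    """Anything that yields MS1 scans as (time_s, mz_array, intensity_array)."""

    polarity: str

    def ms1_scans(self) -> Sequence[tuple[float, np.ndarray, np.ndarray]]: ...


@dataclass(frozen=True)
class Trace:
    """A mass trace: intensity versus time (seconds), times strictly increasing."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.size < 2 or t.size != y.size:
            raise ValueError("trace needs >= 2 samples of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class ChromPeak:
    """Main-peak metrics; times in seconds, symmetry in percent."""

    apex_time: float
    apex_intensity: float
    left50_time: float
    right50_time: float
    width50: float
    symmetry50: float
    tailing_factor: float
    overloaded: bool


@dataclass(frozen=True)
class SuitabilityCriteria:
    """Pass thresholds: symmetry strictly above ``symmetry_min`` percent,
    width at half height within ``width_bounds`` seconds (inclusive)."""

    symmetry_min: float = 90.0
    width_bounds: tuple[float, float] = (1.8, 3.6)

    def __post_init__(self) -> None:
        low, high = self.width_bounds
        if low >= high:
            raise ValueError("width bounds must satisfy low < high")

    def passes(self, peak: "ChromPeak") -> tuple[bool, bool]:
        """(pass_symmetry, pass_width): symmetry strict, width inclusive."""
        low, high = self.width_bounds
        return (
            peak.symmetry50 > self.symmetry_min,
            low <= peak.width50 <= high,
        )


def extract_trace(run: MS1Run, mz: float, ppm_tol: float) -> Trace:
    """Sum, per MS1 scan, the intensity of peaks within ±ppm_tol of ``mz``."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    tol = mz * ppm_tol * 1e-6
    times, totals = [], []
    for time_s, scan_mz, scan_int in run.ms1_scans():
        within = np.abs(np.asarray(scan_mz) - mz) <= tol
        times.append(time_s)
        totals.append(float(np.asarray(scan_int)[within].sum()) if within.any() else 0.0)
    if not times:
        raise ValueError("run contains no MS1 scans")
    return Trace(np.asarray(times), np.asarray(totals))


def _cross_time(t0: float, y0: float, t1: float, y1: float, level: float) -> float:
    """Linear interpolation of the time where the trace crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _refine_apex(t: np.ndarray, y: np.ndarray, apex: int) -> tuple[float, float]:
    """Sub-sample apex by a parabola through the argmax and its neighbours.

    The discrete argmax is off the true apex by up to half a sampling
    interval, which alone would bias the left/right half-width split (and
    hence symmetry) at routine MS1 scan rates; the quadratic vertex removes
    that bias for any smooth peak top.  Falls back to the discrete sample
    for degenerate (non-concave) neighbourhoods.
    """
    t0, t1, t2 = t[apex - 1], t[apex], t[apex + 1]
    y0, y1, y2 = y[apex - 1], y[apex], y[apex + 1]
    coeffs = np.polyfit([t0 - t1, 0.0, t2 - t1], [y0, y1, y2], 2)
    a, b, c = coeffs
    if a >= 0:  # not concave: keep the discrete sample
        return float(t1), float(y1)
    dt_vertex = -b / (2.0 * a)
    if not (t0 - t1 < dt_vertex < t2 - t1):
        return float(t1), float(y1)
    vertex_y = c - b * b / (4.0 * a)
    return float(t1 + dt_vertex), float(max(vertex_y, y1))


def _crossings(
    t: np.ndarray, y: np.ndarray, apex: int, level: float
) -> Optional[tuple[float, float]]:
    """Times where the trace falls to ``level`` on each side of the apex."""
    left = None
    for i in range(apex, 0, -1):
        if y[i - 1] <= level <= y[i]:
            left = _cross_time(t[i - 1], y[i - 1], t[i], y[i], level)
            break
    right = None
    for i in range(apex, len(y) - 1):
        if y[i + 1] <= level <= y[i]:
            right = _cross_time(t[i], y[i], t[i + 1], y[i + 1], level)
            break
    if left is None or right is None:
        return None
    return left, right


def detect_main_peak(
    trace: Trace,
    noise_multiplier: float = 3.0,
    overload_level: float = 0.99,
    overload_span_s: float = 0.5,
) -> Optional[ChromPeak]:
    """Locate the most intense peak and compute its suitability metrics.

    The apex is located at the discrete argmax above the noise floor
    (``noise_multiplier`` times the median nonzero intensity) and refined to
    sub-sample precision by a parabola through its neighbours; half-height
    and 5%-height crossing times come from linear interpolation between the
    bracketing samples.
    Symmetry is ``100 * min(A, B) / max(A, B)`` with ``A``/``B`` the left/right
    half-widths at 50% height, so 100% is a perfectly symmetric peak.  The
    tailing factor is ``(A5 + B5) / (2 * A5)`` at 5% height.  A peak is
    flagged overloaded when the contiguous region within 1% of the apex
    intensity (a flat top, typical of detector saturation) spans more than
    ``overload_span_s`` seconds.  Returns None when no peak is found (all-zero
    or monotone trace) — never raises for that case.
    """
    t, y = trace.times, trace.intensities
    nonzero = y[y > 0]
    if nonzero.size == 0:
        return None
    noise_floor = noise_multiplier * float(np.median(nonzero))
    apex = int(np.argmax(y))
    apex_int = float(y[apex])
    if apex_int <= noise_floor or apex == 0 or apex == len(y) - 1:
        return None
    apex_time, apex_int = _refine_apex(t, y, apex)
    half = _crossings(t, y, apex, apex_int / 2.0)
    if half is None:
        return None
    left50, right50 = half
    a, b = apex_time - left50, right50 - apex_time
    if a <= 0 or b <= 0:
        return None
    symmetry = 100.0 * min(a, b) / max(a, b)

    five = _crossings(t, y, apex, 0.05 * apex_int)
    if five is not None:
        a5, b5 = apex_time - five[0], five[1] - apex_time
        tailing = (a5 + b5) / (2.0 * a5) if a5 > 0 else float("nan")
    else:
        tailing = float("nan")

    # flat-top detection: contiguous samples within (1 - overload_level) of apex
    near = y >= overload_level * apex_int
    lo = apex
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = apex
    while hi < len(y) - 1 and near[hi + 1]:
        hi += 1
    overloaded = (t[hi] - t[lo]) > overload_span_s

    return ChromPeak(
        apex_time=apex_time,
        apex_intensity=apex_int,
        left50_time=left50,
        right50_time=right50,
        width50=right50 - left50,
        symmetry50=symmetry,
        tailing_factor=tailing,
        overloaded=bool(overloaded),
    )


@dataclass(frozen=True)
class CompoundScreen:
    """Per-compound screening outcome for one run."""

    compound_id: str
    found: bool
    peak: Optional[ChromPeak]
    pass_symmetry: bool
    pass_width: bool

    @property
    def pass_both(self) -> bool:
        return self.pass_symmetry and self.pass_width


@dataclass
class ScreenResult:
    """Aggregate of per-compound screens under one condition and polarity."""

    per_compound: list[CompoundScreen]
    criteria: SuitabilityCriteria

    @property
    def n_found(self) -> int:
        return sum(s.found for s in self.per_compound)

    @property
    def n_symmetry(self) -> int:
        return sum(s.pass_symmetry for s in self.per_compound)

    @property
    def n_width(self) -> int:
        return sum(s.pass_width for s in self.per_compound)

    @property
    def n_both(self) -> int:
        return sum(s.pass_both for s in self.per_compound)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.per_compound:
            rows.append({
                "compound_id": s.compound_id,
                "found": s.found,
                "width50_s": s.peak.width50 if s.peak else np.nan,
                "symmetry50_pct": s.peak.symmetry50 if s.peak else np.nan,
                "tailing_factor": s.peak.tailing_factor if s.peak else np.nan,
                "overloaded": s.peak.overloaded if s.peak else False,
                "pass_symmetry": s.pass_symmetry,
                "pass_width": s.pass_width,
                "pass_both": s.pass_both,
            })
        return pd.DataFrame(rows)


def screen_condition(
    run: MS1Run,
    compounds: Sequence[Compound],
    criteria: SuitabilityCriteria = SuitabilityCriteria(),
    ppm_tol: float = 5.0,
) -> ScreenResult:
    """Screen every compound's main peak in one run against the criteria.

    Compounds whose trace has no detectable peak are recorded with
    ``found=False`` and fail both criteria; the screen never aborts on a
    single compound.
    """
    per_compound = []
    for compound in compounds:
        mz = default_precursor_mz(compound.neutral_mass, run.polarity)
        trace = extract_trace(run, mz, ppm_tol)
        peak = detect_main_peak(trace)
        if peak is None:
            per_compound.append(CompoundScreen(compound.id, False, None, False, False))
            continue
        pass_sym, pass_wid = criteria.passes(peak)
        per_compound.append(CompoundScreen(compound.id, True, peak, pass_sym, pass_wid))
    return ScreenResult(per_compound=per_compound, criteria=criteria)


def rank_conditions(
    results: Sequence[tuple[str, Mapping[str, ScreenResult]]],
) -> list[tuple[str, int, int]]:
    """Rank conditions by worst-polarity pass-both count, descending.

    Each item is ``(label, {polarity: ScreenResult})``.  A condition is only
    as good as its weaker polarity (the same column must serve both), so the
    primary key is ``min`` over polarities of the pass-both count; ties break
    on the sum, then on label.  Returns ``(label, min_both, sum_both)``
    triples, best first.
    """
    if not results:
        raise ValueError("no conditions to rank")
    scored = []
    for label, by_polarity in results:
        counts = [res.n_both for res in by_polarity.values()]
        scored.append((label, min(counts), sum(counts)))
    scored.sort(key=lambda item: (-item[1], -item[2], item[0]))
    return scored
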