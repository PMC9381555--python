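"""High-selectivity fragment XIC extraction and peak integration.

Extraction sums centroid intensities within a narrow ppm tolerance of each
fragment m/z, one point per scan (zero-filled).  Peak boundaries are found
on the *reference* channel (the constant-amount isotope partner) and applied
unchanged to the analyte channel — the shared-boundary contract that makes
fragment-ratio comparisons between channels meaningful.  Integration is
plain trapezoidal with no baseline subtraction: background is characterised
separately from blank injections, and subtracting it here would count it
twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import Ms2ScanRecord

__all__ = [
    "Xic",
    "PeakResult",
    "NoPeakError",
    "extract_xic",
    "detect_peak",
    "integrate",
]


class NoPeakError(ValueError):
    """Reference trace carries no signal inside the schedule window."""


@dataclass(frozen=True)
class Xic:
    """A fragment-ion chromatogram: one intensity per scan, zero-filled."""

    target_id: str
    channel: str
    fragment_mz: float
    rt_seconds: np.ndarray
    intensity: np.ndarray
    scan_index: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.rt_seconds) <= 0):
            raise ValueError("retention times must be strictly increasing")


@dataclass(frozen=True)
class PeakResult:
    rt_start: float
    rt_end: float
    apex_rt: float
    apex_intensity: float

    def __post_init__(self) -> None:
        if not self.rt_start <= self.apex_rt <= self.rt_end:
            raise ValueError("apex must lie within the boundaries")

    @property
    def boundaries(self) -> tuple[float, float]:
        return (self.rt_start, self.rt_end)

    @property
    def width_s(self) -> float:
        return self.rt_end - self.rt_start


def extract_xic(
    scans: Sequence[Ms2ScanRecord], fragment_mz: float, tolerance_ppm: float = 10.0
) -> Xic:
    """Sum centroid intensities with |mz - fragment_mz| <= tol per scan.

    `scans` must be the time-ordered scans of a single run/target/channel.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    tol = fragment_mz * tolerance_ppm * 1e-6
    rt = np.array([s.rt_seconds for s in scans])
    idx = np.array([s.scan_index for s in scans])
    intensity = np.zeros(len(scans))
    for i, s in enumerate(scans):
        if s.mz.size == 0:
            continue
        lo = np.searchsorted(s.mz, fragment_mz - tol, side="left")
        hi = np.searchsorted(s.mz, fragment_mz + tol, side="right")
        if hi > lo:
            intensity[i] = s.intensity[lo:hi].sum()
    return Xic(
        target_id=scans[0].target_id if scans else "",
        channel=scans[0].channel if scans else "",
        fragment_mz=fragment_mz,
        rt_seconds=rt,
        intensity=intensity,
        scan_index=idx,
    )


def detect_peak(
    reference_xics: Sequence[Xic],
    schedule_window_s: tuple[float, float] | None = None,
    low_fraction: float = 0.01,
    valley_fraction: float = 0.10,
) -> PeakResult:
    """Find the elution peak on the summed reference-channel XICs.

    The summed trace is 3-point moving-average smoothed; the apex is its
    maximum inside the schedule window.  Boundaries walk outward to the
    nearest point where the smoothed trace drops below ``low_fraction`` of
    the apex, or a local minimum below ``valley_fraction`` of the apex,
    capped at the window edges.
    """
    if not reference_xics:
        raise NoPeakError("no reference XICs")
    rt = reference_xics[0].rt_seconds
    total = np.zeros_like(rt, dtype=float)
    for x in reference_xics:
        if x.rt_seconds.shape != rt.shape or not np.allclose(x.rt_seconds, rt):
            raise ValueError("reference XICs must share a time grid")
        total = total + x.intensity
    if schedule_window_s is None:
        in_win = np.ones(rt.size, dtype=bool)
    else:
        in_win = (rt >= schedule_window_s[0]) & (rt <= schedule_window_s[1])
    if not np.any(in_win) or not np.any(total[in_win] > 0):
        raise NoPeakError("flat reference signal inside the schedule window")

    s = np.empty_like(total)
    if total.size >= 3:
        s[1:-1] = (total[:-2] + total[1:-1] + total[2:]) / 3.0
        s[0] = (total[0] + total[1]) / 2.0
        s[-1] = (total[-2] + total[-1]) / 2.0
    else:
        s[:] = total

    win_idx = np.flatnonzero(in_win)
    apex = win_idx[int(np.argmax(s[win_idx]))]
    apex_val = s[apex]
    lo_thr = low_fraction * apex_val
    valley_thr = valley_fraction * apex_val

    left = apex
    while left > win_idx[0]:
        nxt = left - 1
        if s[nxt] <= lo_thr:
            left = nxt
            break
        if s[nxt] <= valley_thr and nxt > win_idx[0] and s[nxt - 1] >= s[nxt]:
            left = nxt
            break
        left = nxt
    right = apex
    while right < win_idx[-1]:
        nxt = right + 1
        if s[nxt] <= lo_thr:
            right = nxt
            break
        if s[nxt] <= valley_thr and nxt < win_idx[-1] and s[nxt + 1] >= s[nxt]:
            right = nxt
            break
        right = nxt

    return PeakResult(
        rt_start=float(rt[left]),
        rt_end=float(rt[right]),
        apex_rt=float(rt[apex]),
        apex_intensity=float(apex_val),
    )


def integrate(xic: Xic, boundaries: tuple[float, float]) -> float:
    """Trapezoidal area (intensity x seconds) between the boundaries."""
    t0, t1 = boundaries
    if t1 < t0:
        raise ValueError(f"inverted boundaries ({t0}, {t1})")
    rt, y = xic.rt_seconds, xic.intensity
    if t0 < rt[0] - 1e-9 or t1 > rt[-1] + 1e-9:
        raise ValueError("boundaries outside the XIC time range")
    mask = (rt >= t0) & (rt <= t1)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(y[mask], rt[mask]))
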