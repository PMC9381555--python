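"""Per-run processing: scans -> shared-boundary fragment areas per channel.

This is the plumbing between the scan stream and the statistics layers: for
one run and one target it extracts all fragment XICs in both channels,
detects the elution peak on the reference channel, and integrates every
fragment of both channels over those shared boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quantify
from .extract import NoPeakError, PeakResult, Xic, detect_peak, extract_xic, integrate
from .method import PrmTarget
from .simulate import Ms2ScanRecord, SimConfig, scans_for

__all__ = ["RunTargetResult", "process_run_target"]

DEFAULT_TOLERANCE_PPM = 10.0


@dataclass(frozen=True)
class RunTargetResult:
    """Shared-boundary fragment areas for one target in one run."""

    target_id: str
    fragments: tuple[str, ...]
    peak: PeakResult
    reference_channel: str
    areas_light: np.ndarray
    areas_heavy: np.ndarray
    apex_rt_light: np.ndarray
    apex_rt_heavy: np.ndarray
    reference_total_area: float

    def areas(self, channel: str) -> np.ndarray:
        return self.areas_light if channel == "light" else self.areas_heavy

    def fragment_quants(self, analyte_channel: str) -> list[quantify.FragmentQuant]:
        ref = "heavy" if analyte_channel == "light" else "light"
        return quantify.build_fragment_quants(
            self.fragments,
            self.areas(analyte_channel),
            self.areas(ref),
            self.apex_rt_light if analyte_channel == "light" else self.apex_rt_heavy,
            self.apex_rt_light if ref == "light" else self.apex_rt_heavy,
        )


def _apex_rt(xic: Xic, boundaries: tuple[float, float]) -> float:
    mask = (xic.rt_seconds >= boundaries[0]) & (xic.rt_seconds <= boundaries[1])
    if not mask.any() or not np.any(xic.intensity[mask] > 0):
        return float("nan")
    sub = np.flatnonzero(mask)
    return float(xic.rt_seconds[sub[np.argmax(xic.intensity[sub])]])


def process_run_target(
    scans: list[Ms2ScanRecord],
    target: PrmTarget,
    config: SimConfig,
    reference_channel: str = "light",
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> RunTargetResult:
    """Extract, detect on the reference channel, and integrate both channels.

    Raises :class:`NoPeakError` when the reference channel shows no elution
    peak inside the schedule window.
    """
    window = tuple(60.0 * x for x in target.rt_window_min)
    names = config.fragment_names(target)
    xics = {}
    for channel in ("light", "heavy"):
        ch_scans = scans_for(scans, target.target_id, channel)
        if not ch_scans:
            raise NoPeakError(f"no {channel}-channel scans for {target.target_id}")
        frag_mz = config.fragment_mz(target, channel)
        xics[channel] = [extract_xic(ch_scans, m, tolerance_ppm) for m in frag_mz]

    peak = detect_peak(xics[reference_channel], window)
    b = peak.boundaries
    areas = {
        ch: np.array([integrate(x, b) for x in xics[ch]]) for ch in ("light", "heavy")
    }
    apex = {ch: np.array([_apex_rt(x, b) for x in xics[ch]]) for ch in ("light", "heavy")}
    return RunTargetResult(
        target_id=target.target_id,
        fragments=tuple(names),
        peak=peak,
        reference_channel=reference_channel,
        areas_light=areas["light"],
        areas_heavy=areas["heavy"],
        apex_rt_light=apex["light"],
        apex_rt_heavy=apex["heavy"],
        reference_total_area=float(areas[reference_channel].sum()),
    )
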