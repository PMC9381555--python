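"""Scheduled FAIMS-PRM method model and compensation-voltage scan analysis.

A method is a set of :class:`PrmTarget` rows (gene, peptide, charge, light
precursor m/z, FAIMS compensation voltage, collision energy, scheduled
retention time).  The published 11-row method ships with the package and can
be regenerated from sequence + charge alone, which is the round-trip check
on the chemistry layer.

``analyze_cv_scan`` reduces a direct-infusion compensation-voltage scan to
the transmission optimum, a plateau range and the half-maximal range.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem

__all__ = [
    "PrmTarget",
    "CvScanCurve",
    "CvScanResult",
    "MethodConsistencyError",
    "NoSignalError",
    "load_method_table",
    "read_method_csv",
    "write_method_csv",
    "build_method",
    "analyze_cv_scan",
    "MZ_CONSISTENCY_TOL",
]

#: Max |printed - computed| light precursor m/z tolerated when validating a
#: method row.  One unit of the last printed decimal: published tables are
#: rounded to 2 dp from software whose mass constants differ in the 5th
#: decimal, so half-ulp knife-edges occur (and do, for LVVVGACGVGK).
MZ_CONSISTENCY_TOL = 0.01


class MethodConsistencyError(ValueError):
    """A method row's m/z disagrees with the sequence-derived value."""


class NoSignalError(ValueError):
    """CV scan contains no positive intensity."""


@dataclass(frozen=True)
class PrmTarget:
    """One scheduled precursor: light/heavy pair sharing a retention window."""

    gene: str
    sequence: str
    charge: int
    light_mz: float
    heavy_mz: float
    compensation_voltage: float
    collision_energy: float
    scheduled_rt_min: float
    rt_window_half_min: float = 2.0

    def __post_init__(self) -> None:
        if not -100.0 <= self.compensation_voltage <= 0.0:
            raise ValueError(
                f"compensation voltage {self.compensation_voltage} V outside [-100, 0]"
            )
        if self.heavy_mz <= self.light_mz:
            raise ValueError("heavy precursor m/z must exceed light")

    @property
    def target_id(self) -> str:
        return f"{self.gene}_{self.sequence}_{self.charge}"

    @property
    def light(self) -> chem.PeptideSpec:
        return chem.PeptideSpec(self.sequence, self.charge, "light")

    @property
    def heavy(self) -> chem.PeptideSpec:
        return chem.PeptideSpec(self.sequence, self.charge, "heavy")

    @property
    def rt_window_min(self) -> tuple[float, float]:
        return (
            self.scheduled_rt_min - self.rt_window_half_min,
            self.scheduled_rt_min + self.rt_window_half_min,
        )

    @classmethod
    def from_sequence(
        cls,
        gene: str,
        sequence: str,
        charge: int,
        compensation_voltage: float = -50.0,
        collision_energy: float = 22.0,
        scheduled_rt_min: float = 20.0,
        rt_window_half_min: float = 2.0,
    ) -> "PrmTarget":
        """Build a target with both channel m/z computed from the sequence."""
        light = chem.PeptideSpec(sequence, charge, "light")
        heavy = chem.PeptideSpec(sequence, charge, "heavy")
        return cls(
            gene=gene,
            sequence=sequence,
            charge=charge,
            light_mz=chem.precursor_mz(light),
            heavy_mz=chem.precursor_mz(heavy),
            compensation_voltage=compensation_voltage,
            collision_energy=collision_energy,
            scheduled_rt_min=scheduled_rt_min,
            rt_window_half_min=rt_window_half_min,
        )


def read_method_csv(path_or_buf) -> list[PrmTarget]:
    """Read a method table (gene, peptide, z, mz_light, cv_volts, ce, rt_min)."""
    df = pd.read_csv(path_or_buf)
    targets = []
    for row in df.itertuples(index=False):
        heavy = chem.precursor_mz(chem.PeptideSpec(row.peptide, int(row.z), "heavy"))
        targets.append(
            PrmTarget(
                gene=str(row.gene),
                sequence=str(row.peptide),
                charge=int(row.z),
                light_mz=float(row.mz_light),
                heavy_mz=heavy,
                compensation_voltage=float(row.cv_volts),
                collision_energy=float(row.ce),
                scheduled_rt_min=float(row.rt_min),
            )
        )
    return targets


def write_method_csv(targets: list[PrmTarget], path) -> None:
    df = pd.DataFrame(
        {
            "gene": [t.gene for t in targets],
            "peptide": [t.sequence for t in targets],
            "z": [t.charge for t in targets],
            "mz_light": [round(t.light_mz, 4) for t in targets],
            "cv_volts": [t.compensation_voltage for t in targets],
            "ce": [t.collision_energy for t in targets],
            "rt_min": [t.scheduled_rt_min for t in targets],
        }
    )
    df.to_csv(path, index=False)


def load_method_table() -> list[PrmTarget]:
    """The published 11-precursor FAIMS-PRM method bundled with the package."""
    ref = importlib.resources.files("faimsprm.data") / "table1_method.csv"
    with ref.open("r") as fh:
        return read_method_csv(fh)


def build_method(
    targets: list[PrmTarget],
    rt_window_half_min: float | None = None,
    mz_tol: float = MZ_CONSISTENCY_TOL,
) -> list[PrmTarget]:
    """Validate targets against the chemistry layer and set schedule windows.

    Each row's light m/z must agree with the sequence-derived precursor m/z
    within `mz_tol`; a violation raises :class:`MethodConsistencyError`
    naming the row.  Returns (possibly re-windowed) targets; empty input is
    an empty method.
    """
    out = []
    for t in targets:
        computed = chem.precursor_mz(t.light)
        if abs(computed - t.light_mz) > mz_tol:
            raise MethodConsistencyError(
                f"{t.target_id}: method m/z {t.light_mz} vs computed "
                f"{computed:.4f} (|diff| > {mz_tol})"
            )
        if rt_window_half_min is not None:
            t = replace(t, rt_window_half_min=rt_window_half_min)
        out.append(t)
    return out


@dataclass(frozen=True)
class CvScanCurve:
    """A direct-infusion compensation-voltage scan (voltage, intensity) curve."""

    voltages: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if v.size != i.size:
            raise ValueError("voltages and intensities differ in length")
        dv = np.diff(v)
        if v.size >= 2 and not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("voltages must be strictly monotone")
        if np.any(i < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def step_volts(self) -> float:
        v = np.asarray(self.voltages, dtype=float)
        return float(np.median(np.abs(np.diff(v)))) if v.size >= 2 else 0.0

    @classmethod
    def from_arrays(cls, voltages, intensities) -> "CvScanCurve":
        return cls(tuple(float(x) for x in voltages), tuple(float(x) for x in intensities))


@dataclass(frozen=True)
class CvScanResult:
    cv_optimal: float
    plateau_range: tuple[float, float]
    half_max_range: tuple[float, float]


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with truncated edges."""
    if y.size < 3:
        return y.copy()
    out = np.empty_like(y, dtype=float)
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    out[0] = (y[0] + y[1]) / 2.0
    out[-1] = (y[-2] + y[-1]) / 2.0
    return out


def _threshold_range(
    v: np.ndarray, s: np.ndarray, apex_idx: int, threshold: float
) -> tuple[float, float]:
    """Supra-threshold run containing the apex, endpoints interpolated."""
    lo = apex_idx
    while lo > 0 and s[lo - 1] >= threshold:
        lo -= 1
    hi = apex_idx
    while hi < s.size - 1 and s[hi + 1] >= threshold:
        hi += 1
    # interpolate the crossing just outside the run, if any
    left = v[lo]
    if lo > 0 and s[lo] != s[lo - 1]:
        frac = (s[lo] - threshold) / (s[lo] - s[lo - 1])
        left = v[lo] + frac * (v[lo - 1] - v[lo])
    right = v[hi]
    if hi < s.size - 1 and s[hi] != s[hi + 1]:
        frac = (s[hi] - threshold) / (s[hi] - s[hi + 1])
        right = v[hi] + frac * (v[hi + 1] - v[hi])
    return (min(left, right), max(left, right))


def analyze_cv_scan(
    curve: CvScanCurve,
    plateau_fraction: float = 0.9,
    half_fraction: float = 0.5,
) -> CvScanResult:
    """Locate the transmission optimum and supra-threshold voltage ranges.

    The intensity trace is 3-point moving-average smoothed; the optimum is
    the voltage of the smoothed maximum (ties break toward the most negative
    voltage, the direction the scan is acquired in).  The plateau and
    half-max ranges are the contiguous supra-threshold runs containing the
    optimum, with endpoints linearly interpolated between grid points, so
    half_max_range always contains plateau_range which contains cv_optimal.
    """
    v = np.asarray(curve.voltages, dtype=float)
    y = np.asarray(curve.intensities, dtype=float)
    if v.size < 5:
        raise ValueError("CV scan needs at least 5 points")
    if not np.any(y > 0):
        raise NoSignalError("all-zero CV scan")
    order = np.argsort(v)
    v, y = v[order], y[order]
    s = _smooth3(y)
    smax = s.max()
    # ties -> most negative voltage; v is ascending so argmax of the reversed
    # array picks the last ascending index... use first occurrence on v-sorted
    apex_idx = int(np.flatnonzero(s == smax)[0])
    plateau = _threshold_range(v, s, apex_idx, plateau_fraction * smax)
    halfmax = _threshold_range(v, s, apex_idx, half_fraction * smax)
    return CvScanResult(
        cv_optimal=float(v[apex_idx]),
        plateau_range=plateau,
        half_max_range=halfmax,
    )
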