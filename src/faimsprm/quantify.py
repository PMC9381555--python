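"""Stable-isotope-ratio quantitation and interference flagging.

A peptide amount is the analyte/reference fragment area ratio times the
known reference spike (default 5 fmol = 5000 amol) over the loaded mass
(default 1 ug), i.e. amol/ug.  Fragments whose relative-abundance pattern or
apex time disagrees between the two channels are flagged as interfered and
excluded from quantitation, mirroring the manual coelution / fragment-ratio
review done on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FragmentQuant",
    "PeptideQuant",
    "CannotAssessError",
    "QuantitationFailedError",
    "build_fragment_quants",
    "flag_interference",
    "quantify_peptide",
]


class CannotAssessError(ValueError):
    """No fragment has a usable reference area."""


class QuantitationFailedError(ValueError):
    """Every fragment was flagged; no quantitation possible."""


@dataclass(frozen=True)
class FragmentQuant:
    """Per-fragment areas and channel-relative abundances for one peptide."""

    fragment: str
    area_analyte: float
    area_reference: float
    rel_abundance_analyte: float
    rel_abundance_reference: float
    apex_rt_analyte: float
    apex_rt_reference: float
    flagged: bool = False
    flag_reason: str = ""


@dataclass(frozen=True)
class PeptideQuant:
    target_id: str
    used_fragments: tuple[str, ...]
    ratio_to_reference: float
    amount_amol_per_ug: float


def build_fragment_quants(
    fragments: Sequence[str],
    areas_analyte: Sequence[float],
    areas_reference: Sequence[float],
    apex_rt_analyte: Sequence[float] | None = None,
    apex_rt_reference: Sequence[float] | None = None,
) -> list[FragmentQuant]:
    """Assemble fragment records; relative abundances are computed over the
    full fragment set (before any flagging) and sum to 1 per channel."""
    a = np.asarray(areas_analyte, dtype=float)
    r = np.asarray(areas_reference, dtype=float)
    rel_a = a / a.sum() if a.sum() > 0 else np.zeros_like(a)
    rel_r = r / r.sum() if r.sum() > 0 else np.zeros_like(r)
    n = len(fragments)
    ta = apex_rt_analyte if apex_rt_analyte is not None else [np.nan] * n
    tr = apex_rt_reference if apex_rt_reference is not None else [np.nan] * n
    return [
        FragmentQuant(
            fragment=str(f),
            area_analyte=float(a[i]),
            area_reference=float(r[i]),
            rel_abundance_analyte=float(rel_a[i]),
            rel_abundance_reference=float(rel_r[i]),
            apex_rt_analyte=float(ta[i]),
            apex_rt_reference=float(tr[i]),
        )
        for i, f in enumerate(fragments)
    ]


def flag_interference(
    frag_quants: Sequence[FragmentQuant],
    max_ratio_deviation_pct: float = 30.0,
    max_apex_shift_fraction: float = 0.5,
    peak_width_s: float | None = None,
) -> list[FragmentQuant]:
    """Flag fragments whose two channels disagree.

    A fragment is interfered when its analyte relative abundance deviates
    from the reference relative abundance by more than
    ``max_ratio_deviation_pct`` percent (default 30, the 70-130% rubric), or
    when its apex shifts by more than ``max_apex_shift_fraction`` of the
    peak width (coelution failure; only assessed when both apexes and a
    width are available).
    """
    if len(frag_quants) < 2:
        raise CannotAssessError("need >= 2 fragments to assess interference")
    if not any(f.area_reference > 0 for f in frag_quants):
        raise CannotAssessError("all reference areas are zero")
    out = []
    for f in frag_quants:
        reason = ""
        if f.rel_abundance_reference > 0:
            dev = abs(f.rel_abundance_analyte - f.rel_abundance_reference) / (
                f.rel_abundance_reference
            )
            if dev > max_ratio_deviation_pct / 100.0:
                reason = f"fragment-ratio deviation {100 * dev:.0f}%"
        if (
            not reason
            and peak_width_s is not None
            and np.isfinite(f.apex_rt_analyte)
            and np.isfinite(f.apex_rt_reference)
        ):
            shift = abs(f.apex_rt_analyte - f.apex_rt_reference)
            if shift > max_apex_shift_fraction * peak_width_s:
                reason = f"apex shift {shift:.1f}s exceeds {max_apex_shift_fraction:g} peak widths"
        out.append(replace(f, flagged=bool(reason), flag_reason=reason))
    return out


def quantify_peptide(
    frag_quants: Sequence[FragmentQuant],
    mode: Literal["summed", "best", "per-fragment"] = "summed",
    spike_amol: float = 5000.0,
    loaded_ug: float = 1.0,
    target_id: str = "",
    fragment: str | None = None,
) -> PeptideQuant:
    """Analyte amount from the isotope ratio of unflagged fragments.

    ``summed`` uses sum(analyte areas)/sum(reference areas); ``best`` the
    single unflagged fragment with the highest reference area (the
    single-sample proxy for the best-performing fragment); ``per-fragment``
    requires `fragment` and uses that fragment alone.
    """
    usable = [f for f in frag_quants if not f.flagged]
    if mode == "per-fragment":
        if fragment is None:
            raise ValueError("per-fragment mode needs a fragment name")
        usable = [f for f in usable if f.fragment == fragment]
    if not usable:
        raise QuantitationFailedError("no unflagged fragment available")
    if mode == "best":
        usable = [max(usable, key=lambda f: f.area_reference)]
    ref = sum(f.area_reference for f in usable)
    if ref <= 0:
        raise QuantitationFailedError("reference area is zero")
    ratio = sum(f.area_analyte for f in usable) / ref
    return PeptideQuant(
        target_id=target_id,
        used_fragments=tuple(f.fragment for f in usable),
        ratio_to_reference=float(ratio),
        amount_amol_per_ug=float(ratio * spike_amol / loaded_ug),
    )
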