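"""Peptide chemistry for stable-isotope-dilution PRM assays.

Monoisotopic masses, fixed carbamidomethyl-cysteine, C-terminal heavy-isotope
labels (K [13C6,15N2] / R [13C6,15N4]) and precursor / b,y fragment m/z
computation.  All masses are monoisotopic; protonation uses the proton mass,
not the hydrogen atom.

Only the singly-charged-proton convention is implemented: an n-fold
protonated species has m/z = (M + n * PROTON) / n.  Average masses, isotope
envelopes, neutral losses and a/c/x/z series are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from pyteomics import mass as _pmass

__all__ = [
    "PROTON",
    "WATER",
    "CARBAMIDOMETHYL",
    "HEAVY_SHIFT",
    "InvalidSequenceError",
    "InvalidLabelError",
    "PeptideSpec",
    "FragmentIon",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_ladder",
    "mz_display",
]

PROTON = 1.00727646688
WATER = _pmass.calculate_mass(formula="H2O")  # 18.0105646...
CARBAMIDOMETHYL = 57.021464  # fixed modification on every Cys

# 13C-12C and 15N-14N mass differences
_C13 = 13.00335484 - 12.0
_N15 = 15.00010890 - 14.00307401
#: Mass shift of the C-terminal residue in the heavy (SIL) channel.
HEAVY_SHIFT = {
    "K": 6 * _C13 + 2 * _N15,  # +8.014199 Da
    "R": 6 * _C13 + 4 * _N15,  # +10.008269 Da
}

_AA_MONO = dict(_pmass.std_aa_mass)  # 20 standard residue masses
_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class InvalidSequenceError(ValueError):
    """Sequence is empty or contains a non-standard residue letter."""


class InvalidLabelError(ValueError):
    """Heavy label requested on a peptide not ending in K or R."""


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide in one isotope channel at one charge state.

    ``label_state='heavy'`` places a 13C/15N label on the C-terminal residue,
    which must be K or R.  ``fixed_cam_cys`` applies carbamidomethylation to
    every cysteine (the assay's fixed modification).
    """

    sequence: str
    charge: int = 2
    label_state: Literal["light", "heavy"] = "light"
    fixed_cam_cys: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError("empty peptide sequence")
        bad = set(self.sequence) - _VALID_AA
        if bad:
            raise InvalidSequenceError(
                f"non-standard residue(s) {sorted(bad)} in {self.sequence!r}"
            )
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.label_state not in ("light", "heavy"):
            raise ValueError(f"unknown label state {self.label_state!r}")
        if self.label_state == "heavy" and self.sequence[-1] not in HEAVY_SHIFT:
            raise InvalidLabelError(
                f"heavy label requires C-terminal K or R, got "
                f"{self.sequence[-1]!r} in {self.sequence!r}"
            )

    @property
    def heavy_shift(self) -> float:
        """Label mass shift of this spec (0 for the light channel)."""
        if self.label_state == "heavy":
            return HEAVY_SHIFT[self.sequence[-1]]
        return 0.0

    def as_heavy(self) -> "PeptideSpec":
        return PeptideSpec(self.sequence, self.charge, "heavy", self.fixed_cam_cys)

    def as_light(self) -> "PeptideSpec":
        return PeptideSpec(self.sequence, self.charge, "light", self.fixed_cam_cys)


@dataclass(frozen=True)
class FragmentIon:
    """One b- or y-series fragment ion of a peptide."""

    series: Literal["b", "y"]
    ordinal: int
    charge: int
    mz: float

    @property
    def name(self) -> str:
        suffix = "" if self.charge == 1 else f"^{self.charge}"
        return f"{self.series}{self.ordinal}{suffix}"


def _residue_sum(sequence: str, cam: bool) -> float:
    try:
        total = sum(_AA_MONO[a] for a in sequence)
    except KeyError as exc:  # pragma: no cover - guarded by PeptideSpec
        raise InvalidSequenceError(str(exc)) from exc
    if cam:
        total += CARBAMIDOMETHYL * sequence.count("C")
    return total


def monoisotopic_mass(peptide: PeptideSpec) -> float:
    """Neutral monoisotopic mass in Da, including fixed CAM and label shift."""
    return _residue_sum(peptide.sequence, peptide.fixed_cam_cys) + WATER + peptide.heavy_shift


def precursor_mz(peptide: PeptideSpec) -> float:
    """Precursor m/z in Th at the spec's charge; no display rounding."""
    z = peptide.charge
    return (monoisotopic_mass(peptide) + z * PROTON) / z


def mz_display(mz: float, decimals: int = 2) -> float:
    """Round half-up to `decimals`, the convention of printed method tables."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(mz)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def fragment_ladder(peptide: PeptideSpec, max_fragment_charge: int = 1) -> list[FragmentIon]:
    """All b and y ions, ordinals 1..n-1, charges 1..max_fragment_charge.

    The heavy label sits on the C-terminal residue, so it shifts every y ion
    and no b ion.  b = N-terminal residue sum + z protons; y = C-terminal
    residue sum + water + z protons (each divided by z).
    """
    seq = peptide.sequence
    n = len(seq)
    if n < 2:
        raise InvalidSequenceError("fragment ladder needs length >= 2")
    cam = peptide.fixed_cam_cys
    ions: list[FragmentIon] = []
    for k in range(1, n):
        b_neutral = _residue_sum(seq[:k], cam)
        y_neutral = _residue_sum(seq[k:], cam) + WATER + peptide.heavy_shift
        ordinal_y = n - k
        for z in range(1, max_fragment_charge + 1):
            ions.append(FragmentIon("b", k, z, (b_neutral + z * PROTON) / z))
            ions.append(FragmentIon("y", ordinal_y, z, (y_neutral + z * PROTON) / z))
    ions.sort(key=lambda f: (f.series, f.ordinal, f.charge))
    return ions
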