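"""Synthetic scheduled-PRM scan streams, LOQ study designs and cohorts.

The generator emulates the acquisition the analysis chain assumes:

* scheduled PRM with 0.7 m/z isolation, AGC target 1e6 ions and a 100 ms
  maximum injection time — when total flux F (ions/ms) exceeds 1e4 the fill
  time shortens to ``agc_target / F``;
* Gaussian chromatographic elution (~20 s base width) sampled on a fixed
  duty cycle, one MS/MS scan per channel per cycle inside the target's
  retention window;
* ion counting: every centroid's ion count is a Poisson draw whose rate is
  flux x injection time; reported intensities are ions per ms, so peak
  heights are fill-time invariant; the scan's total ion count plays the
  role of the vendor RawOvFtT field;
* signal ions split over a fixed per-target fragment pattern (identical in
  the light and heavy channel, as for a true isotope pair);
* a structureless chemical background, uniform in m/z over the isolation
  product window [200, 1300] Th: ion-exact within narrow zones around each
  monitored fragment (so extraction sees honestly sampled in-tolerance
  background) and coarse-grained into a fixed number of centroids elsewhere;
* FAIMS mode multiplies the background flux by a per-target retention
  fraction (1 - fractional reduction) and the signal by a transmission
  factor (default 1: the compensation voltage is assumed optimised for
  full transmission of each target).

A reverse-dilution LOQ study (constant 5 fmol light spike, ten-point
threefold heavy dilution from 100 fmol to 5 amol, blanks and double blanks)
and a clinical cohort with per-gene latent truths are built on top of the
single-run generator.  All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so identical inputs give identical
byte-level output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem
from .method import PrmTarget

__all__ = [
    "MZ_SPAN",
    "DILUTION_GRID_AMOL",
    "Ms2ScanRecord",
    "InterferenceSpec",
    "SimConfig",
    "StudyDesign",
    "RunSpec",
    "simulate_run",
    "generate_loq_study",
    "iter_study_runs",
    "generate_clinical_cohort",
    "iter_cohort_runs",
    "simulate_cv_scan",
    "scans_for",
    "blank_sample",
    "double_blank_sample",
]

#: m/z span of the simulated centroided MS/MS scans.
MZ_SPAN = (200.0, 1300.0)

#: The ten-point reverse-dilution grid in amol, as printed on the published
#: curves: 100 fmol diluted threefold down to 5 amol.
DILUTION_GRID_AMOL = (100000, 33333, 11111, 3704, 1235, 412, 137, 46, 15, 5)

Channel = Literal["light", "heavy"]


@dataclass
class Ms2ScanRecord:
    """One centroided MS/MS scan of one precursor channel."""

    run_id: str
    scan_index: int
    rt_seconds: float
    target_id: str
    channel: Channel
    isolation_center_mz: float
    isolation_width: float
    compensation_voltage: float | None
    injection_time_ms: float
    total_ion_count: int
    mz: np.ndarray
    intensity: np.ndarray  # ions per ms

    def __post_init__(self) -> None:
        if self.total_ion_count < 0:
            raise ValueError("total_ion_count must be >= 0")
        if not 0 < self.injection_time_ms <= 100.0:
            raise ValueError("injection_time_ms must be in (0, 100]")


@dataclass(frozen=True)
class InterferenceSpec:
    """A coeluting interfering species landing at a specific fragment m/z."""

    target_id: str
    channel: Channel
    mz: float
    apex_offset_s: float
    apex_ions_per_ms: float
    fwhm_s: float = 12.0


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and sample-matrix model for the scan generator.

    response_factor
        Ions per amol per scan at the elution apex at a full 100 ms fill;
        signal flux in ions/ms is ``amount * response_factor * g(t) / 100``.
    background_flux
        Chemical background in ions/ms entering the isolation window in
        no-FAIMS mode; scalar or per-target mapping.
    faims_background_retention
        Fraction of the background flux surviving FAIMS per target (the
        published per-target reductions span 13-86%, i.e. retention
        0.14-0.87); scalar or per-target mapping.
    measurement_cv
        Multiplicative (lognormal) per-run, per-channel amount noise
        emulating spiking/handling variability.
    """

    targets: tuple[PrmTarget, ...]
    response_factor: float = 2.0
    peak_fwhm_s: float = 11.8
    cycle_time_s: float = 3.3
    background_flux: float | Mapping[str, float] = 1000.0
    faims_background_retention: float | Mapping[str, float] = 0.5
    faims_signal_transmission: float = 1.0
    measurement_cv: float = 0.08
    rt_jitter_s: float = 1.0
    mz_jitter_ppm: float = 2.0
    n_fragments: int = 5
    n_background_centroids: int = 40
    fine_zone_half_mz: float = 0.02
    agc_target: float = 1.0e6
    max_injection_ms: float = 100.0
    isolation_width: float = 0.7
    interference_specs: tuple[InterferenceSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_factor < 0 or self.measurement_cv < 0:
            raise ValueError("rates and noise scales must be >= 0")
        if not 0.0 <= self.faims_signal_transmission <= 1.0:
            raise ValueError("faims_signal_transmission must be in [0, 1]")
        for r in self._retention_map().values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("faims_background_retention must be in [0, 1]")
        for b in self._background_map().values():
            if b < 0:
                raise ValueError("background_flux must be >= 0")

    def _background_map(self) -> dict[str, float]:
        if isinstance(self.background_flux, Mapping):
            return dict(self.background_flux)
        return {t.target_id: float(self.background_flux) for t in self.targets}

    def _retention_map(self) -> dict[str, float]:
        if isinstance(self.faims_background_retention, Mapping):
            return dict(self.faims_background_retention)
        return {t.target_id: float(self.faims_background_retention) for t in self.targets}

    def fragment_mz(self, target: PrmTarget, channel: Channel) -> np.ndarray:
        """Monitored fragment m/z for one channel (y ions, singly charged).

        The panel is the ``n_fragments`` largest-ordinal singly charged
        y ions whose m/z falls inside the scan span for both channels; the
        heavy channel carries the C-terminal label shift on every y ion.
        """
        pep = target.heavy if channel == "heavy" else target.light
        shift = chem.HEAVY_SHIFT[target.sequence[-1]]
        lo, hi = MZ_SPAN
        ions = [
            f
            for f in chem.fragment_ladder(target.light, max_fragment_charge=1)
            if f.series == "y"
            and f.ordinal >= 3
            and lo <= f.mz
            and f.mz + shift <= hi
        ]
        ions.sort(key=lambda f: -f.ordinal)
        ions = sorted(ions[: self.n_fragments], key=lambda f: f.ordinal)
        offset = shift if channel == "heavy" else 0.0
        return np.array([f.mz + offset for f in ions])

    def fragment_names(self, target: PrmTarget) -> list[str]:
        light_mz = self.fragment_mz(target, "light")
        ladder = {
            round(f.mz, 6): f.name
            for f in chem.fragment_ladder(target.light, max_fragment_charge=1)
            if f.series == "y"
        }
        return [ladder[round(m, 6)] for m in light_mz]

    def fragment_pattern(self, target: PrmTarget) -> np.ndarray:
        """Fixed fractional fragment intensity pattern, drawn once per config.

        Identical for the light and heavy channel (a true isotope pair
        fragments identically), which is what makes the 70-130% fragment
        ratio criterion satisfiable on clean data.
        """
        idx = [t.target_id for t in self.targets].index(target.target_id)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, 7919, idx])
        )
        n = len(self.fragment_mz(target, "light"))
        pat = rng.dirichlet(np.full(n, 3.0))
        # avoid vanishing fragments: floor at 5% and renormalise
        pat = np.maximum(pat, 0.05)
        return pat / pat.sum()


def blank_sample(config: SimConfig, light_amol: float = 5000.0) -> dict[str, tuple[float, float]]:
    """Light spike plus matrix, no heavy peptide."""
    return {t.target_id: (light_amol, 0.0) for t in config.targets}


def double_blank_sample(config: SimConfig) -> dict[str, tuple[float, float]]:
    """Matrix only."""
    return {t.target_id: (0.0, 0.0) for t in config.targets}


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_run(
    config: SimConfig,
    sample: Mapping[str, tuple[float, float]],
    faims_on: bool,
    seed,
    run_id: str = "run",
) -> list[Ms2ScanRecord]:
    """Simulate one injection: a time-ordered list of MS/MS scans.

    `sample` maps target_id -> (light_amol, heavy_amol) on column; targets
    absent from the mapping are acquired with zero signal.  `seed` may be an
    int or a ``numpy.random.SeedSequence``.
    """
    for amounts in sample.values():
        if min(amounts) < 0:
            raise ValueError("peptide amounts must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    bg_map = config._background_map()
    ret_map = config._retention_map()
    sigma = config.peak_fwhm_s / 2.354820045
    lo, hi = MZ_SPAN
    span = hi - lo
    scans: list[Ms2ScanRecord] = []

    for target in config.targets:
        light_amol, heavy_amol = sample.get(target.target_id, (0.0, 0.0))
        apex_rt = target.scheduled_rt_min * 60.0 + rng.normal(0.0, config.rt_jitter_s)
        w0, w1 = (60.0 * x for x in target.rt_window_min)
        n0 = int(np.ceil(w0 / config.cycle_time_s))
        n1 = int(np.floor(w1 / config.cycle_time_s))
        times = np.arange(n0, n1 + 1) * config.cycle_time_s
        if times.size == 0:
            continue
        g = np.exp(-0.5 * ((times - apex_rt) / sigma) ** 2)
        bg_flux = bg_map.get(target.target_id, 0.0)
        if faims_on:
            bg_flux *= ret_map.get(target.target_id, 1.0)

        for channel, amount in (("light", light_amol), ("heavy", heavy_amol)):
            frag_mz = config.fragment_mz(target, channel)
            nfrag = frag_mz.size
            pattern = config.fragment_pattern(target)
            noise = _lognormal_factor(rng, config.measurement_cv)
            eff_amount = amount * noise
            if faims_on:
                eff_amount *= config.faims_signal_transmission
            sig_flux = eff_amount * config.response_factor * g / config.max_injection_ms

            intf = [
                s
                for s in config.interference_specs
                if s.target_id == target.target_id and s.channel == channel
            ]
            intf_flux = np.zeros((times.size, len(intf)))
            for j, s in enumerate(intf):
                s_sigma = s.fwhm_s / 2.354820045
                intf_flux[:, j] = s.apex_ions_per_ms * np.exp(
                    -0.5 * ((times - (apex_rt + s.apex_offset_s)) / s_sigma) ** 2
                )

            total_flux = sig_flux + bg_flux + intf_flux.sum(axis=1)
            with np.errstate(divide="ignore"):
                it = np.where(
                    total_flux > 0,
                    np.minimum(config.max_injection_ms, config.agc_target / total_flux),
                    config.max_injection_ms,
                )

            # --- Poisson ion counts, vectorised over scans -----------------
            sig_counts = rng.poisson(np.outer(sig_flux * it, pattern))
            zone_w = 2.0 * config.fine_zone_half_mz
            fine_rate = bg_flux * it * (zone_w / span)
            fine_counts = rng.poisson(np.repeat(fine_rate[:, None], nfrag, axis=1))
            k = config.n_background_centroids
            out_rate = bg_flux * it * (1.0 - nfrag * zone_w / span)
            coarse_counts = rng.poisson(np.repeat(out_rate[:, None] / k, k, axis=1))
            intf_counts = (
                rng.poisson(intf_flux * it[:, None])
                if intf
                else np.zeros((times.size, 0), dtype=np.int64)
            )

            # centroid positions
            ppm = config.mz_jitter_ppm * 1e-6
            sig_mz = frag_mz[None, :] * (
                1.0 + rng.normal(0.0, ppm, size=sig_counts.shape)
            )
            fine_mz = frag_mz[None, :] + rng.uniform(
                -config.fine_zone_half_mz, config.fine_zone_half_mz, size=fine_counts.shape
            )
            coarse_mz = rng.uniform(lo, hi, size=coarse_counts.shape)
            # keep coarse centroids out of the ion-exact fine zones
            for _ in range(4):
                bad = np.zeros(coarse_mz.shape, dtype=bool)
                for fmz in frag_mz:
                    bad |= np.abs(coarse_mz - fmz) < config.fine_zone_half_mz
                if not bad.any():
                    break
                coarse_mz[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
            intf_mz = np.array([s.mz for s in intf])[None, :] * np.ones(
                (times.size, max(len(intf), 1))
            )[:, : len(intf)]

            tic = (
                sig_counts.sum(axis=1)
                + fine_counts.sum(axis=1)
                + coarse_counts.sum(axis=1)
                + (intf_counts.sum(axis=1) if intf else 0)
            )
            iso_center = target.heavy_mz if channel == "heavy" else target.light_mz

            for i, t in enumerate(times):
                mz_parts = [sig_mz[i], fine_mz[i], coarse_mz[i]]
                ct_parts = [sig_counts[i], fine_counts[i], coarse_counts[i]]
                if intf:
                    mz_parts.append(intf_mz[i])
                    ct_parts.append(intf_counts[i])
                mz = np.concatenate(mz_parts)
                ct = np.concatenate(ct_parts).astype(float)
                keep = ct > 0
                mz, ct = mz[keep], ct[keep]
                order = np.argsort(mz)
                scans.append(
                    Ms2ScanRecord(
                        run_id=run_id,
                        scan_index=0,  # assigned after global time sort
                        rt_seconds=float(t),
                        target_id=target.target_id,
                        channel=channel,
                        isolation_center_mz=float(iso_center),
                        isolation_width=config.isolation_width,
                        compensation_voltage=(
                            target.compensation_voltage if faims_on else None
                        ),
                        injection_time_ms=float(it[i]),
                        total_ion_count=int(tic[i]),
                        mz=mz[order],
                        intensity=ct[order] / float(it[i]),
                    )
                )

    scans.sort(key=lambda s: (s.rt_seconds, s.target_id, s.channel))
    for i, s in enumerate(scans):
        s.scan_index = i
    return scans


def scans_for(
    scans: Sequence[Ms2ScanRecord], target_id: str, channel: Channel
) -> list[Ms2ScanRecord]:
    """Time-ordered scans of one target/channel within a run."""
    return [s for s in scans if s.target_id == target_id and s.channel == channel]


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Reverse-dilution LOQ study layout.

    The published design: both conditions, two curves per condition, the
    ten-point threefold heavy dilution, a constant 5 fmol light spike, four
    replicates per level, blank and double blank — 192 injections in all.
    """

    conditions: tuple[str, ...] = ("faims", "nofaims")
    curves_per_condition: int = 2
    dilution_levels_amol: tuple[float, ...] = DILUTION_GRID_AMOL
    light_spike_fmol: float = 5.0
    replicates_per_level: int = 4
    include_blank: bool = True
    include_double_blank: bool = True

    def __post_init__(self) -> None:
        lv = self.dilution_levels_amol
        if any(b >= a for a, b in zip(lv, lv[1:])):
            raise ValueError("dilution levels must be strictly decreasing")
        for c in self.conditions:
            if c not in ("faims", "nofaims"):
                raise ValueError(f"unknown condition {c!r}")

    @property
    def light_spike_amol(self) -> float:
        return self.light_spike_fmol * 1000.0

    def level_labels(self) -> list[str]:
        labels = [f"{lv:g}" for lv in self.dilution_levels_amol]
        if self.include_blank:
            labels.append("blank")
        if self.include_double_blank:
            labels.append("double_blank")
        return labels


@dataclass(frozen=True)
class RunSpec:
    run_id: str
    condition: str
    curve: int
    level_label: str
    replicate: int
    light_amol: float
    heavy_amol: float
    seed_index: int

    @property
    def faims_on(self) -> bool:
        return self.condition == "faims"


def generate_loq_study(design: StudyDesign, config: SimConfig, seed: int) -> pd.DataFrame:
    """Manifest of the full (condition x curve x level x replicate) study."""
    rows = []
    idx = 0
    for condition in design.conditions:
        for curve in range(1, design.curves_per_condition + 1):
            for label in design.level_labels():
                if label == "blank":
                    light, heavy = design.light_spike_amol, 0.0
                elif label == "double_blank":
                    light, heavy = 0.0, 0.0
                else:
                    light, heavy = design.light_spike_amol, float(label)
                for rep in range(1, design.replicates_per_level + 1):
                    rows.append(
                        RunSpec(
                            run_id=f"{condition}_c{curve}_{label}_r{rep}",
                            condition=condition,
                            curve=curve,
                            level_label=label,
                            replicate=rep,
                            light_amol=light,
                            heavy_amol=heavy,
                            seed_index=idx,
                        )
                    )
                    idx += 1
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["study_seed"] = seed
    return df


def _run_seed(seed: int, seed_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 104729, int(seed_index)])


def iter_study_runs(
    design: StudyDesign, config: SimConfig, seed: int
) -> Iterator[tuple[RunSpec, list[Ms2ScanRecord]]]:
    """Yield (run spec, scans) for every injection of the study manifest."""
    manifest = generate_loq_study(design, config, seed)
    for row in manifest.itertuples(index=False):
        spec = RunSpec(
            run_id=row.run_id,
            condition=row.condition,
            curve=row.curve,
            level_label=row.level_label,
            replicate=row.replicate,
            light_amol=row.light_amol,
            heavy_amol=row.heavy_amol,
            seed_index=row.seed_index,
        )
        sample = {
            t.target_id: (spec.light_amol, spec.heavy_amol) for t in config.targets
        }
        scans = simulate_run(
            config, sample, spec.faims_on, _run_seed(seed, spec.seed_index), spec.run_id
        )
        yield spec, scans


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

#: Default per-gene endogenous ranges (amol/ug, log-uniform).  HER2 spans the
#: published 30-fold clinical range; the others are plausible tumor levels.
DEFAULT_GENE_RANGES = {
    "ERBB2": (200.0, 6000.0),
    "EGFR": (30.0, 600.0),
    "ESR1": (20.0, 400.0),
    "KRAS": (100.0, 1500.0),
    "MET": (30.0, 800.0),
}

#: HER2 amol/ug thresholds separating IHC classes 0 / 1+ / 2+ / 3+.
DEFAULT_IHC_THRESHOLDS = (500.0, 1500.0, 4000.0)
IHC_CLASSES = ("0", "1+", "2+", "3+")


def _classify_ihc(value: float, thresholds: Sequence[float]) -> str:
    k = int(np.searchsorted(np.asarray(thresholds, dtype=float), value, side="right"))
    return IHC_CLASSES[k]


def generate_clinical_cohort(
    n_samples: int,
    config: SimConfig,
    seed: int,
    gene_ranges: Mapping[str, tuple[float, float]] | None = None,
    ihc_thresholds: Sequence[float] = DEFAULT_IHC_THRESHOLDS,
    ihc_overlap_cv: float = 0.15,
    peptide_level_cv: float = 0.10,
    spike_amol: float = 5000.0,
) -> pd.DataFrame:
    """Per-sample truth table for a simulated FFPE cohort.

    One latent truth per gene per sample (log-uniform over the gene's
    range); peptides of the same gene share it up to a multiplicative
    per-peptide noise of ``peptide_level_cv`` (digestion/recovery
    variability), which is what the between-peptide correlation check
    exercises.  The IHC class is a threshold function of the HER2 truth,
    blurred by ``ihc_overlap_cv`` (0 gives a deterministic step function).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ranges = dict(DEFAULT_GENE_RANGES)
    if gene_ranges:
        ranges.update(gene_ranges)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 15485863]))
    genes = sorted({t.gene for t in config.targets})
    rows = []
    for i in range(1, n_samples + 1):
        sample_id = f"S{i:03d}"
        gene_truth = {}
        for gene in genes:
            glo, ghi = ranges.get(gene, (50.0, 1000.0))
            gene_truth[gene] = float(
                np.exp(rng.uniform(np.log(glo), np.log(ghi)))
            )
        her2 = gene_truth.get("ERBB2", np.nan)
        ihc_var = her2 * _lognormal_factor(rng, ihc_overlap_cv)
        ihc = _classify_ihc(float(ihc_var), ihc_thresholds) if np.isfinite(her2) else ""
        for t in config.targets:
            rows.append(
                {
                    "sample_id": sample_id,
                    "gene": t.gene,
                    "peptide": t.sequence,
                    "z": t.charge,
                    "target_id": t.target_id,
                    "true_gene_amol_per_ug": gene_truth[t.gene],
                    "true_peptide_amol_per_ug": gene_truth[t.gene]
                    * float(_lognormal_factor(rng, peptide_level_cv)),
                    "ihc_class": ihc,
                    "heavy_spike_amol": spike_amol,
                }
            )
    return pd.DataFrame(rows)


def iter_cohort_runs(
    truth: pd.DataFrame, config: SimConfig, seed: int, faims_on: bool = True
) -> Iterator[tuple[str, list[Ms2ScanRecord]]]:
    """Yield (sample_id, scans) for each cohort sample.

    Clinical convention: the light channel carries the endogenous peptide,
    the heavy channel the constant synthetic spike.
    """
    for j, (sample_id, sub) in enumerate(truth.groupby("sample_id", sort=True)):
        sample = {
            r.target_id: (float(r.true_peptide_amol_per_ug), float(r.heavy_spike_amol))
            for r in sub.itertuples(index=False)
        }
        scans = simulate_run(
            config,
            sample,
            faims_on,
            np.random.SeedSequence([seed & 0x7FFFFFFF, 32452843, j]),
            run_id=f"clinical_{sample_id}",
        )
        yield sample_id, scans


# ---------------------------------------------------------------------------
# direct-infusion CV scan
# ---------------------------------------------------------------------------


def simulate_cv_scan(
    cv_optimal: float,
    sigma_volts: float = 8.49,
    step_volts: float = 1.0,
    apex_intensity: float = 1.0e6,
    noise_cv: float = 0.03,
    cv_range: tuple[float, float] = (-100.0, 0.0),
    seed: int = 0,
):
    """A direct-infusion transmission curve: Gaussian in compensation voltage."""
    from .method import CvScanCurve

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2971215073 % (2**31)]))
    v = np.arange(cv_range[0], cv_range[1] + 0.5 * step_volts, step_volts)
    ideal = apex_intensity * np.exp(-0.5 * ((v - cv_optimal) / sigma_volts) ** 2)
    noisy = np.maximum(ideal * _lognormal_factor(rng, noise_cv, size=v.size), 0.0)
    return CvScanCurve.from_arrays(v, noisy)
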