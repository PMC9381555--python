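"""Cohort-level reporting and end-to-end study orchestration.

``run_study`` wires the whole chain together on synthetic data: simulate a
reverse-dilution LOQ study in both FAIMS conditions, back-calculate every
curve, determine per-fragment / summed / best LOQs, merge replicate curves,
compare conditions, account blank-injection background, and (optionally)
quantify a simulated clinical cohort with between-peptide correlation and
IHC-class summaries.  Every output is a CSV or JSON file regenerated
byte-identically from (config, seed); the run log records every threshold
and default in effect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__, background as bg, loq as loqmod, quantify
from .extract import NoPeakError
from .method import PrmTarget, load_method_table
from .pipeline import process_run_target
from .simulate import (
    SimConfig,
    StudyDesign,
    generate_clinical_cohort,
    iter_cohort_runs,
    iter_study_runs,
)

__all__ = [
    "StudyConfig",
    "StageError",
    "peptide_correlation",
    "summarize_by_ihc",
    "run_study",
]

logger = logging.getLogger(__name__)

IHC_ORDER = ("0", "1+", "2+", "3+")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def peptide_correlation(amounts_x: Sequence[float], amounts_y: Sequence[float]) -> dict:
    """Pearson correlation between two peptides' per-sample amounts."""
    x = np.asarray(amounts_x, dtype=float)
    y = np.asarray(amounts_y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired amounts with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in one peptide; correlation undefined")
        return {"pearson_r": float("nan"), "r_squared": float("nan"), "n": int(x.size)}
    r, _ = stats.pearsonr(x, y)
    return {"pearson_r": float(r), "r_squared": float(r * r), "n": int(x.size)}


def summarize_by_ihc(
    cohort: pd.DataFrame, gene: str, peptide: str
) -> tuple[pd.DataFrame, list[dict]]:
    """Five-number summary of amounts per IHC class, with outlier flags.

    A within-class outlier is a sample whose amount is at or above the
    median of the next-higher class (flagged, never removed) — the
    operational form of "a 1+ sample at a typical 2+ level".
    """
    sub = cohort[
        (cohort["gene"] == gene)
        & (cohort["peptide"] == peptide)
        & (cohort["ihc_class"].isin(IHC_ORDER))
    ]
    if sub.empty:
        raise ValueError(f"no classified samples for {gene} {peptide}")
    rows = []
    medians: dict[str, float] = {}
    for cls in IHC_ORDER:
        vals = sub.loc[sub["ihc_class"] == cls, "amount_amol_per_ug"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        medians[cls] = float(np.median(vals))
        rows.append(
            {
                "ihc_class": cls,
                "n": int(vals.size),
                "min": float(vals.min()),
                "q1": float(np.percentile(vals, 25)),
                "median": float(np.median(vals)),
                "q3": float(np.percentile(vals, 75)),
                "max": float(vals.max()),
            }
        )
    outliers = []
    present = [c for c in IHC_ORDER if c in medians]
    for lower, upper in zip(present, present[1:]):
        cls_rows = sub[sub["ihc_class"] == lower]
        for r in cls_rows.itertuples(index=False):
            if r.amount_amol_per_ug >= medians[upper]:
                outliers.append(
                    {
                        "sample_id": r.sample_id,
                        "ihc_class": lower,
                        "amount_amol_per_ug": float(r.amount_amol_per_ug),
                        "next_class_median": medians[upper],
                    }
                )
    return pd.DataFrame(rows), outliers


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Everything run_study needs, loadable from a YAML/JSON mapping."""

    seed: int = 1
    genes: tuple[str, ...] | None = None
    rt_window_half_min: float = 0.4
    # acquisition / matrix model
    response_factor: float = 2.0
    peak_fwhm_s: float = 11.8
    cycle_time_s: float = 3.3
    measurement_cv: float = 0.08
    background_flux_range: tuple[float, float] = (240.0, 5800.0)  # ions/ms, no FAIMS
    retention_range: tuple[float, float] = (0.14, 0.87)
    n_fragments: int = 5
    tolerance_ppm: float = 10.0
    # LOQ design
    conditions: tuple[str, ...] = ("faims", "nofaims")
    curves_per_condition: int = 2
    replicates_per_level: int = 4
    dilution_levels_amol: tuple[float, ...] | None = None
    light_spike_fmol: float = 5.0
    # interference QC
    max_ratio_deviation_pct: float = 30.0
    max_apex_shift_fraction: float = 0.5
    # cohort
    run_cohort: bool = True
    cohort_size: int = 20
    cohort_gene: str = "ERBB2"
    cohort_peptides: tuple[str, str] = ("ELVSEFSR", "SGGGDLTLGLEPSEEEAPR")
    boxplot_peptide: str = "ELVSEFSR"
    ihc_overlap_cv: float = 0.15
    peptide_level_cv: float = 0.10

    @classmethod
    def from_mapping(cls, data: Mapping) -> "StudyConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                v = data[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _per_target_matrix(config: StudyConfig, targets: Sequence[PrmTarget]):
    """Deterministic per-target background flux and FAIMS retention."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 424243]))
    blo, bhi = config.background_flux_range
    rlo, rhi = config.retention_range
    flux = {
        t.target_id: float(np.exp(rng.uniform(np.log(blo), np.log(bhi)))) for t in targets
    }
    retention = {t.target_id: float(rng.uniform(rlo, rhi)) for t in targets}
    return flux, retention


def build_sim_config(config: StudyConfig) -> SimConfig:
    targets = load_method_table()
    if config.genes is not None:
        targets = [t for t in targets if t.gene in config.genes]
    targets = [replace(t, rt_window_half_min=config.rt_window_half_min) for t in targets]
    flux, retention = _per_target_matrix(config, targets)
    return SimConfig(
        targets=tuple(targets),
        response_factor=config.response_factor,
        peak_fwhm_s=config.peak_fwhm_s,
        cycle_time_s=config.cycle_time_s,
        background_flux=flux,
        faims_background_retention=retention,
        measurement_cv=config.measurement_cv,
        n_fragments=config.n_fragments,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, tuple):
        return list(x)
    return x


def run_study(config: StudyConfig, outdir) -> dict:
    """Run the full synthetic study; returns a summary dict of key results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = build_sim_config(config)
    design = StudyDesign(
        conditions=config.conditions,
        curves_per_condition=config.curves_per_condition,
        dilution_levels_amol=(
            config.dilution_levels_amol
            if config.dilution_levels_amol is not None
            else StudyDesign().dilution_levels_amol
        ),
        light_spike_fmol=config.light_spike_fmol,
        replicates_per_level=config.replicates_per_level,
    )
    spike_amol = design.light_spike_amol
    summary: dict = {"seed": config.seed}

    # ---- stage 1: simulate + per-run processing --------------------------
    stage = "simulate/extract"
    level_rows: list[dict] = []
    blank_runs = []
    try:
        manifest = None
        from .simulate import generate_loq_study

        manifest = generate_loq_study(design, sim, config.seed)
        _write_csv(manifest, outdir / "manifest.csv")
        for spec, scans in iter_study_runs(design, sim, config.seed):
            if spec.level_label in ("blank", "double_blank"):
                if spec.level_label == "blank":
                    blank_runs.append((spec.condition, scans))
                continue
            nominal = float(spec.level_label)
            for target in sim.targets:
                try:
                    res = process_run_target(
                        scans, target, sim, "light", config.tolerance_ppm
                    )
                except NoPeakError as exc:
                    logger.warning("%s %s: %s", spec.run_id, target.target_id, exc)
                    continue
                light_sum = res.areas_light.sum()
                if light_sum <= 0:
                    continue
                heavy_sum = res.areas_heavy.sum()
                rel_l = res.areas_light / light_sum
                rel_h = (
                    res.areas_heavy / heavy_sum if heavy_sum > 0 else np.zeros_like(rel_l)
                )
                base = {
                    "condition": spec.condition,
                    "curve": spec.curve,
                    "target_id": target.target_id,
                    "nominal_amol": nominal,
                    "replicate": spec.replicate,
                }
                level_rows.append(
                    {**base, "fragment_set": loqmod.SUMMED,
                     "measured_amol": heavy_sum / light_sum * spike_amol,
                     "ratio_pct": np.nan}
                )
                for i, frag in enumerate(res.fragments):
                    level_rows.append(
                        {**base, "fragment_set": frag,
                         "measured_amol": (
                             res.areas_heavy[i] / res.areas_light[i] * spike_amol
                             if res.areas_light[i] > 0 else np.nan
                         ),
                         "ratio_pct": (
                             100.0 * rel_h[i] / rel_l[i] if rel_l[i] > 0 else np.nan
                         )}
                    )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    replicates = pd.DataFrame(level_rows)

    # ---- stage 2: LOQ determination --------------------------------------
    stage = "loq"
    try:
        level_stats_rows = []
        merged: dict[str, dict[str, dict[str, loqmod.LoqResult]]] = {}
        for condition in design.conditions:
            merged[condition] = {}
            for target in sim.targets:
                sub = replicates[
                    (replicates["condition"] == condition)
                    & (replicates["target_id"] == target.target_id)
                ]
                fragment_sets = [loqmod.SUMMED] + list(sim.fragment_names(target))
                per_set: dict[str, loqmod.LoqResult] = {}
                for fset in fragment_sets:
                    per_curve = []
                    for curve in sorted(sub["curve"].unique()):
                        curve_df = sub[sub["curve"] == curve]
                        levels = loqmod.curve_levels(curve_df, fset)
                        for lv in levels:
                            level_stats_rows.append(
                                {
                                    "condition": condition,
                                    "curve": curve,
                                    "target_id": target.target_id,
                                    "fragment_set": fset,
                                    "nominal_amol": lv.nominal_amol,
                                    "n_replicates": len(lv.replicate_measured_amol),
                                    "cv_percent": lv.cv_percent,
                                    "accuracy_percent": lv.accuracy_percent,
                                    "fragment_ratio_percent": lv.fragment_ratio_percent,
                                    "passed": lv.passed,
                                    "fail_reasons": "; ".join(lv.fail_reasons),
                                }
                            )
                        per_curve.append(loqmod.determine_loq(levels))
                    per_set[fset] = loqmod.merge_replicate_curves(per_curve)
                merged[condition][target.target_id] = per_set
        _write_csv(pd.DataFrame(level_stats_rows), outdir / "level_stats.csv")

        frag_rows = []
        for condition in merged:
            for tid, per_set in merged[condition].items():
                for fset, res in per_set.items():
                    frag_rows.append(
                        {
                            "condition": condition,
                            "target_id": tid,
                            "fragment_set": fset,
                            "lloq_amol_per_ug": res.lloq_amol_per_ug,
                            "uloq_amol_per_ug": res.uloq_amol_per_ug,
                        }
                    )
        _write_csv(pd.DataFrame(frag_rows), outdir / "loq_per_fragment.csv")

        def best_fragment(per_set: dict[str, loqmod.LoqResult]) -> tuple[str, loqmod.LoqResult]:
            candidates = {
                f: r for f, r in per_set.items() if f != loqmod.SUMMED and r.defined
            }
            if not candidates:
                return "", loqmod.LoqResult("best", None, None, reason="no defined fragment")
            name = min(candidates, key=lambda f: (candidates[f].lloq_amol_per_ug, f))
            return name, candidates[name]

        table_rows = []
        for target in sim.targets:
            row = {
                "gene": target.gene,
                "peptide": target.sequence,
                "z": target.charge,
                "target_id": target.target_id,
            }
            for condition in design.conditions:
                per_set = merged[condition][target.target_id]
                bname, bres = best_fragment(per_set)
                row[f"lloq_summed_{condition}"] = per_set[loqmod.SUMMED].lloq_amol_per_ug
                row[f"uloq_summed_{condition}"] = per_set[loqmod.SUMMED].uloq_amol_per_ug
                row[f"best_fragment_{condition}"] = bname
                row[f"lloq_best_{condition}"] = bres.lloq_amol_per_ug
            table_rows.append(row)
        loq_summary = pd.DataFrame(table_rows)
        _write_csv(loq_summary, outdir / "loq_summary.csv")
        summary["loq_summary"] = loq_summary

        comparison = None
        if {"faims", "nofaims"} <= set(design.conditions):
            f_map, nf_map = {}, {}
            for target in sim.targets:
                rf = merged["faims"][target.target_id][loqmod.SUMMED]
                rn = merged["nofaims"][target.target_id][loqmod.SUMMED]
                if rf.defined and rn.defined:
                    f_map[target.target_id] = rf.lloq_amol_per_ug
                    nf_map[target.target_id] = rn.lloq_amol_per_ug
            if f_map:
                comparison = loqmod.compare_conditions(f_map, nf_map)
                _write_csv(comparison.per_precursor, outdir / "condition_comparison.csv")
                _write_json(
                    {
                        "median_lloq_faims_amol_per_ug": comparison.median_faims,
                        "median_lloq_nofaims_amol_per_ug": comparison.median_nofaims,
                        "n_improved": comparison.n_improved,
                        "n_tied": comparison.n_tied,
                        "n_worse": comparison.n_worse,
                    },
                    outdir / "condition_comparison.json",
                )
                summary["comparison"] = comparison
        else:
            logger.warning("both conditions not present; LLOQ comparison skipped")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage 3: background accounting ----------------------------------
    stage = "background"
    try:
        if blank_runs:
            stats_map = bg.collect_background(blank_runs, sim, config.tolerance_ppm)
            bg_rows = []
            reductions: dict[str, float] = {}
            for target in sim.targets:
                sf = stats_map.get((target.target_id, "faims"))
                sn = stats_map.get((target.target_id, "nofaims"))
                for s in (sf, sn):
                    if s is not None:
                        bg_rows.append(
                            {
                                "target_id": s.target_id,
                                "condition": s.condition,
                                "n_scans": s.n_scans,
                                "median_ions_per_scan": s.median,
                            }
                        )
                if sf is not None and sn is not None:
                    reductions[target.target_id] = bg.percent_reduction(sf, sn)
            bg_df = pd.DataFrame(bg_rows)
            if not bg_df.empty:
                red_df = pd.DataFrame(
                    {
                        "target_id": list(reductions),
                        "percent_reduction": list(reductions.values()),
                    }
                )
                _write_csv(bg_df, outdir / "background.csv")
                _write_csv(red_df, outdir / "background_reduction.csv")
                summary["percent_reduction"] = reductions
                nf_medians = bg_df.loc[
                    bg_df["condition"] == "nofaims", "median_ions_per_scan"
                ].to_numpy()
                if nf_medians.size and np.all(nf_medians > 0):
                    summary["background_fold_range_nofaims"] = bg.fold_range(nf_medians)
            if summary.get("comparison") is not None and reductions:
                comp = summary["comparison"]
                improved = set(
                    comp.per_precursor.loc[
                        comp.per_precursor["fold_reduction"] >= 2, "precursor"
                    ]
                )
                grp_imp = [v for k, v in reductions.items() if k in improved]
                grp_unc = [v for k, v in reductions.items() if k not in improved]
                if len(grp_imp) >= 2 and len(grp_unc) >= 2:
                    test = bg.compare_groups(grp_imp, grp_unc)
                    _write_json(
                        {
                            "t_statistic": test.t_statistic,
                            "df": test.df,
                            "p_value_two_sided": test.p_value_two_sided,
                            "mean_difference": test.mean_difference,
                            "ci95_difference": list(test.ci95_difference),
                            "mean_improved": test.mean_improved,
                            "ci95_improved": list(test.ci95_improved),
                            "n_improved": len(grp_imp),
                            "n_unchanged": len(grp_unc),
                        },
                        outdir / "background_group_test.json",
                    )
                    summary["group_test"] = test
                else:
                    logger.warning("group sizes too small for background t test")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage 4: clinical cohort ----------------------------------------
    stage = "report"
    try:
        if config.run_cohort:
            truth = generate_clinical_cohort(
                config.cohort_size,
                sim,
                config.seed,
                ihc_overlap_cv=config.ihc_overlap_cv,
                peptide_level_cv=config.peptide_level_cv,
                spike_amol=spike_amol,
            )
            _write_csv(truth, outdir / "cohort_truth.csv")
            lloq_faims = {
                t.target_id: merged.get("faims", {})
                .get(t.target_id, {})
                .get(loqmod.SUMMED, loqmod.LoqResult(loqmod.SUMMED, None, None))
                .lloq_amol_per_ug
                for t in sim.targets
            }
            cohort_rows = []
            for sample_id, scans in iter_cohort_runs(truth, sim, config.seed, faims_on=True):
                sub = truth[truth["sample_id"] == sample_id]
                ihc = sub["ihc_class"].iloc[0]
                for target in sim.targets:
                    flags = []
                    amount = np.nan
                    try:
                        res = process_run_target(
                            scans, target, sim, "heavy", config.tolerance_ppm
                        )
                        fq = res.fragment_quants("light")
                        fq = quantify.flag_interference(
                            fq,
                            config.max_ratio_deviation_pct,
                            config.max_apex_shift_fraction,
                            peak_width_s=res.peak.width_s,
                        )
                        flags += [f.fragment for f in fq if f.flagged]
                        pq = quantify.quantify_peptide(
                            fq, "summed", spike_amol, 1.0, target.target_id
                        )
                        amount = pq.amount_amol_per_ug
                    except (NoPeakError, quantify.QuantitationFailedError,
                            quantify.CannotAssessError) as exc:
                        logger.warning("%s %s: %s", sample_id, target.target_id, exc)
                        flags.append("quantitation-failed")
                    lloq = lloq_faims.get(target.target_id)
                    below = bool(lloq is not None and np.isfinite(amount) and amount < lloq)
                    cohort_rows.append(
                        {
                            "sample_id": sample_id,
                            "gene": target.gene,
                            "peptide": target.sequence,
                            "z": target.charge,
                            "target_id": target.target_id,
                            "amount_amol_per_ug": amount,
                            "below_lloq": below,
                            "qc_flags": ";".join(flags),
                            "ihc_class": ihc,
                        }
                    )
            cohort = pd.DataFrame(cohort_rows)
            _write_csv(cohort, outdir / "cohort_quant.csv")
            summary["cohort"] = cohort

            pep_a, pep_b = config.cohort_peptides
            wide = cohort[
                (cohort["gene"] == config.cohort_gene)
                & (cohort["peptide"].isin([pep_a, pep_b]))
            ].pivot_table(
                index="sample_id", columns="peptide", values="amount_amol_per_ug"
            )
            if {pep_a, pep_b} <= set(wide.columns) and len(wide) >= 3:
                corr = peptide_correlation(wide[pep_a], wide[pep_b])
                corr["peptides"] = [pep_a, pep_b]
                _write_json(corr, outdir / "cohort_correlation.json")
                summary["correlation"] = corr
            try:
                ihc_summary, outliers = summarize_by_ihc(
                    cohort, config.cohort_gene, config.boxplot_peptide
                )
                _write_csv(ihc_summary, outdir / "ihc_summary.csv")
                _write_json(outliers, outdir / "ihc_outliers.json")
                summary["ihc_summary"] = ihc_summary
                summary["ihc_outliers"] = outliers
            except ValueError as exc:
                logger.warning("IHC summary skipped: %s", exc)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    # ---- run log ----------------------------------------------------------
    log = {f.name: _jsonable(getattr(config, f.name)) for f in dataclasses.fields(config)}
    log.update(
        {
            "package_version": __version__,
            "pass_criteria": {
                "cv_max_pct": loqmod.CV_MAX_PCT,
                "accuracy_range_pct": list(loqmod.ACCURACY_RANGE_PCT),
                "fragment_ratio_range_pct": list(loqmod.FRAGMENT_RATIO_RANGE_PCT),
            },
            "per_target_background_flux_ions_per_ms": sim._background_map(),
            "per_target_faims_background_retention": sim._retention_map(),
            "dilution_grid_amol": list(design.dilution_levels_amol),
            "light_spike_amol": spike_amol,
            "loaded_ug": 1.0,
            "agc_target": sim.agc_target,
            "max_injection_ms": sim.max_injection_ms,
            "isolation_width_mz": sim.isolation_width,
        }
    )
    _write_json(log, outdir / "run_log.json")
    return summary
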