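"""Calibration-curve statistics, LLOQ rules and condition comparison."""

import numpy as np
import pandas as pd
import pytest

from faimsprm import loq
from faimsprm.loq import (
    SUMMED,
    CurveLevel,
    compare_conditions,
    curve_levels,
    determine_loq,
    load_table2,
    merge_replicate_curves,
    per_fragment_comparison,
)


def level(nominal, passed, fragment_set=SUMMED):
    return CurveLevel(
        nominal_amol=nominal,
        fragment_set=fragment_set,
        replicate_measured_amol=(nominal,) * 4,
        cv_percent=5.0 if passed else 35.0,
        accuracy_percent=100.0,
        fragment_ratio_percent=100.0,
        passed=passed,
        fail_reasons=() if passed else ("CV 35.0% >= 20%",),
    )


GRID = [5, 15, 46, 137, 412, 1235, 3704, 11111, 33333, 100000]


class TestDetermineLoq:
    def test_first_failing_level_sets_lloq(self):
        levels = [level(n, n >= 46) for n in GRID]
        res = determine_loq(levels)
        assert res.lloq_amol_per_ug == 46
        assert res.uloq_amol_per_ug == 100000

    def test_all_fail_undefined(self):
        res = determine_loq([level(n, False) for n in GRID])
        assert not res.defined and res.reason == "no passing level"

    def test_isolated_passing_level_below_gap_excluded(self):
        """pass/fail/pass/pass -> the quantitative range is the upper run."""
        flags = {5: True, 15: False, 46: True, 137: True}
        levels = [level(n, flags.get(n, True)) for n in GRID]
        res = determine_loq(levels)
        assert res.lloq_amol_per_ug == 46

    def test_tie_prefers_higher_run(self):
        flags = {5: True, 15: True, 46: False, 137: True, 412: True}
        levels = [level(n, flags.get(n, False)) for n in [5, 15, 46, 137, 412]]
        res = determine_loq(levels)
        assert res.lloq_amol_per_ug == 137
        assert res.uloq_amol_per_ug == 412

    def test_unordered_levels_rejected(self):
        with pytest.raises(ValueError):
            determine_loq([level(46, True), level(5, True)])

    def test_degrading_a_level_never_lowers_lloq(self):
        base = [level(n, n >= 46) for n in GRID]
        lloq0 = determine_loq(base).lloq_amol_per_ug
        for k in range(len(GRID)):
            degraded = list(base)
            degraded[k] = level(GRID[k], False)
            res = determine_loq(degraded)
            if res.defined:
                assert res.lloq_amol_per_ug >= lloq0


class TestMergeReplicateCurves:
    def test_lower_of_two_lloqs(self):
        a = determine_loq([level(n, n >= 46) for n in GRID])
        b = determine_loq([level(n, n >= 137) for n in GRID])
        merged = merge_replicate_curves([a, b])
        assert merged.lloq_amol_per_ug == 46
        assert merged.uloq_amol_per_ug == 100000

    def test_identical_curves_unchanged(self):
        a = determine_loq([level(n, n >= 46) for n in GRID])
        merged = merge_replicate_curves([a, a])
        assert merged.lloq_amol_per_ug == a.lloq_amol_per_ug
        assert merged.uloq_amol_per_ug == a.uloq_amol_per_ug

    def test_undefined_plus_defined_keeps_defined(self):
        a = determine_loq([level(n, False) for n in GRID])
        b = determine_loq([level(n, n >= 137) for n in GRID])
        merged = merge_replicate_curves([a, b])
        assert merged.lloq_amol_per_ug == 137

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_replicate_curves([])


class TestCompareConditions:
    def test_published_table_medians_and_counts(self):
        """The bundled per-precursor table gives median LLOQ 137 (no FAIMS)
        vs 46 (FAIMS) amol/ug and 7 of 11 precursors at threefold."""
        df = load_table2()
        comp = compare_conditions(
            dict(zip(df["precursor"], df["lloq_faims_amol_per_ug"])),
            dict(zip(df["precursor"], df["lloq_nofaims_amol_per_ug"])),
        )
        assert comp.median_faims == 46
        assert comp.median_nofaims == 137
        assert (comp.per_precursor["fold_reduction"] == 3).sum() == 7
        assert comp.n_improved == 7
        assert comp.n_tied == 4
        assert comp.n_worse == 0

    def test_identical_conditions_all_tied(self):
        vals = {"a": 46.0, "b": 137.0}
        comp = compare_conditions(vals, vals)
        assert (comp.per_precursor["fold_reduction"] == 1).all()
        assert comp.n_improved == 0 and comp.n_tied == 2 and comp.n_worse == 0

    def test_threefold_grid_ratio_rounds_to_integer(self):
        comp = compare_conditions({"a": 46.0}, {"a": 137.0})
        assert comp.per_precursor["fold_reduction"].iloc[0] == 3  # 2.978 -> 3

    def test_mismatched_precursors_excluded_with_warning(self, caplog):
        comp = compare_conditions({"a": 46.0, "b": 15.0}, {"a": 137.0, "c": 46.0})
        assert list(comp.per_precursor["precursor"]) == ["a"]

    def test_per_fragment_status_counts(self):
        f = {"p1": {"y5": 46.0, "y6": 137.0}, "p2": {"y5": 15.0}}
        nf = {"p1": {"y5": 137.0, "y6": 137.0}, "p2": {"y5": 46.0}}
        table = per_fragment_comparison(f, nf)
        counts = table["status"].value_counts().to_dict()
        assert counts == {"improved": 2, "tied": 1}


class TestLevelStatistics:
    def make_table(self, measured_by_level, ratios=100.0):
        rows = []
        for nominal, reps in measured_by_level.items():
            for i, m in enumerate(reps, start=1):
                rows.append(
                    {"nominal_amol": nominal, "replicate": i,
                     "fragment_set": SUMMED, "measured_amol": m, "ratio_pct": np.nan}
                )
                rows.append(
                    {"nominal_amol": nominal, "replicate": i,
                     "fragment_set": "y5", "measured_amol": m, "ratio_pct": ratios}
                )
        return pd.DataFrame(rows)

    def test_cv_uses_sample_standard_deviation(self):
        reps = [90.0, 100.0, 110.0, 100.0]
        table = self.make_table({100.0: reps})
        lv = curve_levels(table, SUMMED)[0]
        expected_cv = 100 * np.std(reps, ddof=1) / np.mean(reps)
        assert lv.cv_percent == pytest.approx(expected_cv)
        assert lv.accuracy_percent == pytest.approx(100.0)
        assert lv.passed

    def test_accuracy_and_ratio_criteria(self):
        table = self.make_table({100.0: [130.0, 125.0, 128.0, 127.0]})
        lv = curve_levels(table, SUMMED)[0]
        assert not lv.passed and any("accuracy" in r for r in lv.fail_reasons)
        table = self.make_table({100.0: [100.0, 101.0, 99.0, 100.0]}, ratios=140.0)
        lv = curve_levels(table, "y5")[0]
        assert not lv.passed and any("fragment ratio" in r for r in lv.fail_reasons)

    def test_single_replicate_unevaluable(self):
        table = self.make_table({100.0: [100.0]})
        lv = curve_levels(table, SUMMED)[0]
        assert not lv.evaluable and not lv.passed


class TestBackCalculation:
    def test_clean_ratio_recovers_nominal(self, single_target):
        """With no background or handling noise the isotope ratio
        back-calculates the spiked amount up to counting noise."""
        from faimsprm.simulate import SimConfig, simulate_run

        cfg = SimConfig(
            targets=(single_target,), background_flux=0.0, measurement_cv=0.0,
            rt_jitter_s=0.0, response_factor=20.0, seed=2,
        )
        runs = [
            simulate_run(cfg, {single_target.target_id: (5000.0, 137.0)}, False, s, "r")
            for s in range(6)
        ]
        measured = loq.back_calculate(runs, single_target, cfg)
        assert np.mean(measured) == pytest.approx(137.0, rel=0.05)

    def test_zero_heavy_gives_zero(self, single_target):
        from faimsprm.simulate import SimConfig, simulate_run

        cfg = SimConfig(
            targets=(single_target,), background_flux=0.0, measurement_cv=0.0,
            rt_jitter_s=0.0, seed=2,
        )
        runs = [simulate_run(cfg, {single_target.target_id: (5000.0, 0.0)}, False, 1, "r")]
        assert loq.back_calculate(runs, single_target, cfg) == [0.0]

    def test_mid_grid_simulation_recovery_with_noise(self, single_target):
        """At a mid-grid level with 8% handling noise the mean back-calculated
        amount matches nominal within 3 standard errors."""
        from faimsprm.simulate import SimConfig, simulate_run

        cfg = SimConfig(
            targets=(single_target,), background_flux=0.0, measurement_cv=0.08,
            response_factor=20.0, seed=6,
        )
        runs = [
            simulate_run(cfg, {single_target.target_id: (5000.0, 1235.0)}, False, s, "r")
            for s in range(12)
        ]
        measured = np.array(loq.back_calculate(runs, single_target, cfg))
        se = measured.std(ddof=1) / np.sqrt(measured.size)
        assert abs(measured.mean() - 1235.0) <= 3 * se

    def test_all_replicates_excluded_raises(self, single_target):
        from faimsprm.simulate import SimConfig, double_blank_sample, simulate_run

        cfg = SimConfig(
            targets=(single_target,), background_flux=0.0, measurement_cv=0.0, seed=2
        )
        runs = [simulate_run(cfg, double_blank_sample(cfg), False, 1, "r")]
        with pytest.raises(loq.LevelFailedError):
            loq.back_calculate(runs, single_target, cfg)
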