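"""Isotope-ratio quantitation and interference flagging rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faimsprm import quantify
from faimsprm.quantify import (
    CannotAssessError,
    QuantitationFailedError,
    build_fragment_quants,
    flag_interference,
    quantify_peptide,
)


def fq(analyte, reference, apex_a=None, apex_r=None):
    frags = [f"y{i+3}" for i in range(len(analyte))]
    return build_fragment_quants(frags, analyte, reference, apex_a, apex_r)


class TestFlagInterference:
    def test_identical_patterns_unflagged(self):
        out = flag_interference(fq([0.5, 0.3, 0.2], [0.5, 0.3, 0.2]))
        assert not any(f.flagged for f in out)

    def test_ratio_deviation_flags_fragment(self):
        """0.8 vs 0.5 relative abundance is a 60% deviation: flagged."""
        out = flag_interference(fq([0.8, 0.1, 0.1], [0.5, 0.3, 0.2]))
        assert out[0].flagged and "ratio" in out[0].flag_reason
        # deviations are 60%, 67% and 50%: every fragment exceeds 30%
        assert [f.flagged for f in out] == [True, True, True]
        # a mild pattern distortion flags only the deviating fragment
        mild = flag_interference(fq([0.55, 0.25, 0.20], [0.4, 0.35, 0.25]))
        assert [f.flagged for f in mild] == [True, False, False]

    def test_apex_shift_flags_coelution_failure(self):
        out = flag_interference(
            fq([0.5, 0.5], [0.5, 0.5], apex_a=[100.0, 120.0], apex_r=[100.0, 100.0]),
            peak_width_s=20.0,
        )
        assert not out[0].flagged
        assert out[1].flagged and "apex shift" in out[1].flag_reason

    def test_all_zero_reference_cannot_assess(self):
        with pytest.raises(CannotAssessError):
            flag_interference(fq([0.5, 0.5], [0.0, 0.0]))

    def test_single_fragment_cannot_assess(self):
        with pytest.raises(CannotAssessError):
            flag_interference(fq([1.0], [1.0]))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=5.0, max_value=100.0), st.floats(min_value=0.0, max_value=100.0))
    def test_flag_monotonicity(self, tight, extra):
        """Loosening the deviation threshold never flags more fragments."""
        quants = fq([0.7, 0.2, 0.1], [0.4, 0.35, 0.25])
        n_tight = sum(f.flagged for f in flag_interference(quants, tight))
        n_loose = sum(f.flagged for f in flag_interference(quants, tight + extra))
        assert n_loose <= n_tight


class TestQuantifyPeptide:
    def test_unit_ratio_gives_spike_amount(self):
        out = quantify_peptide(fq([10.0, 10.0], [10.0, 10.0]), "summed")
        assert out.amount_amol_per_ug == pytest.approx(5000.0)

    def test_area_ratio_arithmetic(self):
        """42/1000 of a 5 fmol spike is 210 amol/ug."""
        out = quantify_peptide(fq([42.0], [1000.0]), "per-fragment", fragment="y3")
        assert out.amount_amol_per_ug == pytest.approx(210.0)

    def test_summed_equals_single_for_proportional_patterns(self):
        analyte = [8.0, 6.0, 2.0]
        reference = [80.0, 60.0, 20.0]
        summed = quantify_peptide(fq(analyte, reference), "summed")
        single = quantify_peptide(fq(analyte, reference), "per-fragment", fragment="y4")
        best = quantify_peptide(fq(analyte, reference), "best")
        assert summed.amount_amol_per_ug == pytest.approx(single.amount_amol_per_ug)
        assert best.used_fragments == ("y3",)  # highest reference area
        assert best.amount_amol_per_ug == pytest.approx(summed.amount_amol_per_ug)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, c):
        base = quantify_peptide(fq([3.0, 5.0], [50.0, 70.0]), "summed")
        scaled = quantify_peptide(
            fq([3.0 * c, 5.0 * c], [50.0 * c, 70.0 * c]), "summed"
        )
        assert scaled.amount_amol_per_ug == pytest.approx(
            base.amount_amol_per_ug, rel=1e-9
        )

    def test_flagged_fragments_excluded(self):
        quants = flag_interference(fq([0.55, 0.25, 0.20], [0.4, 0.35, 0.25]))
        out = quantify_peptide(quants, "summed")
        assert "y3" not in out.used_fragments
        assert set(out.used_fragments) == {"y4", "y5"}

    def test_all_flagged_fails(self):
        quants = [
            quantify.FragmentQuant("y3", 1, 1, 0.5, 0.5, 0, 0, flagged=True),
            quantify.FragmentQuant("y4", 1, 1, 0.5, 0.5, 0, 0, flagged=True),
        ]
        with pytest.raises(QuantitationFailedError):
            quantify_peptide(quants, "summed")

    def test_loaded_mass_denominator(self):
        out = quantify_peptide(fq([100.0], [1000.0]), "per-fragment", fragment="y3",
                               loaded_ug=2.0)
        assert out.amount_amol_per_ug == pytest.approx(250.0)


def test_summed_and_best_agree_on_clean_simulated_data(sim_config, single_target):
    """With equal channel patterns and no interference the summed-fragment
    and best-fragment amounts agree within measurement noise."""
    from faimsprm.pipeline import process_run_target
    from faimsprm.simulate import simulate_run

    amounts = []
    for seed in range(6):
        scans = simulate_run(
            sim_config, {single_target.target_id: (5000.0, 1235.0)}, True, seed, "r"
        )
        res = process_run_target(scans, single_target, sim_config, "light")
        quants = flag_interference(
            res.fragment_quants("heavy"), peak_width_s=res.peak.width_s
        )
        summed = quantify_peptide(quants, "summed")
        best = quantify_peptide(quants, "best")
        amounts.append((summed.amount_amol_per_ug, best.amount_amol_per_ug))
    summed_arr = np.array([a for a, _ in amounts])
    best_arr = np.array([b for _, b in amounts])
    assert np.allclose(summed_arr, best_arr, rtol=0.2)
    assert summed_arr.mean() == pytest.approx(1235.0, rel=0.15)


def test_simulated_interference_is_flagged(single_target):
    """A coeluting interferent planted on one heavy fragment distorts that
    fragment's channel ratio and is caught by the 30% rule."""
    from faimsprm.pipeline import process_run_target
    from faimsprm.simulate import InterferenceSpec, SimConfig, simulate_run

    cfg = SimConfig(
        targets=(single_target,),
        background_flux=0.0,
        measurement_cv=0.0,
        rt_jitter_s=0.0,
        seed=3,
    )
    frag_mz = cfg.fragment_mz(single_target, "heavy")
    cfg = SimConfig(
        targets=(single_target,),
        background_flux=0.0,
        measurement_cv=0.0,
        rt_jitter_s=0.0,
        seed=3,
        interference_specs=(
            InterferenceSpec(single_target.target_id, "heavy", float(frag_mz[1]), 0.0, 50.0),
        ),
    )
    scans = simulate_run(cfg, {single_target.target_id: (5000.0, 1000.0)}, True, 5, "r")
    res = process_run_target(scans, single_target, cfg, "light")
    quants = flag_interference(res.fragment_quants("heavy"), peak_width_s=res.peak.width_s)
    flagged = {f.fragment for f in quants if f.flagged}
    assert res.fragments[1] in flagged
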