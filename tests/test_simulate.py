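"""Scan-stream generator: determinism, AGC contract, counting statistics."""

import io
from dataclasses import replace

import numpy as np
import pytest

from faimsprm import scanio, simulate
from faimsprm.simulate import (
    DILUTION_GRID_AMOL,
    SimConfig,
    StudyDesign,
    blank_sample,
    double_blank_sample,
    generate_clinical_cohort,
    generate_loq_study,
    simulate_run,
)


def serialize(scans) -> bytes:
    buf = io.StringIO()
    for s in scans:
        import json

        buf.write(json.dumps(scanio.scan_to_dict(s), separators=(",", ":")))
        buf.write("\n")
    return buf.getvalue().encode()


class TestSimulateRun:
    def test_seed_determinism_bytewise(self, sim_config, single_target):
        sample = {single_target.target_id: (5000.0, 137.0)}
        a = simulate_run(sim_config, sample, True, 42, "r")
        b = simulate_run(sim_config, sample, True, 42, "r")
        assert serialize(a) == serialize(b)
        c = simulate_run(sim_config, sample, True, 43, "r")
        assert serialize(a) != serialize(c)

    def test_zero_amounts_zero_background_all_silent(self, single_target):
        cfg = SimConfig(targets=(single_target,), background_flux=0.0, seed=1)
        scans = simulate_run(cfg, double_blank_sample(cfg), False, 5, "r")
        assert scans and all(s.total_ion_count == 0 for s in scans)

    def test_negative_amount_rejected(self, sim_config, single_target):
        with pytest.raises(ValueError):
            simulate_run(sim_config, {single_target.target_id: (-1.0, 0.0)}, True, 1, "r")

    def test_empty_target_list_empty_run(self):
        cfg = SimConfig(targets=())
        assert simulate_run(cfg, {}, True, 1, "r") == []

    def test_agc_limits_injection_time(self, single_target):
        """1e5 ions/ms of flux fills the 1e6 AGC target in 10 ms."""
        cfg = SimConfig(
            targets=(single_target,),
            background_flux=1.0e5,
            measurement_cv=0.0,
            rt_jitter_s=0.0,
            seed=1,
        )
        scans = simulate_run(cfg, double_blank_sample(cfg), False, 3, "r")
        assert all(s.injection_time_ms == pytest.approx(10.0) for s in scans)
        assert all(s.total_ion_count <= 1.2e6 for s in scans)
        tics = np.array([s.total_ion_count for s in scans])
        assert tics.mean() == pytest.approx(1.0e6, rel=0.01)

    def test_faims_background_retention_ratio(self, single_target):
        """Blank heavy-channel ion counts scale by the retention fraction."""
        cfg = SimConfig(
            targets=(replace(single_target, rt_window_half_min=2.0),),
            background_flux=300.0,
            faims_background_retention=0.25,
            seed=1,
        )
        tics = {}
        for label, faims_on in (("faims", True), ("nofaims", False)):
            pooled = []
            for seed in range(5):
                scans = simulate_run(cfg, double_blank_sample(cfg), faims_on, seed, "r")
                pooled += [
                    s.total_ion_count for s in scans if s.channel == "heavy"
                ]
            tics[label] = np.array(pooled, dtype=float)
        assert tics["faims"].size >= 300
        ratio = tics["faims"].mean() / tics["nofaims"].mean()
        # Poisson SE of the mean ratio
        se = ratio * np.sqrt(
            1 / tics["faims"].sum() + 1 / tics["nofaims"].sum()
        )
        assert abs(ratio - 0.25) <= 3 * se

    def test_signal_linearity_below_agc(self, single_target):
        """Apex fragment intensity is linear in amount with slope
        response_factor x fragment fraction / max fill time."""
        cfg = SimConfig(
            targets=(single_target,),
            background_flux=0.0,
            measurement_cv=0.0,
            rt_jitter_s=0.0,
            mz_jitter_ppm=0.0,
            response_factor=5.0,
            seed=2,
        )
        pattern = cfg.fragment_pattern(single_target)
        frag_mz = cfg.fragment_mz(single_target, "heavy")
        amounts = (2000.0, 4000.0, 8000.0)
        apex = []
        for amount in amounts:
            pooled = []
            for seed in range(8):
                scans = simulate_run(
                    cfg, {single_target.target_id: (0.0, amount)}, False, seed, "r"
                )
                heavy = [s for s in scans if s.channel == "heavy"]
                tot = np.array([s.intensity.sum() for s in heavy])
                pooled.append(tot.max())
            apex.append(np.mean(pooled))
        slopes = np.array(apex) / np.array(amounts)
        expected = cfg.response_factor / cfg.max_injection_ms  # all fragments summed
        assert slopes == pytest.approx(expected, rel=0.1)
        assert apex[2] / apex[0] == pytest.approx(4.0, rel=0.1)

    def test_scan_record_invariants(self, sim_config, single_target):
        scans = simulate_run(sim_config, {single_target.target_id: (5000.0, 412.0)}, True, 9, "r")
        for s in scans:
            assert np.all(np.diff(s.mz) >= 0)
            assert np.all(s.intensity >= 0)
            assert s.compensation_voltage == single_target.compensation_voltage
        nofaims = simulate_run(sim_config, blank_sample(sim_config), False, 9, "r")
        assert all(s.compensation_voltage is None for s in nofaims)


class TestStudyDesign:
    def test_manifest_is_full_cross_product(self, sim_config):
        design = StudyDesign()
        manifest = generate_loq_study(design, sim_config, 7)
        assert len(manifest) == 2 * 2 * (10 + 2) * 4 == 192

    def test_dilution_grid_matches_published_labels(self):
        assert StudyDesign().dilution_levels_amol == DILUTION_GRID_AMOL
        assert DILUTION_GRID_AMOL == (100000, 33333, 11111, 3704, 1235, 412, 137, 46, 15, 5)

    def test_blank_and_double_blank_composition(self, sim_config):
        manifest = generate_loq_study(StudyDesign(), sim_config, 7)
        blanks = manifest[manifest["level_label"] == "blank"]
        dblanks = manifest[manifest["level_label"] == "double_blank"]
        assert (blanks["heavy_amol"] == 0).all() and (blanks["light_amol"] == 5000).all()
        assert (dblanks["heavy_amol"] == 0).all() and (dblanks["light_amol"] == 0).all()

    def test_levels_strictly_decreasing_enforced(self):
        with pytest.raises(ValueError):
            StudyDesign(dilution_levels_amol=(5, 15, 46))

    def test_manifest_deterministic(self, sim_config):
        a = generate_loq_study(StudyDesign(), sim_config, 3)
        b = generate_loq_study(StudyDesign(), sim_config, 3)
        assert a.equals(b)


class TestClinicalCohort:
    def test_truth_ranges_and_shared_gene_truth(self, table1_targets):
        cfg = SimConfig(targets=tuple(table1_targets), seed=5)
        truth = generate_clinical_cohort(20, cfg, seed=5)
        her2 = truth[truth["gene"] == "ERBB2"]
        assert ((her2["true_gene_amol_per_ug"] >= 200) & (her2["true_gene_amol_per_ug"] <= 6000)).all()
        # same latent truth for all peptides of a gene within a sample
        per_sample = her2.groupby("sample_id")["true_gene_amol_per_ug"].nunique()
        assert (per_sample == 1).all()

    def test_zero_overlap_noise_gives_deterministic_classes(self, table1_targets):
        cfg = SimConfig(targets=tuple(table1_targets), seed=5)
        truth = generate_clinical_cohort(40, cfg, seed=11, ihc_overlap_cv=0.0)
        her2 = truth[truth["gene"] == "ERBB2"].drop_duplicates("sample_id")
        for row in her2.itertuples(index=False):
            expected = simulate._classify_ihc(
                row.true_gene_amol_per_ug, simulate.DEFAULT_IHC_THRESHOLDS
            )
            assert row.ihc_class == expected

    def test_nsamples_validated(self, sim_config):
        with pytest.raises(ValueError):
            generate_clinical_cohort(0, sim_config, 1)


def test_scanio_round_trip(sim_config, single_target, tmp_path):
    scans = simulate_run(sim_config, {single_target.target_id: (5000.0, 137.0)}, True, 21, "r")
    path = tmp_path / "run.ndjson"
    scanio.write_ndjson(scans, path)
    back = scanio.read_ndjson(path)
    assert len(back) == len(scans)
    assert serialize(back) == serialize(scans)


def test_cv_scan_simulation_recovers_center():
    from faimsprm.method import analyze_cv_scan

    curve = simulate.simulate_cv_scan(-58.0, sigma_volts=8.49, seed=4)
    res = analyze_cv_scan(curve)
    assert res.cv_optimal == pytest.approx(-58.0, abs=2.0)
    assert res.half_max_range[0] == pytest.approx(-58 - 10, abs=1.5)
    assert res.half_max_range[1] == pytest.approx(-58 + 10, abs=1.5)
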