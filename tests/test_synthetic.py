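"""Generators: determinism, noise-free limits, calibration against truth."""

import numpy as np
import pandas as pd
import pytest

from hergvar.errors import InvalidDesignError
from hergvar.hill import fit_hill
from hergvar.synthetic import (DrugSpec, LabSpec, StudyDesign,
                               default_study_design, expected_percent_loss,
                               simulate_concentration_response,
                               simulate_loss_samples, simulate_study)

from conftest import make_cell


def two_lab_design(tau=0.0, sigma=(0.0, 0.0), offsets=(0.0, -0.2)):
    drugs = (DrugSpec("drugA", 6.0, 1.0, 3.0),)
    labs = tuple(LabSpec(f"L{i+1}", off, f"L{i+1}", (("drugA", False),) * 3)
                 for i, off in enumerate(offsets))
    return StudyDesign(drugs=drugs, labs=labs, tau=tau, sigma_range=sigma)


class TestSimulateStudy:
    def test_noise_free_offsets_exact(self):
        rec, _ = simulate_study(two_lab_design())
        by_lab = rec.groupby("lab_id")["pic50"].mean()
        assert by_lab["L1"] - by_lab["L2"] == pytest.approx(0.2, abs=1e-15)
        # drug+lab means reproduced exactly in the noise-free limit
        assert np.max(np.abs(rec["pic50"] - (6.0 + rec["lab_id"].map(
            {"L1": 0.0, "L2": -0.2})))) < 1e-12

    def test_default_design_counts(self, study_records):
        rec, _ = study_records
        assert len(rec) == 145
        assert rec.groupby("lab_id").size().to_dict() == {
            "Lab1": 30, "Lab2": 36, "Lab3": 16, "Lab4": 30, "Lab5": 33}
        assert rec["experiment_id"].nunique() == 145
        # Lab 2 splits into two variance groups
        assert set(rec.loc[rec.lab_id == "Lab2", "group_label"]) == {"Lab2", "Lab2*"}

    def test_tau_recovered_monte_carlo(self):
        drugs = (DrugSpec("drugA", 6.0, 1.0, 3.0),)
        labs = (LabSpec("L1", 0.0, "L1", (("drugA", False),) * 10_000),)
        design = StudyDesign(drugs=drugs, labs=labs, tau=0.18,
                             sigma_range=(0.0, 0.0), seed=5)
        rec, truth = simulate_study(design)
        sd = np.std(rec["pic50"] - 6.0, ddof=1)
        assert abs(sd - 0.18) / 0.18 < 0.02

    def test_sigma_recorded_as_known_sd(self):
        rec, truth = simulate_study(default_study_design(seed=3))
        assert np.array_equal(rec["sd_pic50"].to_numpy(),
                              truth["sigma"].to_numpy())
        lo, hi = (0.02, 0.15)
        assert rec["sd_pic50"].between(lo, hi).all()

    def test_invalid_designs_rejected(self):
        with pytest.raises(InvalidDesignError):
            two_lab_design(tau=-0.1)
        with pytest.raises(InvalidDesignError):
            two_lab_design(sigma=(-0.01, 0.1))
        with pytest.raises(InvalidDesignError):
            StudyDesign(drugs=(DrugSpec("a", 6, -1.0, 3),),
                        labs=(LabSpec("L", 0, "L", (("a", False),)),))

    def test_deterministic_given_seed(self):
        d = default_study_design(seed=9)
        r1, t1 = simulate_study(d)
        r2, t2 = simulate_study(d)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)


class TestConcentrationResponse:
    def test_hill_midpoint_and_ninety_percent(self):
        pts = simulate_concentration_response(1e-8, 1.0, [1e-8], 3, 0.0, 0)
        assert (pts["inhibition"] == 0.5).all()
        pts = simulate_concentration_response(1e-8, 1.0, [9e-8], 2, 0.0, 0)
        assert pts["inhibition"].to_numpy() == pytest.approx(0.9)

    def test_monotone_in_concentration_when_noise_free(self):
        conc = np.logspace(-9, -5, 9)
        pts = simulate_concentration_response(3e-8, 0.7, conc, 1, 0.0, 4)
        y = pts.sort_values("concentration_molar")["inhibition"].to_numpy()
        assert np.all(np.diff(y) >= 0)

    def test_noisy_panels_recover_ic50(self):
        # 10 nM drug, 5 cells x 4 concentrations, 5% noise: the fitted IC50
        # stays within 25% of truth in >= 95% of repeated panels
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            pts = simulate_concentration_response(
                1e-8, 1.0, [1e-9, 3e-9, 1e-8, 3e-8], 5, 0.05, seed)
            fit = fit_hill(pts)
            if fit.determined and abs(fit.ic50 - 1e-8) / 1e-8 < 0.25:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_empty_concentrations_rejected(self):
        with pytest.raises(InvalidDesignError):
            simulate_concentration_response(1e-8, 1.0, [], 3, 0.0, 0)

    def test_deterministic_given_seed(self):
        a = simulate_concentration_response(1e-8, 1.0, [1e-9, 1e-8], 4, 0.1, 3)
        b = simulate_concentration_response(1e-8, 1.0, [1e-9, 1e-8], 4, 0.1, 3)
        pd.testing.assert_frame_equal(a, b)


class TestCellRecording:
    def test_vehicle_peak_equals_amplitude(self, coarse_protocol):
        from hergvar.traces import measure_sweep
        cell = make_cell(coarse_protocol, herg=1000.0, leak=0.0, n_drug=0,
                         n_e4031=0)
        m = measure_sweep(cell.sweeps[0], coarse_protocol)
        assert m.ramp_peak_pA == pytest.approx(1000.0, abs=1e-12)

    def test_e4031_phase_fully_blocked(self, coarse_protocol):
        from hergvar.protocol import DEFAULT_PROTOCOL
        from hergvar.traces import subtract_e4031
        cell = make_cell(coarse_protocol, leak=2.0, noise=0.5, seed=2)
        # once leak is removed, the averaged e4031 ramp current is noise only
        ref = [i for i, p in enumerate(cell.phase_per_sweep) if p == "e4031"]
        mean_trace = np.mean([cell.sweeps[i].current_pA for i in ref], axis=0)
        sweep = cell.sweeps[ref[0]]
        ramp = coarse_protocol.window_slice(sweep.time_s,
                                            coarse_protocol.ramp_window)
        herg_part = mean_trace - 2.0 * (sweep.voltage_mV - 0.0)
        assert abs(herg_part[ramp].max()) < 3 * 0.5

    def test_rundown_rate_recovered_by_log_regression(self, coarse_protocol):
        from hergvar.traces import subtract_e4031
        cell = make_cell(coarse_protocol, rundown=0.01, n_vehicle=10,
                         n_drug=0, n_e4031=3)
        herg = subtract_e4031(cell, mode="trace")
        veh = herg[herg.phase == "vehicle"]["herg_pA"].to_numpy()
        # geometric decay: log amplitude is linear in sweep index
        slope = np.polyfit(np.arange(10), np.log(veh), 1)[0]
        rate = 1.0 - np.exp(slope)
        assert abs(rate - 0.01) < 0.002 * 0.01 + 1e-9

    def test_deterministic_given_seed(self, coarse_protocol):
        c1 = make_cell(coarse_protocol, noise=1.0, seed=8)
        c2 = make_cell(coarse_protocol, noise=1.0, seed=8)
        for s1, s2 in zip(c1.sweeps, c2.sweeps):
            assert np.array_equal(s1.current_pA, s2.current_pA)


class TestLossSamples:
    def test_sigmoid_midpoint_and_asymptote(self):
        rec = simulate_loss_samples(3.0, 3.0, 0.8, 0.0, 3, 0)
        assert rec.percent_loss == pytest.approx(50.0, abs=1e-9)
        rec = simulate_loss_samples(3.0 - 20 * 0.8, 3.0, 0.8, 0.0, 3, 0)
        assert rec.percent_loss < 1e-6

    def test_grid_recovery_of_x50(self):
        from hergvar.exposure import fit_loss_vs_logp
        logps = np.linspace(0.0, 7.0, 14)
        losses = [simulate_loss_samples(lp, 3.0, 0.8, 0.05, 3, 100 + i).percent_loss
                  for i, lp in enumerate(logps)]
        fit = fit_loss_vs_logp(logps, losses)
        assert fit.converged and abs(fit.x50 - 3.0) < 0.2

    def test_deterministic_given_seed(self):
        a = simulate_loss_samples(4.0, 3.0, 0.8, 0.1, 3, 5)
        b = simulate_loss_samples(4.0, 3.0, 0.8, 0.1, 3, 5)
        assert np.array_equal(a.starting_molar, b.starting_molar)
        assert np.array_equal(a.final_molar, b.final_molar)
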