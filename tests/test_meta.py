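"""Variance decomposition: descriptive procedure, REML, conversions."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from hergvar import meta
from hergvar.errors import FitInputError
from hergvar.synthetic import DrugSpec, LabSpec, StudyDesign, simulate_study


def records_from(drugs, labs, tau=0.0, sigma=(0.05, 0.05), seed=0):
    design = StudyDesign(drugs=tuple(drugs), labs=tuple(labs), tau=tau,
                         sigma_range=sigma, seed=seed)
    rec, _ = simulate_study(design)
    return rec


def hf7_percentile(values, q):
    """Independent Hyndman-Fan-7 percentile: sort then linear interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * (q / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestConversions:
    def test_sd_to_ratio_reference_points(self):
        assert meta.sd_to_ratio(0.0) == 1.0
        assert meta.sd_to_ratio(0.20) == pytest.approx(6.082, abs=5e-3)
        assert meta.span_to_ratio(0.7) == pytest.approx(5.012, abs=5e-3)

    def test_sd_to_ratio_strictly_increasing(self):
        grid = np.linspace(0, 1, 50)
        vals = [meta.sd_to_ratio(s) for s in grid]
        assert np.all(np.diff(vals) > 0)

    def test_negative_sd_rejected(self):
        with pytest.raises(FitInputError):
            meta.sd_to_ratio(-0.1)


class TestDescriptive:
    def test_single_record_per_drug_gives_zero_residuals(self):
        drugs = [DrugSpec(f"d{i}", 5 + i * 0.5, 1.0, 3.0) for i in range(4)]
        labs = [LabSpec("L1", 0.0, "L1",
                        tuple((d.name, False) for d in drugs))]
        rec = records_from(drugs, labs, sigma=(0.0, 0.0))
        d = meta.decompose_descriptive(rec)
        assert np.max(np.abs(d.residuals)) == 0.0
        assert d.span == 0.0 and d.fold_ratio == 1.0

    def test_known_offsets_recovered_exactly(self):
        drugs = [DrugSpec(f"d{i}", 5 + i * 0.3, 1.0, 3.0) for i in range(5)]
        offsets = {"L1": 0.0, "L2": -0.2, "L3": 0.65}
        labs = [LabSpec(lab, off, lab, tuple((d.name, False) for d in drugs))
                for lab, off in offsets.items()]
        rec = records_from(drugs, labs, sigma=(0.0, 0.0))
        d = meta.decompose_descriptive(rec)
        # offsets are identified up to the mean over labs
        rel = d.lab_offsets - d.lab_offsets["L1"]
        assert rel["L2"] == pytest.approx(0.2, abs=1e-12)
        assert rel["L3"] == pytest.approx(-0.65, abs=1e-12)
        assert np.max(np.abs(d.residuals)) < 1e-12

    def test_group_residual_means_are_zero(self, study_records):
        rec, _ = study_records
        d = meta.decompose_descriptive(rec)
        resid = d.residuals.to_numpy()
        for g in rec["group_label"].unique():
            assert abs(resid[(rec["group_label"] == g).to_numpy()].mean()) < 1e-10

    def test_span_matches_independent_percentile_oracle(self, study_records):
        rec, _ = study_records
        d = meta.decompose_descriptive(rec)
        r = d.residuals.to_numpy()
        span = hf7_percentile(r, 97.5) - hf7_percentile(r, 2.5)
        assert d.span == pytest.approx(span, abs=1e-12)
        assert d.fold_ratio == pytest.approx(10 ** span, rel=1e-12)

    def test_constant_shift_of_one_drug_leaves_residuals(self, study_records):
        rec, _ = study_records
        before = meta.decompose_descriptive(rec)
        shifted = rec.copy()
        mask = shifted["drug_id"] == "dofetilide"
        shifted.loc[mask, "pic50"] += 1.0
        after = meta.decompose_descriptive(shifted)
        assert after.drug_means["dofetilide"] == pytest.approx(
            before.drug_means["dofetilide"] + 1.0)
        np.testing.assert_allclose(after.residuals.to_numpy(),
                                   before.residuals.to_numpy(), atol=1e-10)


class TestMixedEffects:
    def test_no_heterogeneity_gives_tau_zero(self):
        rows = []
        for d, base in (("d1", 5.0), ("d2", 7.0)):
            for lab, off in (("L1", 0.0), ("L2", 0.3)):
                for k in range(3):
                    rows.append({"drug_id": d, "lab_id": lab,
                                 "experiment_id": f"{d}{lab}{k}",
                                 "pic50": base + off, "sd_pic50": 0.05,
                                 "group_label": lab})
        fit = meta.fit_mixed_effects(pd.DataFrame(rows))
        assert fit.tau == 0.0
        assert fit.fold_ratio == 1.0
        assert fit.tau_ci[0] == 0.0

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            rec = _random_instance(rng)
            fit = meta.fit_mixed_effects(rec, compute_ci=False)
            tau_grid = _grid_tau(rec)
            assert abs(fit.tau - tau_grid) <= 1e-3

    def test_invariant_to_reference_relabeling(self, study_records):
        rec, _ = study_records
        a = meta.fit_mixed_effects(rec)
        relabeled = rec.copy()
        relabeled["drug_id"] = "zz_" + relabeled["drug_id"]
        relabeled["group_label"] = relabeled["group_label"].map(
            lambda g: {"Lab1": "zLab1"}.get(g, g))
        b = meta.fit_mixed_effects(relabeled)
        assert b.tau == pytest.approx(a.tau, abs=1e-8)
        assert b.fold_ratio == pytest.approx(a.fold_ratio, rel=1e-7)

    def test_restricted_likelihood_maximal_at_estimate(self, study_records):
        rec, _ = study_records
        fit = meta.fit_mixed_effects(rec)
        lab_effect, X, names, y, s2 = meta._prepare(rec, None)
        n = len(y)
        nll_hat = meta.restricted_nll(np.full(n, fit.tau ** 2), X, y, s2)
        for tau in np.linspace(0, 0.8, 81):
            assert meta.restricted_nll(np.full(n, tau * tau), X, y, s2) >= \
                nll_hat - 1e-9

    def test_agrees_with_metafor_reference(self):
        # independent reference implementation of the same REML problem
        drugs = tuple(DrugSpec(f"d{i}", 5 + 0.4 * i, 1.0, 3.0)
                      for i in range(5))
        plan = tuple((d.name, False) for d in drugs) * 2
        labs = tuple(LabSpec(f"L{j}", 0.1 * j, f"L{j}", plan)
                     for j in range(3))
        sub = records_from(drugs, labs, tau=0.2, sigma=(0.03, 0.1), seed=13)
        fit = meta.fit_mixed_effects(sub)
        ls = meta.fit_location_scale(sub, compute_ci=False)
        r_script = r"""
suppressMessages(library(metafor))
d <- read.csv("{csv}")
f <- rma(yi = pic50, sei = sd_pic50,
         mods = ~ factor(drug_id) + factor(group_label),
         data = d, method = "REML")
cat(sqrt(f$tau2), "\n")
g <- rma(yi = pic50, sei = sd_pic50,
         mods = ~ factor(drug_id) + factor(group_label),
         scale = ~ factor(group_label) - 1, link = "identity",
         data = d, method = "REML")
cat(paste(levels(factor(d$group_label)), sqrt(pmax(g$alpha, 0)), sep="="), "\n")
"""
        import tempfile, pathlib
        with tempfile.TemporaryDirectory() as td:
            csv = pathlib.Path(td) / "rec.csv"
            sub.to_csv(csv, index=False)
            script = pathlib.Path(td) / "fit.R"
            script.write_text(r_script.replace("{csv}", str(csv)))
            out = subprocess.run(["Rscript", str(script)], check=True,
                                 capture_output=True, text=True).stdout
        lines = [l for l in out.strip().splitlines() if l.strip()]
        tau_r = float(lines[0])
        assert fit.tau == pytest.approx(tau_r, abs=2e-4)
        taus_r = dict(item.split("=") for item in lines[1].split())
        for g, t in taus_r.items():
            assert ls.tau[g] == pytest.approx(float(t), abs=2e-3)

    def test_descriptive_and_reml_agree_on_balanced_design(self):
        drugs = [DrugSpec(f"d{i}", 4.5 + 0.2 * i, 1.0, 3.0) for i in range(10)]
        labs = [LabSpec(f"L{j}", 0.1 * j, f"L{j}",
                        tuple((d.name, False) for d in drugs) * 20)
                for j in range(10)]
        rec = records_from(drugs, labs, tau=0.15, sigma=(0.05, 0.05), seed=10)
        assert len(rec) == 2000
        d = meta.decompose_descriptive(rec)
        resid_sd = d.residuals.std(ddof=1)
        fit = meta.fit_mixed_effects(rec, compute_ci=False)
        total = np.sqrt(fit.tau ** 2 + 0.05 ** 2)
        assert 0.9 < resid_sd / total < 1.1


def _random_instance(rng):
    rows = []
    for d in ("d1", "d2"):
        for lab in ("L1", "L2"):
            for k in range(3):
                rows.append({
                    "drug_id": d, "lab_id": lab,
                    "experiment_id": f"{d}{lab}{k}",
                    "pic50": rng.normal(6.0 if d == "d1" else 7.5, 0.3),
                    "sd_pic50": rng.uniform(0.02, 0.15),
                    "group_label": lab})
    return pd.DataFrame(rows)


def _grid_tau(rec, step=1e-4, upper=1.0):
    lab_effect, X, names, y, s2 = meta._prepare(rec, None)
    n = len(y)
    grid = np.arange(0.0, upper + step / 2, step)
    vals = [meta.restricted_nll(np.full(n, t * t), X, y, s2) for t in grid]
    return float(grid[int(np.argmin(vals))])


class TestLocationScale:
    def test_identical_records_in_group_give_tau_zero(self):
        rows = []
        for d, base in (("d1", 5.0), ("d2", 7.0)):
            for lab, off, jitter in (("L1", 0.0, 0.0), ("L2", 0.3, 0.1)):
                for k in range(4):
                    noise = jitter * (k - 1.5)
                    rows.append({"drug_id": d, "lab_id": lab,
                                 "experiment_id": f"{d}{lab}{k}",
                                 "pic50": base + off + noise,
                                 "sd_pic50": 0.05, "group_label": lab})
        fit = meta.fit_location_scale(pd.DataFrame(rows), compute_ci=False)
        assert fit.tau["L1"] == 0.0
        assert fit.tau["L2"] > 0.0

    def test_equal_group_taus_approach_pooled_estimate(self):
        drugs = [DrugSpec(f"d{i}", 5 + 0.3 * i, 1.0, 3.0) for i in range(8)]
        labs = [LabSpec(f"L{j}", 0.05 * j, f"L{j}",
                        tuple((d.name, False) for d in drugs) * 6)
                for j in range(3)]
        rec = records_from(drugs, labs, tau=0.15, sigma=(0.03, 0.08), seed=4)
        pooled = meta.fit_mixed_effects(rec, compute_ci=False)
        ls = meta.fit_location_scale(rec, compute_ci=False)
        for t in ls.tau.values():
            assert abs(t - pooled.tau) < 0.08

    def test_singleton_group_reported_undetermined(self):
        rows = [{"drug_id": d, "lab_id": lab, "experiment_id": f"{d}{lab}{k}",
                 "pic50": p, "sd_pic50": 0.05, "group_label": lab}
                for d, lab, k, p in (
                    ("d1", "L1", 0, 5.1), ("d1", "L1", 1, 4.9),
                    ("d2", "L1", 0, 7.2), ("d2", "L1", 1, 6.8),
                    ("d1", "L2", 0, 5.4))]
        fit = meta.fit_location_scale(pd.DataFrame(rows), compute_ci=False)
        assert np.isnan(fit.tau["L2"])
        assert np.isfinite(fit.tau["L1"])


class TestLabRatio:
    def test_identical_lab_has_ratio_one(self):
        drugs = [DrugSpec(f"d{i}", 5 + i, 1.0, 3.0) for i in range(3)]
        labs = [LabSpec(l, 0.0, l, tuple((d.name, False) for d in drugs))
                for l in ("L1", "L2")]
        rec = records_from(drugs, labs, sigma=(0.0, 0.0))
        out = meta.lab_ratio_to_group(rec, "L1")
        assert out.fold_ratio == pytest.approx(1.0, abs=1e-12)

    def test_injected_offset_yields_printed_ratio(self):
        # five labs, one sitting 0.65 pIC50 units below the five-lab group
        # average for every drug: its IC50s average 10^0.65 = 4.47x (the
        # published rounding is 4.5x) the group averages
        drugs = [DrugSpec(f"d{i}", 5 + 0.5 * i, 1.0, 3.0) for i in range(6)]
        plan = tuple((d.name, False) for d in drugs)
        labs = [LabSpec(f"L{j}", 0.0, f"L{j}", plan) for j in range(1, 5)]
        labs.append(LabSpec("L5", -0.8125, "L5", plan))
        rec = records_from(drugs, labs, sigma=(0.0, 0.0))
        out = meta.lab_ratio_to_group(rec, "L5")
        assert out.mean_diff_pic50 == pytest.approx(0.65, abs=1e-12)
        assert out.fold_ratio == pytest.approx(4.47, abs=5e-3)
        assert float(f"{out.fold_ratio:.2g}") == 4.5

    def test_mean_of_differences_identity(self, study_records):
        rec, _ = study_records
        drugs = sorted(rec.loc[rec.lab_id == "Lab4", "drug_id"].unique())
        out = meta.lab_ratio_to_group(rec, "Lab4", drugs=drugs)
        direct = np.mean([
            rec.loc[rec.drug_id == d, "pic50"].mean()
            - rec.loc[(rec.drug_id == d) & (rec.lab_id == "Lab4"),
                      "pic50"].mean()
            for d in drugs])
        assert out.mean_diff_pic50 == pytest.approx(direct, abs=1e-12)

    def test_empty_subset_rejected(self, study_records):
        rec, _ = study_records
        with pytest.raises(FitInputError):
            meta.lab_ratio_to_group(rec, "Lab4", drugs=[])


class TestWithinExperimentSummary:
    def test_constant_sd_collapses_percentiles(self):
        rows = [{"drug_id": f"d{i%3}", "lab_id": "L1",
                 "experiment_id": str(i), "pic50": 5 + 0.1 * i,
                 "sd_pic50": 0.07} for i in range(12)]
        out = meta.within_experiment_summary(pd.DataFrame(rows))
        row = out.per_lab.iloc[0]
        assert row["median_sd"] == row["p2_5_sd"] == row["p97_5_sd"] == 0.07

    def test_percentiles_match_sort_oracle(self, study_records):
        rec, _ = study_records
        out = meta.within_experiment_summary(rec)
        for _, row in out.per_lab.iterrows():
            sd = rec.loc[rec.lab_id == row["lab_id"], "sd_pic50"].to_numpy()
            assert row["p2_5_sd"] == pytest.approx(hf7_percentile(sd, 2.5),
                                                   abs=1e-12)
            assert row["p97_5_sd"] == pytest.approx(hf7_percentile(sd, 97.5),
                                                    abs=1e-12)

    def test_sd_independent_of_bias_by_construction(self):
        # sampling SDs and distances-to-group-mean are independent in the
        # generator, so r stays within its null sampling band (~1/sqrt(n))
        from hergvar.synthetic import default_study_design
        rs = []
        n_seeds = 40
        for seed in range(n_seeds):
            rec, _ = simulate_study(default_study_design(seed=seed))
            out = meta.within_experiment_summary(rec)
            rs.append(out.correlation_r)
        n = 145
        inside = np.mean(np.abs(rs) < 2.0 / np.sqrt(n - 1))
        assert inside >= 0.9
        assert abs(np.mean(rs)) < 0.05
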