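"""Synthetic-run generator: determinism, ground-truth fidelity, scenarios."""

import io
import warnings

import numpy as np
import pytest

from vlcpufa.ms_io import write_tsv_run
from vlcpufa.quant import quantify_runs
from vlcpufa.simulate import (
    IS_AMOUNT_MOL,
    PER_POS_AMOUNTS,
    RESPONSE_PER_MOL,
    ScenarioConfig,
    simulate_experiment,
    simulate_run,
)

# species whose same-m/z neighbours are >= 3 sigma away: chromatographically resolvable
RESOLVABLE = ("20:4", "20:5", "22:4", "22:6", "32:6", "34:4", "34:5", "34:6", "36:6")


class TestSimulateRun:
    def test_zero_amount_species_absent(self, panel):
        run, truth = simulate_run({"32:6": 0.0, "34:6": 1e-9}, seed=1)
        assert "32:6" not in truth.amounts_mol
        assert "32:6" not in truth.true_areas
        assert truth.amounts_mol["34:6"] == 1e-9

    def test_same_seed_identical_run(self, tmp_path):
        outputs = []
        for _ in range(2):
            run, _ = simulate_run({"32:6": 1e-9}, seed=77, noise_cv=0.1)
            buf = io.StringIO()
            path = tmp_path / "run.tsv"
            write_tsv_run(run, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_noiseless_single_species_area_recovery(self, panel):
        """Integrated area matches the analytic Gaussian area within 1%."""
        run, truth = simulate_run({"32:6": 1e-9}, seed=3, noise_cv=0.0, background_per_scan=0)
        table = quantify_runs([run], panel)
        rec = table[table.species_label == "32:6"].iloc[0]
        assert rec.raw_area == pytest.approx(truth.true_areas["32:6"], rel=0.01)

    def test_is_always_present(self):
        run, truth = simulate_run({}, seed=4)
        assert truth.amounts_mol["21:5 (IS)"] == IS_AMOUNT_MOL

    def test_ppm_offsets_within_jitter(self):
        _, truth = simulate_run({"32:6": 1e-9, "34:6": 1e-9}, seed=5, ppm_jitter_max=2.0)
        assert all(abs(off) <= 2.0 for off in truth.ppm_offsets.values())

    def test_coeluting_isomers_warn(self):
        with pytest.warns(UserWarning, match="unresolvable"):
            simulate_run({"22:5 (1)": 1e-9, "22:5 (2)": 1e-9}, seed=6)

    def test_true_areas_proportional_to_amounts(self):
        _, truth = simulate_run({"32:6": 1e-9, "34:6": 3e-9}, seed=7)
        ratio = truth.true_areas["34:6"] / truth.true_areas["32:6"]
        assert ratio == pytest.approx(3.0)
        assert truth.true_areas["32:6"] == pytest.approx(1e-9 * RESPONSE_PER_MOL)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ScenarioConfig(scenario="frisbee")

    def test_zero_dose_means_zero_markers(self, quiet_simulate):
        cfg = ScenarioConfig(scenario="pos_challenge", pos_per_cell=0.0, noise_cv=0.0)
        _, _, truths = quiet_simulate(cfg, n_replicates=1, seed=8)
        for marker in PER_POS_AMOUNTS:
            assert truths[0].nominal_amounts_mol.get(marker, 0.0) == 0.0

    def test_dose_ratios(self, quiet_simulate):
        amounts = {}
        for dose in (10, 20, 40):
            cfg = ScenarioConfig(scenario="pos_challenge", pos_per_cell=dose, noise_cv=0.0)
            _, _, truths = quiet_simulate(cfg, n_replicates=1, seed=9)
            amounts[dose] = truths[0].amounts_mol["36:6"]
        assert amounts[20] / amounts[10] == pytest.approx(2.0)
        assert amounts[40] / amounts[10] == pytest.approx(4.0)

    def test_untreated_has_no_vlc_species(self, quiet_simulate):
        cfg = ScenarioConfig(scenario="untreated_rpe", noise_cv=0.0)
        _, _, truths = quiet_simulate(cfg, n_replicates=1, seed=10)
        for label in truths[0].amounts_mol:
            carbons = int(label.split(":")[0])
            assert carbons < 30 or label.endswith("(IS)") or carbons == 21

    def test_knockdown_scales_uptake(self, quiet_simulate):
        base = ScenarioConfig(scenario="pos_challenge", pos_per_cell=10, noise_cv=0.0)
        kd = ScenarioConfig(
            scenario="knockdown", pos_per_cell=10, knockdown_effect=0.82, noise_cv=0.0
        )
        _, _, t_base = quiet_simulate(base, n_replicates=1, seed=11)
        _, _, t_kd = quiet_simulate(kd, n_replicates=1, seed=11)
        # 36:6 has no endogenous background: ratio is exactly 1 - effect
        ratio = t_kd[0].amounts_mol["36:6"] / t_base[0].amounts_mol["36:6"]
        assert ratio == pytest.approx(0.18)

    def test_calibration_series_levels(self, quiet_simulate):
        cfg = ScenarioConfig(scenario="calibration_series", noise_cv=0.0)
        runs, design, truths = quiet_simulate(cfg, seed=12)
        levels = design.table["calibration_nmol_l"].astype(float).tolist()
        assert levels == [50.0, 100.0, 250.0, 500.0, 1000.0]
        amounts = [t.amounts_mol["32:6"] for t in truths]
        np.testing.assert_allclose(np.diff(np.array(amounts) / amounts[0]) > 0, True)

    def test_design_table_matches_runs(self, quiet_simulate, challenge_config):
        runs, design, truths = quiet_simulate(challenge_config, n_replicates=3, seed=13)
        assert len(runs) == 3
        assert set(design.table["sample_id"]) == {r.run_id for r in runs}


class TestEndToEndRecovery:
    def test_noiseless_full_pipeline_within_one_percent(self, panel, quiet_simulate, challenge_config):
        runs, _, truths = quiet_simulate(challenge_config, n_replicates=1, seed=14)
        table = quantify_runs([runs[0]], panel, is_amount=IS_AMOUNT_MOL)
        truth = truths[0]
        for label in RESOLVABLE:
            true_amount = truth.amounts_mol.get(label)
            if not true_amount:
                continue
            est = table.loc[table.species_label == label, "est_amount_mol"].iloc[0]
            assert est == pytest.approx(true_amount, rel=0.01), label

    def test_noisy_full_pipeline_within_five_percent(self, panel, quiet_simulate):
        cfg = ScenarioConfig(scenario="pos_challenge", pos_per_cell=20, noise_cv=0.05)
        runs, _, truths = quiet_simulate(cfg, n_replicates=1, seed=15)
        table = quantify_runs([runs[0]], panel, is_amount=IS_AMOUNT_MOL)
        truth = truths[0]
        for label in RESOLVABLE:
            true_amount = truth.amounts_mol.get(label)
            if not true_amount:
                continue
            est = table.loc[table.species_label == label, "est_amount_mol"].iloc[0]
            assert est == pytest.approx(true_amount, rel=0.05), label

    def test_composition_recovers_ground_truth_fractions(self, panel, quiet_simulate):
        from vlcpufa.quant import quantify_run, composition_profile

        cfg = ScenarioConfig(scenario="pos_only", pos_per_cell=20, noise_cv=0.0)
        runs, _, truths = quiet_simulate(cfg, n_replicates=1, seed=16)
        records = quantify_run(runs[0], panel)
        profile = composition_profile(records)
        truth = truths[0]
        total = sum(a for l, a in truth.amounts_mol.items() if not l.endswith("(IS)"))
        for label, amount in truth.amounts_mol.items():
            if label.endswith("(IS)"):
                continue
            assert profile[label] == pytest.approx(amount / total, abs=0.02), label

    def test_per_pos_amount_round_trip(self, panel, quiet_simulate):
        """Dividing recovered totals by the POS count returns the per-POS content."""
        from vlcpufa.quant import amount_per_pos

        cfg = ScenarioConfig(scenario="pos_only", pos_per_cell=20, n_cells=1e5, noise_cv=0.0)
        runs, _, _ = quiet_simulate(cfg, n_replicates=1, seed=17)
        table = quantify_runs([runs[0]], panel, is_amount=IS_AMOUNT_MOL)
        n_pos = 20 * 1e5
        for label, per_pos in PER_POS_AMOUNTS.items():
            est = table.loc[table.species_label == label, "est_amount_mol"].iloc[0]
            assert amount_per_pos(est, n_pos) == pytest.approx(per_pos, rel=0.02), label

    def test_uptake_per_cell_round_trip(self, panel, quiet_simulate):
        """Challenge at 20 POS/cell with full internalization gains 20*p mol/cell."""
        from vlcpufa.quant import uptake_per_cell

        n_cells = 1e5
        ref = ScenarioConfig(scenario="untreated_rpe", noise_cv=0.0, n_cells=n_cells)
        chall = ScenarioConfig(
            scenario="pos_challenge", pos_per_cell=20, n_cells=n_cells, noise_cv=0.0
        )
        runs_ref, _, _ = quiet_simulate(ref, n_replicates=1, seed=18)
        runs_ch, _, _ = quiet_simulate(chall, n_replicates=1, seed=18)
        t_ref = quantify_runs([runs_ref[0]], panel, is_amount=IS_AMOUNT_MOL)
        t_ch = quantify_runs([runs_ch[0]], panel, is_amount=IS_AMOUNT_MOL)
        for label, per_pos in PER_POS_AMOUNTS.items():
            ref_amt = t_ref.loc[t_ref.species_label == label, "est_amount_mol"].iloc[0]
            ch_amt = t_ch.loc[t_ch.species_label == label, "est_amount_mol"].iloc[0]
            ref_amt = 0.0 if ref_amt is None or np.isnan(ref_amt) else ref_amt
            gained = uptake_per_cell(ch_amt, ref_amt, n_cells)
            assert gained == pytest.approx(20 * per_pos, rel=0.02), label

    def test_replicate_cv_reflects_injected_noise(self, panel, quiet_simulate):
        """15% injected replicate noise yields a measured CV consistent with 15%.

        With n = 10 replicates the sample CV of a 15%-CV lognormal lies in
        (6%, 26%) with >= 99% probability (chi-square bounds on the SD).
        """
        from vlcpufa.quant import replicate_cv

        cfg = ScenarioConfig(scenario="replicate_cv", pos_per_cell=20, noise_cv=0.15)
        runs, _, _ = quiet_simulate(cfg, n_replicates=10, seed=19)
        table = quantify_runs(runs, panel)
        vals = table.loc[table.species_label == "34:6", "normalized_response"].dropna()
        assert len(vals) == 10
        cv = replicate_cv(list(vals))
        assert 6.0 < cv < 26.0
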