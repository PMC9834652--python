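import numpy as np
import pytest

from ne_pipeline.energy_balance import analyze_experiment, load_records
from ne_pipeline.errors import ConstraintError, ValidationError
from ne_pipeline.pipeline import ingredient_energy_table
from ne_pipeline.synthetic_data import (
    DietTruth,
    difference_method_experiment,
    reference_config,
    simulate_experiment,
    truth_from_energies,
    write_simulation,
)


class TestConfigValidation:
    def test_digestibility_bounds_enforced(self):
        with pytest.raises(ValidationError):
            DietTruth(
                attd={"GE": 1.2, "DM": 0.8, "CP": 0.8, "NDF": 0.5, "ADF": 0.4, "OM": 0.8},
                ue_de=0.02, ch4e_de=0.005, rq_fed=1.07, rq_fasted=0.82,
                fhp_metab=805.0, ne_mj_kg_dm=13.0, rep_frac=0.4,
            )

    def test_rq_outside_physiological_range_rejected(self):
        with pytest.raises(ValidationError):
            truth_from_energies(18.4, 16.0, 15.7, 13.0, rq_fed=1.5)

    def test_ne_above_me_is_infeasible(self):
        config, diets = reference_config(seed=0)
        bad = dict(config.diet_truths)
        t = bad["basal"]
        bad["basal"] = DietTruth(
            attd=t.attd, ue_de=t.ue_de, ch4e_de=t.ch4e_de, rq_fed=t.rq_fed,
            rq_fasted=t.rq_fasted, fhp_metab=t.fhp_metab,
            ne_mj_kg_dm=30.0, rep_frac=t.rep_frac,
        )
        config2 = type(config)(
            seed=0, diet_truths=bad, noise_cv=0.0
        )
        with pytest.raises(ConstraintError, match="NE"):
            simulate_experiment(config2, diets)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_csvs(self, tmp_path):
        config, diets = reference_config(seed=5, noise_cv=0.03)
        p1 = write_simulation(config, diets, tmp_path / "a")
        p2 = write_simulation(config, diets, tmp_path / "b")
        for k in ("chamber_records", "balance_records", "ground_truth"):
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        c1, diets = reference_config(seed=1, noise_cv=0.03)
        c2, _ = reference_config(seed=2, noise_cv=0.03)
        a, _, _ = simulate_experiment(c1, diets)
        b, _, _ = simulate_experiment(c2, diets)
        assert not a.equals(b)


class TestGroundTruthRecovery:
    def test_zero_noise_recovers_diet_energy_and_fhp(self, zero_noise_run):
        truth = zero_noise_run["truth"]
        config = zero_noise_run["config"]
        per_diet = zero_noise_run["per_diet"].set_index("diet_id")
        for diet_id, te in truth.diet_energy.items():
            row = per_diet.loc[diet_id]
            assert row["DE_MJ_kgDM"] == pytest.approx(te["DE"], rel=1e-6)
            assert row["ME_MJ_kgDM"] == pytest.approx(te["ME"], rel=1e-6)
            assert row["NE_MJ_kgDM"] == pytest.approx(te["NE"], rel=1e-6)
            assert row["FHP_kJ_mbw_d"] == pytest.approx(
                config.diet_truths[diet_id].fhp_metab, rel=1e-6
            )

    def test_zero_noise_recovers_thp_per_pig(self, zero_noise_run):
        truth_pig = zero_noise_run["truth"].pig.set_index("pig_id")
        per_pig = zero_noise_run["per_pig"].set_index("pig_id")
        for pig_id, row in per_pig.iterrows():
            t = truth_pig.loc[pig_id]
            mbw = t["BW_kg"] ** 0.6
            assert row["THP_kJ_mbw_d"] * mbw == pytest.approx(t["THP_kJ_d"], rel=1e-9)
            assert row["RE_kJ_mbw_d"] * mbw == pytest.approx(t["RE_kJ_d"], rel=1e-9)

    def test_records_satisfy_invariants_with_noise(self, tmp_path):
        config, diets = reference_config(seed=9, noise_cv=0.03)
        chamber, balance, _ = simulate_experiment(config, diets)
        d = tmp_path
        chamber.to_csv(d / "c.csv", index=False)
        balance.to_csv(d / "b.csv", index=False)
        records = load_records(d / "c.csv", d / "b.csv")  # validation happens here
        assert len(records) == 48
        assert all(r.fasting_window.duration == 8.0 for r in records)

    def test_difference_method_round_trip(self, tmp_path):
        ing_truth = {"GE": 18.9, "DE": 11.5, "ME": 10.7, "NE": 7.50}
        config, diets, ingredient = difference_method_experiment(ing_truth, seed=3)
        chamber, balance, _ = simulate_experiment(config, diets)
        chamber.to_csv(tmp_path / "c.csv", index=False)
        balance.to_csv(tmp_path / "b.csv", index=False)
        _, per_diet = analyze_experiment(load_records(tmp_path / "c.csv", tmp_path / "b.csv"))
        _, values = ingredient_energy_table(per_diet, diets, [ingredient], 0.97, "dm")
        v = values[0]
        assert v.NE_final == pytest.approx(ing_truth["NE"], abs=0.01)
        assert v.DE_final == pytest.approx(ing_truth["DE"], rel=5e-3)
        assert v.ME_final == pytest.approx(ing_truth["ME"], rel=5e-3)


class TestNoiseModel:
    def test_noise_is_mean_one_multiplicative(self):
        config, diets = reference_config(seed=21, noise_cv=0.03)
        _, balance, truth = simulate_experiment(config, diets)
        # noisy GE intake over its own latent truth (diet GE x true DMI)
        ge = {d.diet_id: d.analyzed["GE"] for d in diets}
        latent = truth.pig.set_index("pig_id")
        rel = np.array(
            [
                row["GE_intake_kJ_d"]
                / (ge[row["diet_id"]] * 1000.0 * latent.loc[row["pig_id"], "DMI_kg_d"])
                for _, row in balance.iterrows()
            ]
        )
        assert np.mean(rel) == pytest.approx(1.0, abs=0.02)
        assert np.std(rel) == pytest.approx(0.03, abs=0.015)

    def test_diet_mean_ne_tracks_truth_under_noise(self, tmp_path):
        """With 3 % noise and 6 pigs the diet-mean NE error stays within ~2 %."""
        config, diets = reference_config(seed=13, noise_cv=0.03)
        chamber, balance, truth = simulate_experiment(config, diets)
        chamber.to_csv(tmp_path / "c.csv", index=False)
        balance.to_csv(tmp_path / "b.csv", index=False)
        _, per_diet = analyze_experiment(load_records(tmp_path / "c.csv", tmp_path / "b.csv"))
        for _, row in per_diet.iterrows():
            t = truth.diet_energy[row["diet_id"]]["NE"]
            assert abs(row["NE_MJ_kgDM"] - t) / t < 0.02
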