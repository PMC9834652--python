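"""Synthetic respiration-chamber experiments with known ground truth.

The generator builds a complete experiment — pigs, daily chamber gas
exchange, and total-collection balance records — from diet-level truths
(digestibilities, urinary/methane energy fractions, respiratory quotients,
fasting heat production, target net energy). Gas volumes are obtained by
inverting the Brouwer equation at the configured RQ, so with zero noise the
analysis pipeline reproduces every configured quantity exactly; the defaults
are anchored to the study's diet-mean tables so synthetic output is
magnitude-realistic for 30-50 kg growing barrows.

Measurement noise is multiplicative mean-one log-normal, applied last and
only to measured quantities (intakes, fecal/urinary outputs, gas volumes):
energy is conserved in the latent truth but not in the noisy measurements,
as in real chamber data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chamber_calorimetry import METHANE_ENERGY_KJ_PER_L, invert_brouwer
from .datasets import load_diet_energy, load_diet_performance, load_diets
from .datasets import load_reference_tables  # noqa: F401  (re-export: fixture surface)
from .errors import ConstraintError, ValidationError
from .feed_tables import DietFormulation
from .units import CP_PER_N, PROTEIN_ENERGY_KJ_PER_G, metabolic_weight

_ANALYTES = ("DM", "GE", "CP", "NDF", "ADF", "OM")


@dataclass(frozen=True)
class DietTruth:
    """Ground-truth physiology for pigs on one diet."""

    attd: dict[str, float]  # fraction digested per analyte in _ANALYTES
    ue_de: float  # urinary energy / DE intake
    ch4e_de: float  # methane energy / DE intake
    rq_fed: float
    rq_fasted: float
    fhp_metab: float  # kJ/kg BW^0.60/d
    ne_mj_kg_dm: float  # target diet NE
    rep_frac: float  # share of RE retained as protein
    fasting_n_frac: float = 0.5  # fasting urinary N rate / fed rate

    def __post_init__(self) -> None:
        for a, d in self.attd.items():
            if not 0.0 <= d <= 1.0:
                raise ValidationError(f"digestibility of {a} outside [0, 1]: {d}")
        for name in ("ue_de", "ch4e_de", "rep_frac", "fasting_n_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]: {v}")
        for name in ("rq_fed", "rq_fasted"):
            v = getattr(self, name)
            if not 0.7 <= v <= 1.2:
                raise ValidationError(f"{name} outside [0.7, 1.2]: {v}")
        if self.fhp_metab < 0 or self.ne_mj_kg_dm <= 0:
            raise ValidationError("FHP must be >= 0 and target NE > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment-level settings; identical configs give identical outputs."""

    seed: int = 0
    n_pigs_per_diet: int = 6
    bw_mean_kg: float = 41.0
    bw_sd_kg: float = 2.0
    dmi_per_mbw: float = 0.156  # kg DM/d per kg BW^0.60 (fixed DMI if dmi_fixed set)
    dmi_fixed_kg_d: float | None = None
    n_fed_days: int = 4
    fasting_duration_h: float = 8.0
    noise_cv: float = 0.0  # CV of multiplicative measurement noise
    diet_truths: dict[str, DietTruth] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pigs_per_diet < 1 or self.n_fed_days < 1:
            raise ValidationError("need >= 1 pig per diet and >= 1 fed day")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be nonnegative")
        if self.bw_mean_kg <= 0 or self.fasting_duration_h <= 0:
            raise ValidationError("BW mean and fasting duration must be positive")


@dataclass
class GroundTruth:
    """Latent truths the pipeline should recover."""

    diet_energy: dict[str, dict[str, float]]  # diet_id -> GE/DE/ME/NE, MJ/kg DM
    pig: pd.DataFrame  # pig_id, diet_id, BW, DMI, THP/FHP/RE kJ/d

    def to_json(self, path: str | Path) -> None:
        payload = {
            "diet_energy": self.diet_energy,
            "pig": self.pig.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def truth_from_energies(
    ge: float, de: float, me: float, ne: float,
    rq_fed: float = 1.08, rq_fasted: float = 0.82, fhp_metab: float = 805.0,
    rep_frac: float = 0.40, urine_share: float = 0.8,
    attd_overrides: dict[str, float] | None = None,
) -> DietTruth:
    """DietTruth consistent with target diet GE/DE/ME/NE (MJ/kg DM).

    The DE->ME loss is split between urine and methane by ``urine_share``.
    Non-energy digestibilities default to values typical of the study diets.
    """
    if not ge >= de >= me >= ne > 0:
        raise ConstraintError(f"need GE >= DE >= ME >= NE > 0, got {ge}, {de}, {me}, {ne}")
    loss = 1.0 - me / de
    attd = {"DM": 0.82, "GE": de / ge, "CP": 0.77, "NDF": 0.57, "ADF": 0.42, "OM": 0.84}
    if attd_overrides:
        attd.update(attd_overrides)
    return DietTruth(
        attd=attd,
        ue_de=loss * urine_share,
        ch4e_de=loss * (1.0 - urine_share),
        rq_fed=rq_fed,
        rq_fasted=rq_fasted,
        fhp_metab=fhp_metab,
        ne_mj_kg_dm=ne,
        rep_frac=rep_frac,
    )


def reference_config(seed: int = 0, noise_cv: float = 0.0, **overrides) -> tuple[SimulationConfig, list[DietFormulation]]:
    """Simulation configured to the study's diet-mean tables.

    Digestibilities, urinary/methane fractions, RQs, FHP, protein-retention
    share and target NE are read per diet from the packaged reference tables,
    so the synthetic herd emulates the study conditions (6 pigs/diet,
    ~41 kg BW, ~1.45 kg DM/d, 8-h fasting window).
    """
    perf = load_diet_performance().set_index("diet_id")
    energy = load_diet_energy().set_index("diet_id")
    diets = load_diets()
    truths = {}
    for d in diets:
        p = perf.loc[d.diet_id]
        e = energy.loc[d.diet_id]
        truths[d.diet_id] = DietTruth(
            attd={
                "DM": p["ATTD_DM_pct"] / 100.0,
                "GE": p["ATTD_GE_pct"] / 100.0,
                "CP": p["ATTD_CP_pct"] / 100.0,
                "NDF": p["ATTD_NDF_pct"] / 100.0,
                "ADF": p["ATTD_ADF_pct"] / 100.0,
                "OM": p["ATTD_OM_pct"] / 100.0,
            },
            ue_de=p["UE_DE_pct"] / 100.0,
            ch4e_de=p["CH4E_DE_pct"] / 100.0,
            rq_fed=float(e["RQ_fed"]),
            rq_fasted=float(e["RQ_fasted"]),
            fhp_metab=float(e["FHP_kJ_mbw_d"]),
            ne_mj_kg_dm=float(e["NE_MJ_kgDM"]),
            rep_frac=float(e["REP_kJ_mbw_d"] / e["RE_kJ_mbw_d"]),
        )
    config = SimulationConfig(seed=seed, noise_cv=noise_cv, diet_truths=truths, **overrides)
    return config, diets


def difference_method_experiment(
    ingredient_energy: dict[str, float],
    mixture_energy: dict[str, float] | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
    f_test_pct: float = 30.0,
    mixture_fraction: float = 0.97,
    fhp_metab: float = 805.0,
    **config_overrides,
):
    """Two-diet trial (basal + one test diet) with a known test ingredient.

    ``ingredient_energy`` and ``mixture_energy`` map GE/DE/ME/NE -> MJ/kg DM
    ground truths; diet energies compose linearly on the DM basis with an
    energy-free mineral carrier. All components share one DM content so the
    as-fed and DM inclusion bases coincide, making difference-method recovery
    exact rather than basis-dependent. Returns (config, diets, ingredient).
    """
    from .feed_tables import IngredientComposition

    mix = mixture_energy or {"GE": 18.98, "DE": 16.55, "ME": 16.19, "NE": 13.49}
    ing_e = ingredient_energy
    for e in (mix, ing_e):
        if not e["GE"] >= e["DE"] >= e["ME"] >= e["NE"] > 0:
            raise ConstraintError(f"need GE >= DE >= ME >= NE > 0, got {e}")
    dm = 99.0  # shared DM content, % (matches the assumed mineral-carrier DM)
    ingredient = IngredientComposition(
        ingredient_id="synthetic test ingredient",
        GE=ing_e["GE"], DM=dm, CP=17.0, EE=2.5, starch=16.0,
        NDF=42.0, ADF=11.0, IDF=40.0, TDF=43.0, ash=5.5,
    )
    f_test = f_test_pct / 100.0
    f_mix_test = 1.0 - f_test - (1.0 - mixture_fraction)  # same carrier share in both diets
    mix_chem = {"CP": 19.4, "EE": 2.3, "NDF": 13.8, "ADF": 4.3, "ash": 5.1}
    basal_chem = {k: mixture_fraction * v for k, v in mix_chem.items()}
    test_chem = {
        k: f_mix_test * mix_chem[k] + f_test * getattr(ingredient, {"ash": "ash"}.get(k, k))
        for k in mix_chem
    }
    diets = [
        DietFormulation(
            diet_id="synthetic basal",
            inclusions={"corn": 72.35, "soybean meal": 24.65, "minerals": 3.00},
            analyzed={"GE": mixture_fraction * mix["GE"], "DM": dm, **basal_chem},
            mixture_ids=frozenset({"corn", "soybean meal"}),
        ),
        DietFormulation(
            diet_id="synthetic test diet",
            inclusions={
                "corn": 50.00, "soybean meal": 100.0 * f_mix_test - 50.00,
                ingredient.ingredient_id: f_test_pct, "minerals": 3.00,
            },
            analyzed={
                "GE": f_mix_test * mix["GE"] + f_test * ing_e["GE"], "DM": dm, **test_chem,
            },
            mixture_ids=frozenset({"corn", "soybean meal"}),
            test_id=ingredient.ingredient_id,
        ),
    ]
    truths = {
        "synthetic basal": truth_from_energies(
            *(mixture_fraction * mix[k] for k in ("GE", "DE", "ME", "NE")),
            fhp_metab=fhp_metab,
        ),
        "synthetic test diet": truth_from_energies(
            *(f_mix_test * mix[k] + f_test * ing_e[k] for k in ("GE", "DE", "ME", "NE")),
            fhp_metab=fhp_metab,
        ),
    }
    config = SimulationConfig(
        seed=seed, noise_cv=noise_cv, diet_truths=truths, **config_overrides
    )
    return config, diets, ingredient


def _noise_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative log-normal factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def simulate_experiment(
    config: SimulationConfig, diets: list[DietFormulation]
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (chamber_records, balance_records, ground_truth) for the herd.

    Every diet in ``diets`` must have a truth in ``config.diet_truths``.
    Infeasible targets (NE above ME, negative urinary N, negative THP) raise
    ConstraintError before any record is emitted.
    """
    rng = np.random.default_rng(config.seed)
    chamber_rows, balance_rows, pig_rows = [], [], []
    diet_energy: dict[str, dict[str, float]] = {}
    for diet in diets:
        if diet.diet_id not in config.diet_truths:
            raise ConstraintError(f"no ground truth configured for diet {diet.diet_id!r}")
    for diet in diets:
        t = config.diet_truths[diet.diet_id]
        chem = diet.analyzed
        ge = chem["GE"]  # MJ/kg DM
        de = ge * t.attd["GE"]
        me = de * (1.0 - t.ue_de - t.ch4e_de)
        ne = t.ne_mj_kg_dm
        if ne > me:
            raise ConstraintError(
                f"{diet.diet_id}: target NE ({ne}) exceeds implied ME ({me:.3f})"
            )
        diet_energy[diet.diet_id] = {"GE": ge, "DE": de, "ME": me, "NE": ne}
        for j in range(config.n_pigs_per_diet):
            pig_id = f"{diet.diet_id}/pig{j + 1}"
            bw = float(np.clip(rng.normal(config.bw_mean_kg, config.bw_sd_kg),
                               0.5 * config.bw_mean_kg, None))
            mbw = metabolic_weight(bw)
            dmi = config.dmi_fixed_kg_d or config.dmi_per_mbw * mbw
            # latent daily truth (kJ, g)
            ge_int = ge * 1000.0 * dmi
            de_int = ge_int * t.attd["GE"]
            ue = t.ue_de * de_int
            ch4e = t.ch4e_de * de_int
            ch4_l = ch4e / METHANE_ENERGY_KJ_PER_L
            mei = de_int - ue - ch4e
            fhp = t.fhp_metab * mbw
            re = ne * 1000.0 * dmi - fhp
            thp = mei - re
            if thp <= 0 or re < 0:
                raise ConstraintError(
                    f"{diet.diet_id}: infeasible energy partition "
                    f"(THP={thp:.0f}, RE={re:.0f} kJ/d)"
                )
            # nutrient flows, g/d
            intakes = {
                "DM": dmi * 1000.0,
                "CP": chem["CP"] / 100.0 * dmi * 1000.0,
                "NDF": chem["NDF"] / 100.0 * dmi * 1000.0,
                "ADF": chem["ADF"] / 100.0 * dmi * 1000.0,
                "OM": (100.0 - chem["ash"]) / 100.0 * dmi * 1000.0,
            }
            n_int = intakes["CP"] / CP_PER_N
            fecal_n = n_int * (1.0 - t.attd["CP"])
            n_ret = t.rep_frac * re / (CP_PER_N * PROTEIN_ENERGY_KJ_PER_G)
            urine_n = n_int - fecal_n - n_ret
            if urine_n < 0:
                raise ConstraintError(
                    f"{diet.diet_id}: protein retention target implies negative "
                    f"urinary N ({urine_n:.2f} g/d)"
                )
            o2_fed, co2_fed = invert_brouwer(thp, t.rq_fed, ch4_l, urine_n)
            fast_h = config.fasting_duration_h
            fhp_window = fhp * fast_h / 24.0
            fast_n = t.fasting_n_frac * urine_n * fast_h / 24.0
            o2_fast, co2_fast = invert_brouwer(fhp_window, t.rq_fasted, 0.0, fast_n)
            nz = lambda x: float(x * _noise_factor(rng, config.noise_cv))
            # one weighing-error factor per pig: feed intake is recorded once,
            # so its error moves DMI and every intake-derived flow together
            # (and largely cancels in per-kg-DM energy densities)
            f_intake = float(_noise_factor(rng, config.noise_cv))
            for day in range(1, config.n_fed_days + 1):
                chamber_rows.append(
                    {
                        "pig_id": pig_id, "period": 1, "diet_id": diet.diet_id,
                        "BW_kg": bw, "day": day, "state": "fed",
                        "O2_L": nz(o2_fed), "CO2_L": nz(co2_fed),
                        "CH4_L": nz(ch4_l), "urine_N_g": nz(urine_n),
                        "duration_h": 24.0,
                    }
                )
            chamber_rows.append(
                {
                    "pig_id": pig_id, "period": 1, "diet_id": diet.diet_id,
                    "BW_kg": bw, "day": config.n_fed_days + 1, "state": "fasting",
                    "O2_L": nz(o2_fast), "CO2_L": nz(co2_fast),
                    "CH4_L": 0.0, "urine_N_g": nz(fast_n),
                    "duration_h": fast_h,
                }
            )
            balance_rows.append(
                {
                    "pig_id": pig_id, "period": 1, "diet_id": diet.diet_id,
                    "BW_kg": bw, "DMI_kg_d": dmi * f_intake,
                    "GE_intake_kJ_d": ge_int * f_intake,
                    "fecal_GE_kJ_d": nz(ge_int * (1.0 - t.attd["GE"])),
                    "N_intake_g_d": n_int * f_intake, "fecal_N_g_d": nz(fecal_n),
                    "urine_N_g_d": nz(urine_n), "urine_E_kJ_d": nz(ue),
                    "DM_intake_g_d": intakes["DM"] * f_intake,
                    "fecal_DM_g_d": nz(intakes["DM"] * (1.0 - t.attd["DM"])),
                    "OM_intake_g_d": intakes["OM"] * f_intake,
                    "fecal_OM_g_d": nz(intakes["OM"] * (1.0 - t.attd["OM"])),
                    "NDF_intake_g_d": intakes["NDF"] * f_intake,
                    "fecal_NDF_g_d": nz(intakes["NDF"] * (1.0 - t.attd["NDF"])),
                    "ADF_intake_g_d": intakes["ADF"] * f_intake,
                    "fecal_ADF_g_d": nz(intakes["ADF"] * (1.0 - t.attd["ADF"])),
                }
            )
            pig_rows.append(
                {
                    "pig_id": pig_id, "diet_id": diet.diet_id, "BW_kg": bw,
                    "DMI_kg_d": dmi, "THP_kJ_d": thp, "FHP_kJ_d": fhp, "RE_kJ_d": re,
                }
            )
    truth = GroundTruth(diet_energy=diet_energy, pig=pd.DataFrame(pig_rows))
    return pd.DataFrame(chamber_rows), pd.DataFrame(balance_rows), truth


def write_simulation(
    config: SimulationConfig, diets: list[DietFormulation], out_dir: str | Path
) -> dict[str, Path]:
    """Run the generator and write chamber/balance CSVs plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chamber, balance, truth = simulate_experiment(config, diets)
    paths = {
        "chamber_records": out / "chamber_records.csv",
        "balance_records": out / "balance_records.csv",
        "ground_truth": out / "ground_truth.json",
    }
    chamber.to_csv(paths["chamber_records"], index=False)
    balance.to_csv(paths["balance_records"], index=False)
    truth.to_json(paths["ground_truth"])
    return paths
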