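"""Packaged reference tables from the wheat-bran energy-evaluation study.

The package ships the study's printed summary tables as small CSVs:

* ``ingredients.csv`` — chemistry of six wheat brans and one wheat shorts
  (DM basis; GE in MJ/kg DM).
* ``diets.csv`` / ``diet_chemistry.csv`` — formulation (as-fed inclusion %)
  and analyzed chemistry of the basal, six wheat-bran and one wheat-shorts
  diets.
* ``diet_performance.csv`` — diet-mean digestibility and nitrogen balance
  (n = 6 pigs per diet).
* ``diet_energy.csv`` — diet-mean energy balance (kJ/kg BW^0.60/d) and
  energy values (MJ/kg DM).
* ``ingredient_energy.csv`` — difference-method ingredient energy values,
  prediction-equation estimates and their relative errors.

Per-animal records were never published; the diet-level tables are means,
which is why the synthetic generator (not these tables) feeds the per-pig
stages of the pipeline in tests.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .feed_tables import (
    DietFormulation,
    IngredientComposition,
    read_diet_tables,
    read_ingredient_table,
)

WHEAT_BRAN_IDS = tuple(f"wheat bran {i}" for i in range(1, 7))
WHEAT_SHORTS_ID = "wheat shorts"


def _data_path(name: str):
    return resources.files("ne_pipeline") / "data" / name


def load_ingredients() -> list[IngredientComposition]:
    """The seven test-ingredient compositions as validated records."""
    return read_ingredient_table(_data_path("ingredients.csv"))


def load_diets() -> list[DietFormulation]:
    """The eight diet formulations (basal, six wheat-bran, one wheat-shorts)."""
    return read_diet_tables(_data_path("diets.csv"), _data_path("diet_chemistry.csv"))


def load_diet_performance() -> pd.DataFrame:
    """Diet-mean digestibility and nitrogen-balance table."""
    return pd.read_csv(_data_path("diet_performance.csv"))


def load_diet_energy() -> pd.DataFrame:
    """Diet-mean energy balance and energy values."""
    return pd.read_csv(_data_path("diet_energy.csv"))


def load_ingredient_energy() -> pd.DataFrame:
    """Ingredient-level energy values, predictions and relative errors."""
    return pd.read_csv(_data_path("ingredient_energy.csv"))


def load_reference_tables() -> dict:
    """All packaged reference tables, keyed by role."""
    return {
        "ingredients": load_ingredients(),
        "diets": load_diets(),
        "diet_performance": load_diet_performance(),
        "diet_energy": load_diet_energy(),
        "ingredient_energy": load_ingredient_energy(),
    }


def wheat_bran_frame() -> pd.DataFrame:
    """Chemistry plus determined DE/ME/NE for the six wheat brans, one row each.

    This is the 6-sample table behind the correlation matrix and the NE
    prediction equations (chemistry in % DM, energies in MJ/kg DM).
    """
    ing = {r.ingredient_id: r for r in load_ingredients()}
    energy = load_ingredient_energy().set_index("ingredient_id")
    rows = []
    for iid in WHEAT_BRAN_IDS:
        r = ing[iid]
        e = energy.loc[iid]
        rows.append(
            {
                "ingredient_id": iid,
                "GE": r.GE, "CP": r.CP, "EE": r.EE, "starch": r.starch,
                "NDF": r.NDF, "ADF": r.ADF, "IDF": r.IDF, "SDF": r.SDF,
                "TDF": r.TDF, "ash": r.ash,
                "DE": float(e["DE_MJ_kgDM"]),
                "ME": float(e["ME_MJ_kgDM"]),
                "NE": float(e["NE_MJ_kgDM"]),
                "NE_ME": 100.0 * float(e["NE_MJ_kgDM"]) / float(e["ME_MJ_kgDM"]),
            }
        )
    return pd.DataFrame(rows).set_index("ingredient_id")
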