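"""Ingredient and diet tables: data model, validation, derived chemistry, CSV I/O.

Ingredient chemistry is stored on a dry-matter (DM) basis except for DM itself,
which is % as-fed. Two analytes are derivable and are filled in when absent:
soluble dietary fiber (SDF = TDF - IDF) and crude protein from Kjeldahl
nitrogen (CP = 6.25 * N). When both the derived and the assayed value are
present they must agree within a small tolerance that absorbs two-decimal
rounding of published tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError
from .units import CP_PER_N

#: Agreement required between assayed SDF and TDF - IDF, % DM.
SDF_TOLERANCE = 0.02
#: Agreement required between assayed CP and 6.25 * N, % DM.
CP_TOLERANCE = 0.05

_PCT_FIELDS = ("DM", "CP", "EE", "starch", "NDF", "ADF", "IDF", "SDF", "TDF", "ash")

INGREDIENT_COLUMNS = {
    "ingredient_id": "ingredient_id",
    "GE_MJ_kgDM": "GE",
    "DM_pct": "DM",
    "CP_pctDM": "CP",
    "EE_pctDM": "EE",
    "starch_pctDM": "starch",
    "NDF_pctDM": "NDF",
    "ADF_pctDM": "ADF",
    "IDF_pctDM": "IDF",
    "SDF_pctDM": "SDF",
    "TDF_pctDM": "TDF",
    "ash_pctDM": "ash",
}
_OPTIONAL_COLUMNS = {"N_pctDM": "N", "SDF_pctDM": "SDF"}


def derive_sdf(tdf: float, idf: float) -> float:
    """Soluble dietary fiber as the difference between total and insoluble, % DM."""
    if idf < 0 or tdf < 0:
        raise DomainError(f"fiber fractions must be nonnegative (TDF={tdf}, IDF={idf})")
    if idf > tdf:
        raise DomainError(f"IDF ({idf}) exceeds TDF ({tdf})")
    return tdf - idf


def cp_from_nitrogen(n: float) -> float:
    """Crude protein from Kjeldahl nitrogen, CP = 6.25 * N, % DM."""
    if n < 0:
        raise DomainError(f"nitrogen must be nonnegative, got {n}")
    return CP_PER_N * n


@dataclass
class IngredientComposition:
    """Proximate and fiber chemistry of one feedstuff (DM basis, GE in MJ/kg DM)."""

    ingredient_id: str
    GE: float
    DM: float
    CP: float
    EE: float
    starch: float
    NDF: float
    ADF: float
    IDF: float
    TDF: float
    ash: float
    SDF: float | None = None
    N: float | None = None

    def __post_init__(self) -> None:
        if self.GE <= 0:
            raise ValidationError(f"{self.ingredient_id}: GE must be positive, got {self.GE}")
        if self.SDF is None:
            self.SDF = derive_sdf(self.TDF, self.IDF)
        if self.N is not None and (self.CP is None or _isnan(self.CP)):
            self.CP = cp_from_nitrogen(self.N)
        for name in _PCT_FIELDS:
            v = getattr(self, name)
            if v is None or _isnan(v):
                continue
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{self.ingredient_id}: {name} must be within [0, 100], got {v}"
                )
        if self.ADF > self.NDF:
            raise ValidationError(
                f"{self.ingredient_id}: ADF ({self.ADF}) exceeds NDF ({self.NDF})"
            )
        if self.IDF > self.TDF:
            raise ValidationError(
                f"{self.ingredient_id}: IDF ({self.IDF}) exceeds TDF ({self.TDF})"
            )
        if abs(self.SDF - (self.TDF - self.IDF)) > SDF_TOLERANCE:
            raise ValidationError(
                f"{self.ingredient_id}: SDF ({self.SDF}) disagrees with "
                f"TDF - IDF ({self.TDF - self.IDF:.4f}) beyond {SDF_TOLERANCE}"
            )
        if self.N is not None and abs(self.CP - cp_from_nitrogen(self.N)) > CP_TOLERANCE:
            raise ValidationError(
                f"{self.ingredient_id}: CP ({self.CP}) disagrees with "
                f"6.25*N ({cp_from_nitrogen(self.N):.4f}) beyond {CP_TOLERANCE}"
            )


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass
class DietFormulation:
    """One diet: as-fed inclusion percentages plus analyzed chemistry (DM basis).

    ``mixture_ids`` names the ingredients forming the reference basal mixture
    (corn, soybean meal, crystalline amino acids); ``test_id`` names the test
    ingredient and is None for the basal diet.
    """

    diet_id: str
    inclusions: dict[str, float]
    analyzed: dict[str, float]  # keys: GE (MJ/kg DM), DM, CP, EE, NDF, ADF, ash (% DM)
    mixture_ids: frozenset[str] = field(default_factory=frozenset)
    test_id: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.inclusions.values())
        if abs(total - 100.0) > 0.01:
            raise ValidationError(
                f"{self.diet_id}: inclusions sum to {total:.4f}, expected 100 +/- 0.01"
            )
        f_mix = self.mixture_fraction_pct
        if not 0.0 < f_mix <= 100.0:
            raise ValidationError(
                f"{self.diet_id}: mixture fraction {f_mix:.4f}% outside (0, 100]"
            )
        if self.test_id is not None and self.test_id not in self.inclusions:
            raise ValidationError(
                f"{self.diet_id}: test ingredient {self.test_id!r} not among inclusions"
            )

    @property
    def mixture_fraction_pct(self) -> float:
        """As-fed % of the diet contributed by the basal-mixture ingredients."""
        return sum(self.inclusions.get(i, 0.0) for i in self.mixture_ids)

    @property
    def test_fraction_pct(self) -> float:
        """As-fed % of the diet contributed by the test ingredient (0 for basal)."""
        return self.inclusions.get(self.test_id, 0.0) if self.test_id else 0.0


@dataclass
class CompositionSummary:
    """Per-analyte mean and coefficient of variation over a set of ingredients."""

    analytes: tuple[str, ...]
    mean: dict[str, float]
    cv_pct: dict[str, float]
    n: int
    denominator: Literal["population", "sample"] = "population"


def summarize_compositions(
    records: Sequence[IngredientComposition],
    analytes: Iterable[str] = ("GE", "DM", "CP", "EE", "starch", "NDF", "ADF", "IDF", "SDF", "TDF", "ash"),
    denominator: Literal["population", "sample"] = "population",
) -> CompositionSummary:
    """Mean and CV (100*sd/mean) per analyte.

    The CV denominator defaults to the population form (divide by n), which is
    what published ingredient tables in this field most often use.
    """
    records = list(records)
    if len(records) < 2:
        raise DomainError(f"need at least 2 records to summarize, got {len(records)}")
    analytes = tuple(analytes)
    ddof = 0 if denominator == "population" else 1
    mean: dict[str, float] = {}
    cv: dict[str, float] = {}
    for a in analytes:
        vals = np.array([getattr(r, a) for r in records], dtype=float)
        if np.isnan(vals).any():
            raise DomainError(f"analyte {a!r} missing in some records")
        m = float(vals.mean())
        mean[a] = m
        cv[a] = float(100.0 * vals.std(ddof=ddof) / m) if m != 0 else float("nan")
    return CompositionSummary(analytes, mean, cv, len(records), denominator)


# ---------------------------------------------------------------------------
# CSV I/O


def read_ingredient_table(path: str | Path) -> list[IngredientComposition]:
    """Read ``ingredients.csv`` into validated records.

    SDF and CP are derived from TDF-IDF and 6.25*N respectively when their
    columns are absent or empty.
    """
    df = pd.read_csv(path)
    mandatory = [c for c in INGREDIENT_COLUMNS if c not in _OPTIONAL_COLUMNS]
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col, attr in {**INGREDIENT_COLUMNS, **_OPTIONAL_COLUMNS}.items():
            if col in df.columns:
                v = row[col]
                kwargs[attr] = None if (col in _OPTIONAL_COLUMNS and pd.isna(v)) else v
        kwargs["ingredient_id"] = str(row["ingredient_id"])
        try:
            records.append(IngredientComposition(**kwargs))
        except (ValidationError, DomainError) as e:
            raise ValidationError(f"{path} row {idx}: {e}") from e
    return records


def write_ingredient_table(records: Sequence[IngredientComposition], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "ingredient_id": r.ingredient_id,
                "GE_MJ_kgDM": r.GE,
                "DM_pct": r.DM,
                "CP_pctDM": r.CP,
                "EE_pctDM": r.EE,
                "starch_pctDM": r.starch,
                "NDF_pctDM": r.NDF,
                "ADF_pctDM": r.ADF,
                "IDF_pctDM": r.IDF,
                "SDF_pctDM": r.SDF,
                "TDF_pctDM": r.TDF,
                "ash_pctDM": r.ash,
                "N_pctDM": r.N,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_diet_tables(
    diets_path: str | Path, chemistry_path: str | Path
) -> list[DietFormulation]:
    """Read the long-form inclusion table plus the companion analyzed-chemistry table."""
    inc = pd.read_csv(diets_path)
    chem = pd.read_csv(chemistry_path)
    for col in (
        "diet_id",
        "ingredient_id",
        "inclusion_pct_asfed",
        "is_mixture_component",
        "is_test_ingredient",
    ):
        if col not in inc.columns:
            raise SchemaError(f"{diets_path}: missing mandatory column {col!r}")
    if "diet_id" not in chem.columns:
        raise SchemaError(f"{chemistry_path}: missing mandatory column 'diet_id'")
    chem = chem.set_index("diet_id")
    diets = []
    for diet_id, g in inc.groupby("diet_id", sort=False):
        inclusions = dict(zip(g["ingredient_id"], g["inclusion_pct_asfed"].astype(float)))
        mixture = frozenset(g.loc[g["is_mixture_component"] == 1, "ingredient_id"])
        test = g.loc[g["is_test_ingredient"] == 1, "ingredient_id"]
        if len(test) > 1:
            raise ValidationError(f"{diet_id}: more than one test ingredient")
        if diet_id not in chem.index:
            raise SchemaError(f"{chemistry_path}: no analyzed chemistry for diet {diet_id!r}")
        row = chem.loc[diet_id]
        analyzed = {
            "GE": float(row["GE_MJ_kgDM"]),
            "DM": float(row["DM_pct"]),
            "CP": float(row["CP_pctDM"]),
            "EE": float(row["EE_pctDM"]),
            "NDF": float(row["NDF_pctDM"]),
            "ADF": float(row["ADF_pctDM"]),
            "ash": float(row["ash_pctDM"]),
        }
        diets.append(
            DietFormulation(
                diet_id=str(diet_id),
                inclusions=inclusions,
                analyzed=analyzed,
                mixture_ids=mixture,
                test_id=str(test.iloc[0]) if len(test) == 1 else None,
            )
        )
    return diets
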