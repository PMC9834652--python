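"""Ingredient energy values by the difference method.

A test ingredient's energy is isolated by feeding a basal diet (corn +
soybean meal + crystalline amino acids, the "mixture", plus an energy-free
mineral/vitamin carrier) and a test diet in which the test ingredient
replaces part of the mixture. The mixture's energy per kg DM is the basal
diet's energy divided by the mixture's share of the basal diet (0.97 by
formulation); the test ingredient's calculated energy is then

    E_c = (E_test_diet - f_mix * E_mixture) / f_test

for each of GE, DE, ME, NE. Because the calculated GE (GEc) rarely equals
the bomb-calorimetry GE of the ingredient (GEm), the final values propagate
the measured GE through the cascade ratios:

    DE = GEm * DEc/GEc;  ME = DE * MEc/DEc;  NE = ME * NEc/MEc

Inclusion fractions are published as-fed but energies are per kg DM; by
default the fractions are converted to a DM basis before the subtraction
(a config switch keeps raw as-fed fractions for sensitivity checks).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

from .errors import DomainError
from .feed_tables import DietFormulation, IngredientComposition

#: Mixture share of the basal diet used to scale basal energy to mixture energy.
DEFAULT_MIXTURE_FRACTION = 0.97

#: Assumed DM content of the mineral/vitamin carrier fraction, % (salt,
#: limestone, dicalcium phosphate, premix are nearly moisture-free).
DEFAULT_MINERAL_DM_PCT = 99.0

ENERGY_KEYS = ("GE", "DE", "ME", "NE")


@dataclass(frozen=True)
class MixtureEnergy:
    """Energy of the corn-soybean-meal-amino-acid mixture, MJ/kg DM."""

    GE: float
    DE: float
    ME: float
    NE: float
    mixture_fraction_basal: float = DEFAULT_MIXTURE_FRACTION

    def __post_init__(self) -> None:
        for k in ENERGY_KEYS:
            if getattr(self, k) <= 0:
                raise DomainError(f"mixture {k} must be positive")
        if not 0.0 < self.mixture_fraction_basal <= 1.0:
            raise DomainError("mixture fraction must be in (0, 1]")


@dataclass(frozen=True)
class IngredientEnergyValues:
    """Difference-method intermediates and final energy values, MJ/kg DM."""

    ingredient_id: str
    GEc: float
    DEc: float
    MEc: float
    NEc: float
    GEm: float
    DE_final: float
    ME_final: float
    NE_final: float

    @property
    def DE_over_GE(self) -> float:
        return 100.0 * self.DE_final / self.GEm

    @property
    def ME_over_DE(self) -> float:
        return 100.0 * self.ME_final / self.DE_final

    @property
    def NE_over_ME(self) -> float:
        return 100.0 * self.NE_final / self.ME_final


def basal_mixture_energy(basal_diet_energy: float, mixture_fraction: float = DEFAULT_MIXTURE_FRACTION) -> float:
    """Mixture energy per kg DM from basal-diet energy: E / fraction."""
    if mixture_fraction <= 0:
        raise DomainError(f"mixture fraction must be positive, got {mixture_fraction}")
    return basal_diet_energy / mixture_fraction


def mixture_from_basal(
    basal_energy: Mapping[str, float],
    mixture_fraction: float = DEFAULT_MIXTURE_FRACTION,
) -> MixtureEnergy:
    """Scale a basal diet's GE/DE/ME/NE (MJ/kg DM) to the mixture alone."""
    return MixtureEnergy(
        **{k: basal_mixture_energy(basal_energy[k], mixture_fraction) for k in ENERGY_KEYS},
        mixture_fraction_basal=mixture_fraction,
    )


def energy_by_difference(
    test_diet_energy: float, mixture_energy: float, f_mix: float, f_test: float
) -> float:
    """Calculated ingredient energy: (E_diet - f_mix * E_mixture) / f_test.

    Fractions are proportions of the test diet (same basis as the energies);
    their sum may fall slightly below 1 because of the energy-free
    mineral/vitamin carrier. A negative result is flagged but returned.
    """
    if f_test <= 0:
        raise DomainError(f"test-ingredient fraction must be positive, got {f_test}")
    if f_mix < 0 or f_mix + f_test > 1.0 + 1e-6:
        raise DomainError(f"fractions infeasible: f_mix={f_mix}, f_test={f_test}")
    e = (test_diet_energy - f_mix * mixture_energy) / f_test
    if e < 0:
        warnings.warn(f"negative calculated energy ({e:.3f} MJ/kg DM)", stacklevel=2)
    return e


def finalize_with_ge_ratio(
    ingredient_id: str, GEc: float, DEc: float, MEc: float, NEc: float, GEm: float
) -> IngredientEnergyValues:
    """Propagate the measured ingredient GE through the calculated cascade ratios."""
    if min(GEc, DEc, MEc) <= 0:
        raise DomainError(
            f"{ingredient_id}: calculated GE/DE/ME must be positive "
            f"(GEc={GEc}, DEc={DEc}, MEc={MEc})"
        )
    de = GEm * DEc / GEc
    me = de * MEc / DEc
    ne = me * NEc / MEc
    return IngredientEnergyValues(
        ingredient_id=ingredient_id,
        GEc=GEc, DEc=DEc, MEc=MEc, NEc=NEc, GEm=GEm,
        DE_final=de, ME_final=me, NE_final=ne,
    )


def inclusion_fractions(
    diet: DietFormulation,
    test_ingredient: IngredientComposition | None = None,
    basis: Literal["dm", "as-fed"] = "dm",
    mineral_dm_pct: float = DEFAULT_MINERAL_DM_PCT,
) -> tuple[float, float]:
    """(f_mix, f_test) shares of the test diet on the requested basis.

    On the "dm" basis the as-fed inclusions are converted with ingredient DM
    contents: the test ingredient uses its assayed DM, the mineral carrier an
    assumed DM, and the mixture's DM is inferred by closure against the
    analyzed diet DM (sum of inclusion*DM equals 100*diet DM).
    """
    f_mix_af = diet.mixture_fraction_pct / 100.0
    f_test_af = diet.test_fraction_pct / 100.0
    if basis == "as-fed":
        return f_mix_af, f_test_af
    if test_ingredient is None:
        raise DomainError("DM-basis fractions need the test ingredient's DM content")
    diet_dm = diet.analyzed["DM"]
    test_dm_share = f_test_af * test_ingredient.DM / diet_dm
    f_mineral_af = 1.0 - f_mix_af - f_test_af
    mineral_dm_share = f_mineral_af * mineral_dm_pct / diet_dm
    mix_dm_share = 1.0 - test_dm_share - mineral_dm_share
    if mix_dm_share <= 0:
        raise DomainError(f"{diet.diet_id}: inferred mixture DM share nonpositive")
    return mix_dm_share, test_dm_share


def ingredient_energy_from_diets(
    test_diet_energy: Mapping[str, float],
    mixture: MixtureEnergy,
    diet: DietFormulation,
    ingredient: IngredientComposition,
    basis: Literal["dm", "as-fed"] = "dm",
    mineral_dm_pct: float = DEFAULT_MINERAL_DM_PCT,
) -> IngredientEnergyValues:
    """Full difference-method chain for one test diet.

    ``test_diet_energy`` maps GE/DE/ME/NE -> MJ/kg DM of the test diet
    (analyzed GE; DE/ME/NE from the energy balance). The ingredient's bomb
    GE (``ingredient.GE``) anchors the final values.
    """
    f_mix, f_test = inclusion_fractions(diet, ingredient, basis, mineral_dm_pct)
    calc = {
        k: energy_by_difference(test_diet_energy[k], getattr(mixture, k), f_mix, f_test)
        for k in ENERGY_KEYS
    }
    return finalize_with_ge_ratio(
        ingredient.ingredient_id, calc["GE"], calc["DE"], calc["ME"], calc["NE"], ingredient.GE
    )
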