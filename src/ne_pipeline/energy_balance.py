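"""Digestibility, nitrogen balance, and diet-level energy partition per pig.

The energy cascade per pig is:

    GE intake -> DE   (minus fecal energy)
    DE        -> ME   (minus urinary energy and methane energy)
    ME intake -> RE   (minus total heat production, THP)
    NE        = (RE + FHP) / DM intake

with THP and FHP from respiration-chamber gas exchange (Brouwer equation),
retained energy as protein REP = N retention * 6.25 * 23.86 kJ/g, and retained
energy as lipid REL = RE - REP. Diet-level values are per-pig means ("per-pig
first"); THP can additionally be adjusted to a common reference ME intake by
within-period covariance (a pooled least-squares slope of THP on MEI).

Units: kJ and g per day internally; diet energy densities are reported in
MJ/kg DM; per-size energy flows in kJ/kg BW^0.60/d.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chamber_calorimetry import (
    GasExchangeWindow,
    extrapolate_fhp,
    heat_production,
    methane_energy,
    respiratory_quotient,
)
from .errors import DomainError, SchemaError, ValidationError
from .units import CP_PER_N, PROTEIN_ENERGY_KJ_PER_G, kj_to_mj, metabolic_weight

#: Experiment-mean ME intake used as the covariance-adjustment reference,
#: kJ/kg BW^0.60/d.
DEFAULT_MEI_REF = 2254.0


# ---------------------------------------------------------------------------
# Elementary operations


def attd(fi: float, ff: float) -> float:
    """Apparent total tract digestibility, % = 100*(Fi - Ff)/Fi.

    ``Fi`` is total intake and ``Ff`` total fecal output of the analyte over a
    collection period (kJ for energy, g for nutrients). Fecal output larger
    than intake yields a negative digestibility, which is flagged but returned.
    """
    if fi <= 0:
        raise DomainError(f"intake must be positive, got {fi}")
    if ff < 0:
        raise DomainError(f"fecal output must be nonnegative, got {ff}")
    if ff > fi:
        warnings.warn(
            f"fecal output ({ff}) exceeds intake ({fi}); negative digestibility",
            stacklevel=2,
        )
    return 100.0 * (fi - ff) / fi


def nitrogen_balance(intake: float, fecal: float, urinary: float) -> float:
    """Nitrogen retention, g/d = intake - fecal - urinary."""
    if min(intake, fecal, urinary) < 0:
        raise DomainError("nitrogen flows must be nonnegative")
    return intake - fecal - urinary


def diet_de(ge_intake_kj_d: float, fecal_ge_kj_d: float, dm_intake_kg_d: float) -> float:
    """Digestible energy density of the diet, MJ/kg DM."""
    if dm_intake_kg_d <= 0:
        raise DomainError(f"DM intake must be positive, got {dm_intake_kg_d}")
    return kj_to_mj((ge_intake_kj_d - fecal_ge_kj_d) / dm_intake_kg_d)


def diet_me(
    de_mj_kg_dm: float,
    urine_energy_kj_d: float,
    ch4_l_d: float,
    dm_intake_kg_d: float,
) -> float:
    """Metabolizable energy density, MJ/kg DM: DE minus urinary and methane energy."""
    if dm_intake_kg_d <= 0:
        raise DomainError(f"DM intake must be positive, got {dm_intake_kg_d}")
    if urine_energy_kj_d < 0:
        raise DomainError("urine energy must be nonnegative")
    me = de_mj_kg_dm - kj_to_mj((urine_energy_kj_d + methane_energy(ch4_l_d)) / dm_intake_kg_d)
    if me < 0:
        warnings.warn(f"negative ME ({me:.3f} MJ/kg DM)", stacklevel=2)
    return me


def retained_energy(mei: float, thp: float) -> float:
    """Retained energy = ME intake - total heat production (any common basis)."""
    if mei < 0:
        raise DomainError(f"ME intake must be nonnegative, got {mei}")
    return mei - thp


def retained_energy_protein(n_retention_g_d: float) -> float:
    """Energy retained as protein, kJ/d = N retention * 6.25 * 23.86."""
    return n_retention_g_d * CP_PER_N * PROTEIN_ENERGY_KJ_PER_G


def diet_ne(re_kj_d: float, fhp_kj_d: float, dm_intake_kg_d: float) -> float:
    """Net energy density, MJ/kg DM = (RE + FHP)/DM intake."""
    if dm_intake_kg_d <= 0:
        raise DomainError(f"DM intake must be positive, got {dm_intake_kg_d}")
    return kj_to_mj((re_kj_d + fhp_kj_d) / dm_intake_kg_d)


def adjust_thp_for_mei(
    records: Sequence[tuple[float, float]], mei_ref: float = DEFAULT_MEI_REF
) -> list[float]:
    """Covariance-adjust THP to a common reference ME intake.

    ``records`` are (THP, MEI) pairs for the pigs of one collection period, on
    the kJ/kg BW^0.60/d basis. A single least-squares slope b of THP on MEI is
    fitted across the period's pigs (pooled over diets) and each pig's THP is
    moved along it: adjusted_i = THP_i + b*(mei_ref - MEI_i). With all MEI
    identical the slope is undefined and raw values are returned with a warning.
    """
    if len(records) < 3:
        raise DomainError(f"need >= 3 pigs to fit a covariance slope, got {len(records)}")
    thp = np.asarray([r[0] for r in records], dtype=float)
    mei = np.asarray([r[1] for r in records], dtype=float)
    if np.ptp(mei) == 0:
        warnings.warn("all MEI identical; returning raw THP", stacklevel=2)
        return list(thp)
    b = float(np.polyfit(mei, thp, 1)[0])
    return list(thp + b * (mei_ref - mei))


# ---------------------------------------------------------------------------
# Per-pig records and full balance


@dataclass
class AnimalPeriodRecord:
    """One pig in one collection period: intakes, outputs, and gas windows.

    ``intake`` and ``fecal`` map analyte name -> daily flow: GE in kJ/d, the
    rest (DM, OM, N, CP, NDF, ADF) in g/d. ``fed_windows`` holds one
    cumulative GasExchangeWindow per chamber day of the fed state;
    ``fasting_window`` the overnight fasted window.
    """

    pig_id: str
    period: int
    diet_id: str
    BW: float  # kg
    DM_intake: float  # kg/d
    intake: dict[str, float]
    fecal: dict[str, float]
    urine_energy: float  # kJ/d
    urine_N: float  # g/d
    fed_windows: list[GasExchangeWindow] = field(default_factory=list)
    fasting_window: GasExchangeWindow | None = None

    def __post_init__(self) -> None:
        if self.BW <= 0:
            raise ValidationError(f"{self.pig_id}: BW must be positive")
        if self.DM_intake <= 0:
            raise ValidationError(f"{self.pig_id}: DM intake must be positive")
        for analyte, v in self.intake.items():
            if v <= 0:
                raise ValidationError(f"{self.pig_id}: intake of {analyte} must be positive")
        for analyte, v in self.fecal.items():
            if v < 0:
                raise ValidationError(f"{self.pig_id}: fecal {analyte} must be nonnegative")
        if self.urine_energy < 0 or self.urine_N < 0:
            raise ValidationError(f"{self.pig_id}: urinary outputs must be nonnegative")


@dataclass
class EnergyBalanceResult:
    """Per-pig (or diet-mean) energy partition, digestibility, and N balance."""

    pig_id: str
    diet_id: str
    period: int
    BW: float
    DM_intake: float
    attd: dict[str, float]  # % per analyte
    N_retention: float  # g/d
    DE: float  # MJ/kg DM
    ME: float  # MJ/kg DM
    NE: float  # MJ/kg DM
    UE_over_DE: float  # %
    CH4E_over_DE: float  # %
    ME_over_DE: float  # %
    NE_over_ME: float  # %
    MEI: float  # kJ/kg BW^0.60/d
    THP: float  # kJ/kg BW^0.60/d
    FHP: float  # kJ/kg BW^0.60/d
    RE: float  # kJ/kg BW^0.60/d
    REP: float  # kJ/kg BW^0.60/d
    REL: float  # kJ/kg BW^0.60/d
    RQ_fed: float | None
    RQ_fasted: float | None
    adjTHP: float | None = None  # filled by covariance adjustment


def pig_energy_balance(record: AnimalPeriodRecord) -> EnergyBalanceResult:
    """Full energy partition for one pig-period.

    Daily fed-state heat production is computed per chamber day from that
    day's cumulative gas volumes; THP is the mean of the daily values. FHP is
    the fasting window extrapolated to 24 h. Negative retained energy as lipid
    (body-fat mobilization) is permitted and flagged.
    """
    mbw = metabolic_weight(record.BW)
    # digestibility
    attd_pct = {a: attd(record.intake[a], record.fecal.get(a, 0.0)) for a in record.intake}
    # nitrogen balance
    n_ret = nitrogen_balance(record.intake["N"], record.fecal.get("N", 0.0), record.urine_N)
    # energy cascade
    ch4_l_d = float(np.mean([w.CH4 * 24.0 / w.duration for w in record.fed_windows]))
    de = diet_de(record.intake["GE"], record.fecal.get("GE", 0.0), record.DM_intake)
    me = diet_me(de, record.urine_energy, ch4_l_d, record.DM_intake)
    mei_d = me * 1000.0 * record.DM_intake  # kJ/d
    thp_daily = [heat_production(w).HP_daily for w in record.fed_windows]
    thp_d = float(np.mean(thp_daily))
    if record.fasting_window is None:
        raise ValidationError(f"{record.pig_id}: fasting window required for NE")
    fhp_d = extrapolate_fhp(
        record.fasting_window, expected_duration=record.fasting_window.duration
    ).HP_daily
    re_d = retained_energy(mei_d, thp_d)
    rep_d = retained_energy_protein(n_ret)
    rel_d = re_d - rep_d
    if rel_d < 0:
        warnings.warn(
            f"{record.pig_id}: negative retained energy as lipid ({rel_d:.0f} kJ/d)",
            stacklevel=2,
        )
    ne = diet_ne(re_d, fhp_d, record.DM_intake)
    ue_over_de = 100.0 * record.urine_energy / (de * 1000.0 * record.DM_intake)
    ch4e_over_de = 100.0 * methane_energy(ch4_l_d) / (de * 1000.0 * record.DM_intake)
    rq_fed = float(np.mean([respiratory_quotient(w) for w in record.fed_windows]))
    rq_fasted = (
        respiratory_quotient(record.fasting_window) if record.fasting_window.O2 > 0 else None
    )
    return EnergyBalanceResult(
        pig_id=record.pig_id,
        diet_id=record.diet_id,
        period=record.period,
        BW=record.BW,
        DM_intake=record.DM_intake,
        attd=attd_pct,
        N_retention=n_ret,
        DE=de,
        ME=me,
        NE=ne,
        UE_over_DE=ue_over_de,
        CH4E_over_DE=ch4e_over_de,
        ME_over_DE=100.0 * me / de,
        NE_over_ME=100.0 * ne / me,
        MEI=mei_d / mbw,
        THP=thp_d / mbw,
        FHP=fhp_d / mbw,
        RE=re_d / mbw,
        REP=rep_d / mbw,
        REL=rel_d / mbw,
        RQ_fed=rq_fed,
        RQ_fasted=rq_fasted,
    )


def results_to_frame(results: Iterable[EnergyBalanceResult]) -> pd.DataFrame:
    """Flatten EnergyBalanceResult records into a tidy per-pig DataFrame."""
    rows = []
    for r in results:
        row = {
            "pig_id": r.pig_id,
            "diet_id": r.diet_id,
            "period": r.period,
            "BW_kg": r.BW,
            "DMI_kg_d": r.DM_intake,
            "N_retention_g_d": r.N_retention,
            "DE_MJ_kgDM": r.DE,
            "ME_MJ_kgDM": r.ME,
            "NE_MJ_kgDM": r.NE,
            "UE_DE_pct": r.UE_over_DE,
            "CH4E_DE_pct": r.CH4E_over_DE,
            "ME_DE_pct": r.ME_over_DE,
            "NE_ME_pct": r.NE_over_ME,
            "MEI_kJ_mbw_d": r.MEI,
            "THP_kJ_mbw_d": r.THP,
            "adjTHP_kJ_mbw_d": r.adjTHP,
            "FHP_kJ_mbw_d": r.FHP,
            "RE_kJ_mbw_d": r.RE,
            "REP_kJ_mbw_d": r.REP,
            "REL_kJ_mbw_d": r.REL,
            "RQ_fed": r.RQ_fed,
            "RQ_fasted": r.RQ_fasted,
        }
        for analyte, v in r.attd.items():
            row[f"ATTD_{analyte}_pct"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_diet(per_pig: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic diet means of every numeric column (per-pig-first convention)."""
    if per_pig.empty:
        raise DomainError("no per-pig results to aggregate")
    numeric = per_pig.select_dtypes(include=[np.number]).columns.difference(["period"])
    return per_pig.groupby("diet_id", sort=False)[list(numeric)].mean().reset_index()


# ---------------------------------------------------------------------------
# CSV-level driver


_BALANCE_MANDATORY = (
    "pig_id",
    "period",
    "diet_id",
    "BW_kg",
    "DMI_kg_d",
    "GE_intake_kJ_d",
    "fecal_GE_kJ_d",
    "N_intake_g_d",
    "fecal_N_g_d",
    "urine_N_g_d",
    "urine_E_kJ_d",
)
_CHAMBER_MANDATORY = (
    "pig_id",
    "period",
    "diet_id",
    "BW_kg",
    "day",
    "state",
    "O2_L",
    "CO2_L",
    "CH4_L",
    "urine_N_g",
    "duration_h",
)

#: optional analyte columns: intake/fecal pairs in g/d
_ANALYTE_PAIRS = {
    "DM": ("DM_intake_g_d", "fecal_DM_g_d"),
    "OM": ("OM_intake_g_d", "fecal_OM_g_d"),
    "NDF": ("NDF_intake_g_d", "fecal_NDF_g_d"),
    "ADF": ("ADF_intake_g_d", "fecal_ADF_g_d"),
}


def load_records(
    chamber_path: str | Path, balance_path: str | Path
) -> list[AnimalPeriodRecord]:
    """Join ``chamber_records.csv`` and ``balance_records.csv`` into per-pig records."""
    chamber = pd.read_csv(chamber_path)
    balance = pd.read_csv(balance_path)
    for col in _CHAMBER_MANDATORY:
        if col not in chamber.columns:
            raise SchemaError(f"{chamber_path}: missing mandatory column {col!r}")
    for col in _BALANCE_MANDATORY:
        if col not in balance.columns:
            raise SchemaError(f"{balance_path}: missing mandatory column {col!r}")
    records = []
    gas_groups = dict(tuple(chamber.groupby(["pig_id", "period"], sort=False)))
    for _, row in balance.iterrows():
        key = (row["pig_id"], row["period"])
        if key not in gas_groups:
            raise ValidationError(f"no chamber records for pig {key[0]} period {key[1]}")
        gas = gas_groups[key]
        fed = gas[gas["state"] == "fed"]
        fasting = gas[gas["state"] == "fasting"]
        if fed.empty or len(fasting) != 1:
            raise ValidationError(
                f"pig {key[0]} period {key[1]}: need >=1 fed day and exactly 1 fasting window"
            )
        fed_windows = [
            GasExchangeWindow(
                O2=g["O2_L"], CO2=g["CO2_L"], CH4=g["CH4_L"],
                urinary_N=g["urine_N_g"], duration=g["duration_h"], basis_BW=row["BW_kg"],
            )
            for _, g in fed.iterrows()
        ]
        f = fasting.iloc[0]
        fasting_window = GasExchangeWindow(
            O2=f["O2_L"], CO2=f["CO2_L"], CH4=f["CH4_L"],
            urinary_N=f["urine_N_g"], duration=f["duration_h"], basis_BW=row["BW_kg"],
        )
        intake = {"GE": float(row["GE_intake_kJ_d"]), "N": float(row["N_intake_g_d"])}
        fecal = {"GE": float(row["fecal_GE_kJ_d"]), "N": float(row["fecal_N_g_d"])}
        for analyte, (ic, fc) in _ANALYTE_PAIRS.items():
            if ic in balance.columns and fc in balance.columns:
                intake[analyte] = float(row[ic])
                fecal[analyte] = float(row[fc])
        records.append(
            AnimalPeriodRecord(
                pig_id=str(row["pig_id"]),
                period=int(row["period"]),
                diet_id=str(row["diet_id"]),
                BW=float(row["BW_kg"]),
                DM_intake=float(row["DMI_kg_d"]),
                intake=intake,
                fecal=fecal,
                urine_energy=float(row["urine_E_kJ_d"]),
                urine_N=float(row["urine_N_g_d"]),
                fed_windows=fed_windows,
                fasting_window=fasting_window,
            )
        )
    return records


def analyze_experiment(
    records: Sequence[AnimalPeriodRecord], mei_ref: float = DEFAULT_MEI_REF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the balance for every pig, adjust THP within periods, aggregate by diet.

    Returns (per_pig, per_diet) DataFrames. The covariance adjustment is
    applied within each collection period across that period's pigs; periods
    with fewer than 3 pigs keep raw THP.
    """
    results = [pig_energy_balance(r) for r in records]
    by_period: dict[int, list[EnergyBalanceResult]] = {}
    for r in results:
        by_period.setdefault(r.period, []).append(r)
    for period_results in by_period.values():
        if len(period_results) >= 3:
            adjusted = adjust_thp_for_mei(
                [(r.THP, r.MEI) for r in period_results], mei_ref=mei_ref
            )
            for r, a in zip(period_results, adjusted):
                r.adjTHP = a
        else:
            for r in period_results:
                r.adjTHP = r.THP
    per_pig = results_to_frame(results)
    return per_pig, aggregate_by_diet(per_pig)
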