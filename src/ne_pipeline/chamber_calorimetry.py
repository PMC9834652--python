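"""Heat production from respiration-chamber gas exchange.

Indirect calorimetry estimates heat production (HP) from oxygen consumption,
carbon dioxide and methane production, and urinary nitrogen excretion via the
Brouwer factorial equation:

    HP (kJ) = 16.18*O2 (L) + 5.02*CO2 (L) - 2.17*CH4 (L) - 5.99*urinary N (g)

Fasting heat production (FHP) is measured over a short overnight window late
in the fasting day and extrapolated linearly to 24 h so it shares a time basis
with total heat production. All per-size quantities are scaled by metabolic
body weight BW^0.60.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, ValidationError
from .units import metabolic_weight

#: Brouwer coefficients, kJ per L of gas or per g of urinary N.
BROUWER_O2 = 16.18
BROUWER_CO2 = 5.02
BROUWER_CH4 = 2.17
BROUWER_URINARY_N = 5.99

#: Energy lost as methane, kJ per L of CH4.
METHANE_ENERGY_KJ_PER_L = 39.5

#: Default length of the overnight fasting HP window, hours.
DEFAULT_FASTING_WINDOW_H = 8.0


@dataclass(frozen=True)
class GasExchangeWindow:
    """Cumulative gas exchange and urinary N over one measurement window."""

    O2: float  # L consumed
    CO2: float  # L produced
    CH4: float = 0.0  # L produced
    urinary_N: float = 0.0  # g excreted over the window
    duration: float = 24.0  # hours
    basis_BW: float | None = None  # kg, for metabolic-weight scaling

    def __post_init__(self) -> None:
        for name in ("O2", "CO2", "CH4", "urinary_N"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.duration <= 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        if self.basis_BW is not None and self.basis_BW <= 0:
            raise ValidationError(f"basis_BW must be positive, got {self.basis_BW}")


@dataclass(frozen=True)
class HeatProductionResult:
    """Heat production over a window and its daily / metabolic-weight scalings."""

    HP: float  # kJ over the window
    HP_daily: float  # kJ/d
    HP_metabolic: float | None  # kJ/kg BW^0.60/d, None if no BW given
    RQ: float | None  # CO2/O2, None if O2 == 0


def brouwer_hp(window: GasExchangeWindow) -> float:
    """Heat production over the window, kJ, by the Brouwer equation."""
    return (
        BROUWER_O2 * window.O2
        + BROUWER_CO2 * window.CO2
        - BROUWER_CH4 * window.CH4
        - BROUWER_URINARY_N * window.urinary_N
    )


def methane_energy(ch4_litres: float) -> float:
    """Energy lost as methane, kJ, at 39.5 kJ/L."""
    if ch4_litres < 0:
        raise DomainError(f"CH4 volume must be nonnegative, got {ch4_litres}")
    return METHANE_ENERGY_KJ_PER_L * ch4_litres


def respiratory_quotient(window: GasExchangeWindow) -> float:
    """RQ = CO2 produced / O2 consumed."""
    if window.O2 <= 0:
        raise DomainError("respiratory quotient undefined for O2 <= 0")
    return window.CO2 / window.O2


def heat_production(window: GasExchangeWindow) -> HeatProductionResult:
    """Brouwer HP with daily extrapolation and metabolic-weight scaling."""
    hp = brouwer_hp(window)
    hp_daily = hp * 24.0 / window.duration
    hp_metab = (
        hp_daily / metabolic_weight(window.basis_BW) if window.basis_BW is not None else None
    )
    rq = window.CO2 / window.O2 if window.O2 > 0 else None
    return HeatProductionResult(HP=hp, HP_daily=hp_daily, HP_metabolic=hp_metab, RQ=rq)


def extrapolate_fhp(
    fasting_window: GasExchangeWindow,
    expected_duration: float = DEFAULT_FASTING_WINDOW_H,
) -> HeatProductionResult:
    """Fasting heat production extrapolated from the overnight window to 24 h.

    The window's urinary N must already be the amount excreted during the
    window itself (prorate a longer fasting collection by time before calling).
    """
    if fasting_window.duration <= 0:
        raise DomainError("fasting window duration must be positive")
    if abs(fasting_window.duration - expected_duration) > 1e-9:
        raise DomainError(
            f"fasting window lasts {fasting_window.duration} h, expected "
            f"{expected_duration} h (pass expected_duration to override)"
        )
    return heat_production(fasting_window)


def invert_brouwer(
    hp_kj: float, rq: float, ch4_litres: float = 0.0, urinary_n_g: float = 0.0
) -> tuple[float, float]:
    """Gas volumes (O2, CO2 in L) that yield ``hp_kj`` at respiratory quotient ``rq``.

    Solves the Brouwer equation for O2 given CO2 = RQ*O2:
    O2 = (HP + 2.17*CH4 + 5.99*N) / (16.18 + 5.02*RQ).
    """
    if hp_kj < 0:
        raise DomainError(f"heat production must be nonnegative, got {hp_kj}")
    if rq <= 0:
        raise DomainError(f"RQ must be positive, got {rq}")
    o2 = (hp_kj + BROUWER_CH4 * ch4_litres + BROUWER_URINARY_N * urinary_n_g) / (
        BROUWER_O2 + BROUWER_CO2 * rq
    )
    return o2, rq * o2
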