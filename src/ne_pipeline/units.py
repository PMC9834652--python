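"""Unit conventions and conversions.

Internal policy: energies are carried in kJ everywhere; MJ appears only at
report boundaries (diet and ingredient energy densities, MJ/kg DM). Energy
flows across pigs of different size are scaled by metabolic body weight,
BW^0.60, the exponent used throughout for growing pigs.
"""

KJ_PER_MJ = 1000.0

#: Exponent of metabolic body weight used to scale energy flows (kg^0.60).
METABOLIC_BW_EXPONENT = 0.60

#: Energy density of body protein, kJ per g of protein retained.
PROTEIN_ENERGY_KJ_PER_G = 23.86

#: Conventional crude-protein-to-nitrogen ratio.
CP_PER_N = 6.25


def kj_to_mj(x: float) -> float:
    return x / KJ_PER_MJ


def mj_to_kj(x: float) -> float:
    return x * KJ_PER_MJ


def metabolic_weight(bw_kg: float) -> float:
    """kg of metabolic body weight, BW^0.60."""
    if bw_kg <= 0:
        raise ValueError(f"body weight must be positive, got {bw_kg}")
    return bw_kg ** METABOLIC_BW_EXPONENT
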