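"""Unit conventions and conversion constants.

Internally the hydraulics code works in a self-consistent micro-scale system
in which the Hagen--Poiseuille law needs no conversion factors:

* length      : μm
* viscosity   : mPa·s
* pressure    : mPa
* flow rate   : μm³·s⁻¹
* resistance  : mPa·s·μm⁻³   (so Δp[mPa] = Q[μm³/s] · R[mPa·s·μm⁻³])

Interfaces accept and report the bench units used for pressure-driven
microfluidics: mbar for applied pressures (1 mbar = 100 Pa) and μl·min⁻¹ for
flow rates.
"""

#: 1 mbar = 100 Pa = 1e5 mPa
MBAR_TO_MPA = 1.0e5

#: 1 μl·min⁻¹ = 1e9 μm³ / 60 s
ULMIN_TO_UM3_PER_S = 1.0e9 / 60.0

#: 1 m²·s⁻¹ = 1e12 μm²·s⁻¹ (molecular diffusivities are quoted in m²/s)
M2S_TO_UM2S = 1.0e12


def mbar_to_mpa(p: float) -> float:
    return p * MBAR_TO_MPA


def mpa_to_mbar(p: float) -> float:
    return p / MBAR_TO_MPA


def ulmin_to_um3s(q: float) -> float:
    return q * ULMIN_TO_UM3_PER_S


def um3s_to_ulmin(q: float) -> float:
    return q / ULMIN_TO_UM3_PER_S
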