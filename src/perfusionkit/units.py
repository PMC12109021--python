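"""Unit conversion constants and helpers.

Internally the package works in SI (m, kg, s, Pa).  I/O follows the bench
conventions of interstitial-flow work: drive pressure in psi, volumetric
flow in μL/s, velocity in μm/s, distances in the image plane in μm.
"""

PSI_TO_PA = 6894.757
"""Exact conversion used throughout: 1 psi = 6894.757 Pa."""

G_STANDARD = 9.80665
"""Standard gravity (m/s²) used for hydrostatic heads."""

M3_PER_S_TO_UL_PER_S = 1e9
M_PER_S_TO_UM_PER_S = 1e6


def psi_to_pa(psi: float) -> float:
    return psi * PSI_TO_PA


def pa_to_psi(pa: float) -> float:
    return pa / PSI_TO_PA


def m3s_to_uls(v: float) -> float:
    """m³/s → μL/s."""
    return v * M3_PER_S_TO_UL_PER_S


def uls_to_m3s(v: float) -> float:
    """μL/s → m³/s."""
    return v / M3_PER_S_TO_UL_PER_S


def ms_to_ums(u: float) -> float:
    """m/s → μm/s."""
    return u * M_PER_S_TO_UM_PER_S


def ums_to_ms(u: float) -> float:
    """μm/s → m/s."""
    return u / M_PER_S_TO_UM_PER_S
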