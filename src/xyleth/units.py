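"""Unit conversions used at the I/O boundary.

Internally the model works in mg, L and h throughout; these helpers convert
between the reporting units of the monitored channels (ppm in air, µmol/L in
blood, g metabolite per g creatinine in urine) and the internal units.
"""

from __future__ import annotations

import numpy as np

#: Molar volume of an ideal gas at 25 degC and 1 atm (L/mol).
MOLAR_VOLUME_25C = 24.45

#: Molar mass of creatinine (mg/mmol), used for the per-gram-creatinine scale.
MW_CREATININE = 113.12

#: Density of absolute ethanol (g/mL) at room temperature.
ETHANOL_DENSITY = 0.789


def ppm_to_mg_per_l(ppm, molecular_mass: float):
    """Convert a gas-phase concentration from ppm (v/v) to mg/L at 25 degC."""
    ppm = np.asarray(ppm, dtype=float)
    if np.any(ppm < 0):
        raise ValueError("ppm must be non-negative")
    out = ppm * molecular_mass / (MOLAR_VOLUME_25C * 1000.0)
    return float(out) if out.ndim == 0 else out


def mg_per_l_to_ppm(mg_per_l, molecular_mass: float):
    """Inverse of :func:`ppm_to_mg_per_l`."""
    c = np.asarray(mg_per_l, dtype=float)
    out = c * (MOLAR_VOLUME_25C * 1000.0) / molecular_mass
    return float(out) if out.ndim == 0 else out


def mmol_per_l_to_mg_per_l(mmol_per_l, molecular_mass: float):
    """Convert mmol/L to mg/L (Michaelis constants printed in mM)."""
    return np.asarray(mmol_per_l, dtype=float) * molecular_mass


def umol_per_l_to_mg_per_l(umol_per_l, molecular_mass: float):
    """Convert µmol/L to mg/L (in-vitro constants printed in µM)."""
    return np.asarray(umol_per_l, dtype=float) * molecular_mass / 1000.0


def mg_per_l_to_umol_per_l(mg_per_l, molecular_mass: float):
    return np.asarray(mg_per_l, dtype=float) * 1000.0 / molecular_mass


def halflife_from_ke(ke):
    """Half-life (h) of a first-order process with rate constant ``ke`` (1/h)."""
    ke = np.asarray(ke, dtype=float)
    if np.any(ke <= 0):
        raise ValueError("rate constant must be positive")
    out = np.log(2.0) / ke
    return float(out) if out.ndim == 0 else out


def ke_from_halflife(t_half):
    """Rate constant (1/h) from a half-life (h); self-inverse with the above."""
    return halflife_from_ke(t_half)


def bmi(body_mass_kg, height_m):
    """Body mass index, kg/m^2."""
    m = np.asarray(body_mass_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(m <= 0) or np.any(h <= 0):
        raise ValueError("body mass and height must be positive")
    out = m / h**2
    return float(out) if out.ndim == 0 else out
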