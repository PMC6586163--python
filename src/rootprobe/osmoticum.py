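"""Osmoticum bookkeeping: PEG-8000 water potential, van't Hoff osmotic pressure.

High-molecular-weight PEG 8000 lowers the water potential of a hydroponic
medium without being taken up by roots, which makes it the standard osmoticum
for imposing a defined, purely osmotic water deficit.  This module converts
between the three descriptions of the medium used throughout the analysis:

* PEG-8000 mass fraction  ->  water potential ψ (MPa, ≤ 0), via the empirical
  Michel calibration polynomial for PEG 8000;
* osmolality (mOsmol kg⁻¹)  ->  osmotic pressure π = R·T·Cs (MPa, ≥ 0), the
  ideal van't Hoff relation;
* molar concentration of a dissociating salt  ->  ideal osmolality
  (e.g. 30 mM NaCl -> 60 mOsmol kg⁻¹).

Sign convention: water *potential* ψ is reported as a negative number in MPa,
osmotic *pressure* π as a positive number in MPa.  The two are never mixed
silently.

The Michel polynomial is evaluated with the PEG concentration expressed as the
w/w mass fraction of the **total** solution; under that convention the standard
stress levels 17.5 %, 25.4 % and 31.6 % w/w map to −0.4, −0.8 and −1.2 MPa at
23 °C (the daytime growth temperature used as the default here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE_C",
    "OsmoticumSpec",
    "peg8000_water_potential",
    "peg8000_mass_fraction",
    "vant_hoff_osmotic_pressure",
    "ideal_osmolality",
]

#: Universal gas constant, J mol⁻¹ K⁻¹.
GAS_CONSTANT = 8.314

#: Daytime growth-chamber temperature, °C (day:night = 23:20).
DEFAULT_TEMPERATURE_C = 23.0

#: Calibration range of the Michel PEG-8000 polynomial (w/w fraction).
_PEG_FRACTION_MAX = 0.45

_ZERO_C_IN_K = 273.15


@dataclass(frozen=True)
class OsmoticumSpec:
    """Composition of the bathing medium.

    Parameters
    ----------
    peg_mass_fraction :
        PEG-8000 mass fraction of the total solution (w/w), in [0, 0.45].
    temperature :
        Solution temperature, °C, in [0, 40].
    background_osmolality :
        Osmolality of the salt background (e.g. half-strength Hoagland
        ≈ 20 mOsmol kg⁻¹), mOsmol kg⁻¹, ≥ 0.
    """

    peg_mass_fraction: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE_C
    background_osmolality: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peg_mass_fraction <= _PEG_FRACTION_MAX:
            raise ValueError(
                f"peg_mass_fraction must lie in [0, {_PEG_FRACTION_MAX}], "
                f"got {self.peg_mass_fraction}"
            )
        if not 0.0 <= self.temperature <= 40.0:
            raise ValueError(f"temperature must lie in [0, 40] °C, got {self.temperature}")
        if self.background_osmolality < 0:
            raise ValueError("background_osmolality must be non-negative")

    def water_potential(self) -> float:
        """Total ψ of the medium: PEG contribution + van't Hoff of the background."""
        psi_peg = peg8000_water_potential(self.peg_mass_fraction, self.temperature)
        psi_salt = -vant_hoff_osmotic_pressure(self.background_osmolality, self.temperature)
        return psi_peg + psi_salt


def peg8000_water_potential(mass_fraction: float, temperature: float = DEFAULT_TEMPERATURE_C) -> float:
    """Water potential of a PEG-8000 solution, MPa (≤ 0).

    Empirical Michel calibration for PEG 8000,

        ψ [bar] = 1.29·c²·T − 140·c² − 4.0·c,

    with ``c`` the PEG mass fraction of the total solution (w/w) and ``T`` in
    °C; the result is converted to MPa.  Strictly decreasing in ``c`` over the
    calibration range at any admissible temperature, and ψ(0, T) = 0.

    Parameters
    ----------
    mass_fraction :
        PEG-8000 w/w fraction of total solution, in [0, 0.45].
    temperature :
        °C, in [5, 40].

    Returns
    -------
    float
        ψ in MPa (non-positive).
    """
    if not 0.0 <= mass_fraction <= _PEG_FRACTION_MAX:
        raise ValueError(
            f"PEG-8000 mass fraction {mass_fraction} outside the calibration "
            f"range [0, {_PEG_FRACTION_MAX}] (w/w fraction of total solution)"
        )
    if not 5.0 <= temperature <= 40.0:
        raise ValueError(f"temperature must lie in [5, 40] °C, got {temperature}")
    c = mass_fraction
    psi_bar = 1.29 * c * c * temperature - 140.0 * c * c - 4.0 * c
    return 0.1 * psi_bar  # bar -> MPa


def peg8000_mass_fraction(
    target_psi: float,
    temperature: float = DEFAULT_TEMPERATURE_C,
    tol: float = 1e-10,
) -> float:
    """Invert the Michel calibration: mass fraction giving water potential ψ.

    Bisection on the strictly monotone calibration curve.  ``target_psi`` must
    be in MPa and within the range attainable over [0, 0.45] w/w at the given
    temperature.
    """
    if target_psi > 0:
        raise ValueError("water potential must be ≤ 0 MPa")
    lo, hi = 0.0, _PEG_FRACTION_MAX
    psi_hi = peg8000_water_potential(hi, temperature)
    if target_psi < psi_hi:
        raise ValueError(
            f"target ψ = {target_psi} MPa below the calibration range "
            f"(ψ({hi:g} w/w, {temperature:g} °C) = {psi_hi:.3f} MPa)"
        )
    # ψ decreases with the fraction, so bisect on sign of ψ(mid) − target.
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if peg8000_water_potential(mid, temperature) > target_psi:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def vant_hoff_osmotic_pressure(osmolality: float, temperature: float = DEFAULT_TEMPERATURE_C) -> float:
    """Ideal (van't Hoff) osmotic pressure π = R·T·Cs, MPa.

    ``osmolality`` in mOsmol kg⁻¹ is treated as an ideal dilute concentration
    (1 mOsmol kg⁻¹ ≙ 1 mol m⁻³); ``temperature`` in °C is converted to K.
    Linear in osmolality; π(0) = 0.
    """
    if osmolality < 0:
        raise ValueError("osmolality must be non-negative")
    conc_mol_m3 = float(osmolality)  # 1 mOsmol kg⁻¹ ≈ 1 mol m⁻³ for dilute aqueous media
    pressure_pa = GAS_CONSTANT * (temperature + _ZERO_C_IN_K) * conc_mol_m3
    return pressure_pa * 1e-6  # Pa -> MPa


def ideal_osmolality(molar_concentration: float, dissociation_number: int = 1) -> float:
    """Ideal osmolality of a fully dissociating solute, mOsmol kg⁻¹.

    ``molar_concentration`` in mM times the number of osmotically active
    particles per formula unit (2 for NaCl), in the dilute ideal limit where
    mM ≈ mmol kg⁻¹.
    """
    if molar_concentration < 0:
        raise ValueError("molar concentration must be non-negative")
    if int(dissociation_number) != dissociation_number or dissociation_number < 1:
        raise ValueError("dissociation_number must be a positive integer")
    return float(molar_concentration) * int(dissociation_number)
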