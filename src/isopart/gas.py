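"""Raw gas measurements → concentrations and ratios.

Two instrument streams feed the partitioning stage:

* **MIMS** (membrane inlet mass spectrometry) ion currents at m/z 32 (O₂),
  40 (Ar), 44 (¹²CO₂) and 45 (¹³CO₂), recorded daily in unreplicated
  monitoring bottles.  Ar is biologically inert, so expressing every channel
  as a ratio to Ar removes instrument drift; the ratios are treated as
  uncalibrated trend data.
* **Headspace-equilibrated dissolved CO₂**: a water sample equilibrates with
  a headspace, the headspace CO₂ mixing ratio (ppm) and δ¹³C are measured,
  and the original dissolved concentration is reconstructed from the
  gas/water partitioning (ideal gas + temperature-dependent solubility).

The solubility function is the Weiss (1974)-type polynomial at zero
salinity; the constant set name is carried in outputs so the choice is
auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .isotopes import VPDB, IsotopeStandard, IsotopeValue, ATOM_FRACTION

__all__ = [
    "IonCurrentRecord",
    "GasRatioSeries",
    "DissolvedCO2",
    "ratios_from_currents",
    "co2_solubility",
    "dissolved_co2_from_headspace",
    "delta_from_45_44",
    "subtract_baseline",
    "SOLUBILITY_CONSTANTS",
]

#: Gas constant in l·atm·mol⁻¹·K⁻¹.
R_GAS_L_ATM = 0.082057366

#: Weiss-type ln K0 coefficients (freshwater, K0 in mol l⁻¹ atm⁻¹):
#: ln K0 = a1 + a2·(100/T) + a3·ln(T/100), T in kelvin.
SOLUBILITY_CONSTANTS = {
    "name": "Weiss-1974-freshwater",
    "a1": -58.0931,
    "a2": 90.5069,
    "a3": 22.2940,
    "valid_celsius": (-1.0, 40.0),
}

_REQUIRED_MZ = (32, 40, 44, 45)


@dataclass(frozen=True)
class IonCurrentRecord:
    """One day of MIMS monitoring for one bottle (arbitrary current units)."""

    day: int
    treatment_id: str
    currents: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        for mz in _REQUIRED_MZ:
            if mz not in self.currents:
                raise KeyError(f"missing m/z channel {mz} in MIMS record")
            if not self.currents[mz] > 0:
                raise ValueError(f"ion current at m/z {mz} must be > 0")


@dataclass(frozen=True)
class GasRatioSeries:
    """Argon-normalised gas ratios for one monitoring day."""

    day: int
    treatment_id: str
    o2_ar: float
    co2_12_ar: float
    co2_13_ar: float
    r13_co2: float


@dataclass(frozen=True)
class DissolvedCO2:
    """A replicated dissolved-CO₂ observation (µmol C l⁻¹ plus δ¹³C)."""

    conc: float
    delta13: IsotopeValue
    temperature: float = 17.0
    replicate: int = 0
    treatment_id: str = ""
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"dissolved CO2 concentration must be >= 0, got {self.conc}")


def ratios_from_currents(rec: IonCurrentRecord) -> GasRatioSeries:
    """Express MIMS ion currents as ratios to the inert Ar channel.

    No calibration is applied: ratios to Ar are relative trend data.  The
    r13 channel ratio is current(45)/current(44).
    """
    ar = rec.currents[40]
    return GasRatioSeries(
        day=rec.day,
        treatment_id=rec.treatment_id,
        o2_ar=rec.currents[32] / ar,
        co2_12_ar=rec.currents[44] / ar,
        co2_13_ar=rec.currents[45] / ar,
        r13_co2=rec.currents[45] / rec.currents[44],
    )


def co2_solubility(temperature_c: float) -> float:
    """CO₂ solubility K₀(T) in mol l⁻¹ atm⁻¹ (zero salinity).

    Raises outside the polynomial's stated validity range.
    """
    lo, hi = SOLUBILITY_CONSTANTS["valid_celsius"]
    if not lo <= temperature_c <= hi:
        raise ValueError(
            f"temperature {temperature_c} degC outside solubility validity "
            f"range [{lo}, {hi}]"
        )
    t_k = temperature_c + 273.15
    ln_k0 = (
        SOLUBILITY_CONSTANTS["a1"]
        + SOLUBILITY_CONSTANTS["a2"] * (100.0 / t_k)
        + SOLUBILITY_CONSTANTS["a3"] * math.log(t_k / 100.0)
    )
    return math.exp(ln_k0)


def dissolved_co2_from_headspace(
    ppm: float,
    temperature_c: float,
    pressure_atm: float = 1.0,
    headspace_vol_ml: float = 5.0,
    water_vol_ml: float = 12.0,
) -> float:
    """Original dissolved CO₂ (µmol C l⁻¹) from an equilibrated headspace.

    After equilibration the total CO₂ splits between the gas phase (ideal
    gas at the measured mixing ratio) and the water phase (Henry's law with
    K₀(T)); all of it originated in the water sample, so

        C₀ = (n_gas + n_aq) / V_water.

    The result is linear in ppm; with zero headspace it reduces to the
    direct Henry's-law concentration K₀·pCO₂.
    """
    if not 0.0 <= ppm < 1.0e6:
        raise ValueError(f"ppm must lie in [0, 1e6), got {ppm}")
    if water_vol_ml <= 0 or headspace_vol_ml < 0 or pressure_atm <= 0:
        raise ValueError("volumes and pressure must be positive")
    p_co2_atm = ppm * 1.0e-6 * pressure_atm
    k0 = co2_solubility(temperature_c)  # mol / l / atm
    v_gas_l = headspace_vol_ml / 1000.0
    v_water_l = water_vol_ml / 1000.0
    n_gas_mol = p_co2_atm * v_gas_l / (R_GAS_L_ATM * (temperature_c + 273.15))
    n_aq_mol = k0 * p_co2_atm * v_water_l
    return (n_gas_mol + n_aq_mol) / v_water_l * 1.0e6  # µmol / l


def delta_from_45_44(r45_44: float, standard: IsotopeStandard = VPDB) -> IsotopeValue:
    """Trend-level δ¹³C from the MIMS 45/44 channel ratio.

    The 45/44 current ratio is treated directly as ¹³C/¹²C, with no ¹⁷O
    (Craig) correction: against a strongly ¹³C-enriched label the ¹²C¹⁷O¹⁶O
    contribution at m/z 45 is negligible.  For natural-abundance work this
    approximation overestimates ¹³C slightly.
    """
    if not r45_44 > 0:
        raise ValueError(f"45/44 ratio must be > 0, got {r45_44}")
    return IsotopeValue((r45_44 / standard.r13 - 1.0) * 1000.0, standard=standard)


def subtract_baseline(final: DissolvedCO2, initial: DissolvedCO2) -> DissolvedCO2:
    """Net CO₂ production with an isotope-aware baseline subtraction.

    Subtracting the initial (pre-incubation) dissolved CO₂ must be done in
    isotopologue space, not in δ-space: the net ¹³C and ¹²C amounts are the
    differences of the respective totals, and the net signature follows.
    This removes a constant background (e.g. air-equilibrated water CO₂)
    exactly, whatever its signature.
    """
    c_f, c_i = final.conc, initial.conc
    net = c_f - c_i
    if net < 0:
        raise ValueError(
            f"final concentration {c_f} below baseline {c_i}; no net production"
        )
    f13_f = final.delta13.as_atom_fraction()
    f13_i = initial.delta13.as_atom_fraction()
    n13_net = c_f * f13_f - c_i * f13_i
    if net == 0:
        raise ValueError("zero net production; net signature undefined")
    f13_net = n13_net / net
    if not 0.0 < f13_net < 1.0:
        raise ValueError(
            f"net atom fraction {f13_net:.4g} outside (0,1); inconsistent baseline"
        )
    return DissolvedCO2(
        conc=net,
        delta13=IsotopeValue(f13_net, ATOM_FRACTION, final.delta13.standard),
        temperature=final.temperature,
        replicate=final.replicate,
        treatment_id=final.treatment_id,
        day=final.day,
    )
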