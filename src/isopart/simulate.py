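"""Mechanistic incubation simulator with exact two-source ground truth.

The simulator emulates a bottle incubation in which two isotopically
distinct organic-matter pools degrade under a microbial community:

* a **bioavailable pool** (daphnia carcasses, near natural ¹³C abundance)
  decaying first-order at rate ``k_d``;
* a **persistent pool** (¹³C-labelled leaf lignocellulose, ~10 atom% ¹³C)
  decaying at ``k_l`` times a biomass-driven Monod multiplier
  ``1 + p·B/(B + K)`` — the priming interaction.  ``p = 0`` gives a purely
  additive system; ``p > 0`` gives bounded, saturating stimulation of leaf
  decay by the biomass grown largely on the bioavailable pool.

Uptake is split by a growth yield ``y`` into microbial biomass and respired
CO₂; biomass pays a maintenance respiration ``m·B``.  Biomass and the
cumulative CO₂ are tracked as *per-source sub-pools* (daphnia-derived vs
leaf-derived carbon), with no kinetic isotope fractionation, so every carbon
atom in the bottle is attributable to exactly one source at all times and
both ¹²C and ¹³C are conserved to machine precision.  This exact ground
truth (:class:`SimTruth`) is the oracle for parameter-recovery tests of the
whole analysis pipeline.

:func:`emit_measurements` turns a truth run into the measurement files a
real study would produce (dissolved CO₂ + δ¹³C, POC, DOC, PLFA, MIMS ion
currents, design table), with seeded instrument noise: Gaussian δ noise
(default sd 0.2 ‰, the stated accuracy of the isotope-ratio measurement)
and multiplicative lognormal concentration noise (default CV 5%).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .isotopes import (
    ATOM_FRACTION,
    Endmembers,
    IsotopeValue,
    atom_fraction_to_delta,
    delta_to_atom_fraction,
)
from .partition import Treatment, carbon_molar_mass

__all__ = [
    "SimConfig",
    "SimTruth",
    "StudyData",
    "simulate_incubation",
    "emit_measurements",
    "scenario_presets",
    "run_study",
    "endmembers_from_config",
    "F13_DAPHNIA_DEFAULT",
]

#: Default daphnia-carcass signature: δ¹³C = −25 ‰ (typical fresh biomass),
#: as an atom fraction.
F13_DAPHNIA_DEFAULT = float(delta_to_atom_fraction(-25.0))

#: Air-equilibrated background dissolved CO₂ signature (δ¹³C = −10 ‰).
F13_BACKGROUND_DEFAULT = float(delta_to_atom_fraction(-10.0))

#: PLFA emission: within-group compound weights (fractions of the group
#: total), eukaryotic vs bacterial.
_EUK_WEIGHTS = {"18:2ω6,9": 0.6, "18:1ω9t/7c": 0.4}
_BACT_WEIGHTS = {
    "i15:0": 0.30,
    "a15:0": 0.20,
    "cy-17:0": 0.15,
    "16:1ω9": 0.20,
    "18:1ω9c": 0.15,
}


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters (units in comments; defaults = study conditions).

    Decay/priming parameters describe the *complex* community; the bacterial
    community presets lower ``k_l`` and ``priming_p`` (less access to
    lignocellulose, weaker stimulation).
    """

    duration_days: float = 11.0     # incubation length
    dt: float = 0.05                # integrator step, days
    k_d: float = 0.25               # daphnia-pool decay, d⁻¹
    k_l: float = 0.02               # leaf-pool base decay, d⁻¹
    priming_p: float = 2.0          # priming amplitude, unitless ≥ 0
    half_sat_b: float = 20.0        # biomass half-saturation, µmol C l⁻¹
    yield_y: float = 0.30           # growth yield (fraction of uptake)
    maintenance_m: float = 0.05     # maintenance respiration, d⁻¹
    f13_d: float = F13_DAPHNIA_DEFAULT  # daphnia atom fraction ¹³C
    f13_l: float = 0.10             # leaf atom fraction ¹³C (~10 atom%)
    c_frac_d: float = 0.45          # carbon content of daphnia dry mass
    c_frac_l: float = 0.45          # carbon content of leaf dry mass
    doc_frac: float = 0.08          # daphnia carbon initially leached as DOC
    k_doc: float = 1.0              # DOC consumption rate, d⁻¹
    b0_umol: float = 0.0            # initial microbial biomass, µmol C l⁻¹
    co2_background_umol: float = 10.0   # constant dissolved-CO₂ background
    f13_background: float = F13_BACKGROUND_DEFAULT
    temperature_c: float = 17.0     # incubation temperature (16–18 °C band)
    fractionation_alpha: float = 1.0  # kinetic fractionation hook (1 = none)
    # measurement-noise model
    delta_sd_permil: float = 0.2    # IRMS accuracy, ‰
    conc_cv: float = 0.05           # multiplicative concentration noise
    n_replicates: int = 4
    seed: int = 0
    # emission constants
    o2_init_umol: float = 300.0
    ar_umol: float = 15.0
    mims_gain: float = 1.0e-12      # ion current per µmol l⁻¹
    plfa_euk_per_mg_daphnia: float = 400.0   # ng l⁻¹ per mg l⁻¹ carcass
    plfa_bact_per_mg_daphnia: float = 150.0  # carcass-attached community
    plfa_per_umol_biomass: float = 30.0      # ng PLFA per µmol biomass C
    plfa_euk_growth_frac_complex: float = 0.15
    plfa_min_conc_for_delta: float = 5.0     # ng l⁻¹; below → δ unmeasurable

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        n = self.duration_days / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt must divide duration_days")
        if not 0.0 <= self.yield_y < 1.0:
            raise ValueError("yield_y must lie in [0, 1)")
        for name in ("k_d", "k_l", "priming_p", "maintenance_m", "k_doc",
                     "half_sat_b", "b0_umol", "co2_background_umol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("f13_d", "f13_l", "f13_background"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.doc_frac < 1.0:
            raise ValueError("doc_frac must lie in [0, 1)")
        if self.fractionation_alpha != 1.0:
            raise NotImplementedError(
                "kinetic isotope fractionation is a config hook only; "
                "the mixing model assumes alpha = 1"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config, overriding defaults with keys from a YAML file."""
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        unknown = set(overrides) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown SimConfig fields in YAML: {sorted(unknown)}")
        return cls(**overrides)


def endmembers_from_config(cfg: SimConfig) -> Endmembers:
    """The true source signatures of a simulated study, as Endmembers."""
    return Endmembers(
        source_a=IsotopeValue(cfg.f13_d, ATOM_FRACTION),
        source_b=IsotopeValue(cfg.f13_l, ATOM_FRACTION),
    )


@dataclass(frozen=True)
class SimTruth:
    """Exact state trajectory of one simulated bottle (daily resolution).

    All pools in µmol C l⁻¹.  ``co2_daphnia``/``co2_leaf`` are *cumulative*
    respired CO₂ per source; ``ie_true_percent`` compares total final CO₂
    with an additive twin run (``priming_p = 0``), when defined.
    """

    treatment: Treatment
    config: SimConfig
    days: np.ndarray
    c_daphnia: np.ndarray
    c_leaf: np.ndarray
    doc_daphnia: np.ndarray
    b_daphnia: np.ndarray
    b_leaf: np.ndarray
    co2_daphnia: np.ndarray
    co2_leaf: np.ndarray
    ie_true_percent: Optional[float] = None

    # -- derived views ------------------------------------------------------
    @property
    def co2_total(self) -> np.ndarray:
        return self.co2_daphnia + self.co2_leaf

    @property
    def biomass(self) -> np.ndarray:
        return self.b_daphnia + self.b_leaf

    @property
    def f_daphnia_co2(self) -> float:
        """True cumulative daphnia share of respired carbon at the final day."""
        tot = self.co2_total[-1]
        if tot == 0:
            raise ValueError("no CO2 produced; source split undefined")
        return float(self.co2_daphnia[-1] / tot)

    def co2_atom_fraction(self) -> np.ndarray:
        """Atom fraction of cumulative produced CO₂ (excluding background)."""
        cfg = self.config
        tot = self.co2_total
        n13 = cfg.f13_d * self.co2_daphnia + cfg.f13_l * self.co2_leaf
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, n13 / np.where(tot > 0, tot, 1.0), np.nan)

    def dissolved_co2(self) -> tuple[np.ndarray, np.ndarray]:
        """(concentration µmol l⁻¹, atom fraction) of total dissolved CO₂,
        production plus the constant air-equilibrated background."""
        cfg = self.config
        conc = cfg.co2_background_umol + self.co2_total
        n13 = (
            cfg.f13_background * cfg.co2_background_umol
            + cfg.f13_d * self.co2_daphnia
            + cfg.f13_l * self.co2_leaf
        )
        return conc, n13 / conc

    def poc_umol(self) -> np.ndarray:
        """Particulate carbon: remaining substrate pools plus biomass."""
        return self.c_daphnia + self.c_leaf + self.biomass

    def poc_n13_umol(self) -> np.ndarray:
        cfg = self.config
        return cfg.f13_d * (self.c_daphnia + self.b_daphnia) + cfg.f13_l * (
            self.c_leaf + self.b_leaf
        )

    def poc_mg_l(self) -> np.ndarray:
        """POC in mg C l⁻¹ using exact isotopologue masses."""
        n = self.poc_umol()
        n13 = self.poc_n13_umol()
        return (12.0 * (n - n13) + 13.00335 * n13) / 1000.0

    def poc_delta(self) -> np.ndarray:
        n = self.poc_umol()
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, self.poc_n13_umol() / np.where(n > 0, n, 1.0), np.nan)
        return atom_fraction_to_delta(f)

    def doc_mg_l(self) -> np.ndarray:
        n = self.doc_daphnia
        n13 = self.config.f13_d * n
        return (12.0 * (n - n13) + 13.00335 * n13) / 1000.0

    def conservation_error(self) -> float:
        """Max relative drift of total ¹²C and ¹³C over the run."""
        cfg = self.config
        tot_d = self.c_daphnia + self.doc_daphnia + self.b_daphnia + self.co2_daphnia
        tot_l = self.c_leaf + self.b_leaf + self.co2_leaf
        n13 = cfg.f13_d * tot_d + cfg.f13_l * tot_l
        n12 = (1 - cfg.f13_d) * tot_d + (1 - cfg.f13_l) * tot_l
        errs = []
        for series in (n12, n13):
            if series[0] > 0:
                errs.append(np.max(np.abs(series - series[0])) / series[0])
            else:
                errs.append(np.max(np.abs(series)))
        return float(max(errs))


def _derivatives(y: np.ndarray, cfg: SimConfig) -> np.ndarray:
    c_d, c_l, doc_d, b_d, b_l, r_d, r_l = y
    b = b_d + b_l
    if cfg.half_sat_b > 0 or b > 0:
        monod = b / (b + cfg.half_sat_b) if (b + cfg.half_sat_b) > 0 else 0.0
    else:
        monod = 0.0
    k_l_eff = cfg.k_l * (1.0 + cfg.priming_p * monod)
    u_d = cfg.k_d * c_d + cfg.k_doc * doc_d   # daphnia-derived uptake
    u_l = k_l_eff * c_l                        # leaf-derived uptake
    y_ = cfg.yield_y
    m = cfg.maintenance_m
    return np.array(
        [
            -cfg.k_d * c_d,
            -k_l_eff * c_l,
            -cfg.k_doc * doc_d,
            y_ * u_d - m * b_d,
            y_ * u_l - m * b_l,
            (1.0 - y_) * u_d + m * b_d,
            (1.0 - y_) * u_l + m * b_l,
        ]
    )


def simulate_incubation(
    cfg: SimConfig, tr: Treatment, with_twin: bool = True
) -> SimTruth:
    """Integrate one bottle with fixed-step classical Runge–Kutta (RK4).

    Initial conditions derive from the treatment's substrate dry masses and
    the configured carbon contents; a ``doc_frac`` share of the daphnia
    carbon starts as rapidly consumed leachate DOC (the leaves were leached
    before incubation, so contribute none).  Initial microbial biomass
    defaults to zero so that every atom in the system is two-source.

    Raises if any state goes below −1e−12 (step too large for the rates).
    """
    umol_per_mg_d = 1000.0 * cfg.c_frac_d / carbon_molar_mass(cfg.f13_d)
    umol_per_mg_l = 1000.0 * cfg.c_frac_l / carbon_molar_mass(cfg.f13_l)
    n_d0 = tr.daphnia_mg_l * umol_per_mg_d
    n_l0 = tr.leaf_mg_l * umol_per_mg_l
    y = np.array(
        [
            (1.0 - cfg.doc_frac) * n_d0,   # particulate daphnia C
            n_l0,                          # particulate leaf C
            cfg.doc_frac * n_d0,           # daphnia leachate DOC
            cfg.b0_umol, 0.0,              # biomass sub-pools
            0.0, 0.0,                      # cumulative CO2 per source
        ]
    )
    n_steps = round(cfg.duration_days / cfg.dt)
    times = np.arange(n_steps + 1) * cfg.dt
    traj = np.empty((n_steps + 1, y.size))
    traj[0] = y
    h = cfg.dt
    for i in range(n_steps):
        k1 = _derivatives(y, cfg)
        k2 = _derivatives(y + 0.5 * h * k1, cfg)
        k3 = _derivatives(y + 0.5 * h * k2, cfg)
        k4 = _derivatives(y + h * k3, cfg)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.any(y < -1e-12):
            raise RuntimeError(
                f"state went negative at t = {times[i + 1]:.3f} d; "
                "reduce dt or the rate constants"
            )
        traj[i + 1] = y

    # daily-resolution truth (plus the final instant if non-integer)
    day_mask = np.isclose(times % 1.0, 0.0, atol=1e-9) | np.isclose(
        times, cfg.duration_days, atol=1e-9
    )
    days = times[day_mask]
    t = traj[day_mask]

    ie_true = None
    if with_twin and cfg.priming_p > 0 and tr.is_mixed:
        twin = simulate_incubation(
            replace(cfg, priming_p=0.0), tr, with_twin=False
        )
        co2_twin = twin.co2_total[-1]
        co2_this = t[-1, 5] + t[-1, 6]
        if co2_twin > 0:
            ie_true = 100.0 * (co2_this - co2_twin) / co2_twin

    return SimTruth(
        treatment=tr,
        config=cfg,
        days=days,
        c_daphnia=t[:, 0],
        c_leaf=t[:, 1],
        doc_daphnia=t[:, 2],
        b_daphnia=t[:, 3],
        b_leaf=t[:, 4],
        co2_daphnia=t[:, 5],
        co2_leaf=t[:, 6],
        ie_true_percent=ie_true,
    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioPreset:
    treatment: Treatment
    config: SimConfig


#: Bacterial community: reduced access to lignocellulose and weaker priming.
BACTERIAL_K_L_FACTOR = 0.4
BACTERIAL_PRIMING_FACTOR = 0.15


def scenario_presets(base: Optional[SimConfig] = None) -> dict[str, ScenarioPreset]:
    """The seven study treatments at 6 mg l⁻¹ total OM (or less, controls).

    Mixed treatments at daphnia:leaf ratios 1:1, 1:3 and 1:5; single-source
    daphnia and leaf controls at 3 mg l⁻¹; a substrate-free blank; and a
    1:1 mixture degraded by the simplified bacterial community, which gets
    a lower leaf decay rate and weaker priming than the complex community.
    """
    if base is None:
        base = SimConfig()
    bact = replace(
        base,
        k_l=base.k_l * BACTERIAL_K_L_FACTOR,
        priming_p=base.priming_p * BACTERIAL_PRIMING_FACTOR,
        plfa_euk_growth_frac_complex=0.0,
    )
    defs = {
        "DL1:1": (3.0, 3.0, "complex", base),
        "b-DL1:1": (3.0, 3.0, "bacterial", bact),
        "DL1:3": (1.5, 4.5, "complex", base),
        "DL1:5": (1.0, 5.0, "complex", base),
        "Daphnia": (3.0, 0.0, "complex", base),
        "Leaves": (0.0, 3.0, "complex", base),
        "Blank": (0.0, 0.0, "complex", base),
    }
    out = {}
    for name, (d, l, community, cfg) in defs.items():
        out[name] = ScenarioPreset(
            treatment=Treatment(
                id=name,
                daphnia_mg_l=d,
                leaf_mg_l=l,
                community=community,
                n_replicates=base.n_replicates,
            ),
            config=cfg,
        )
    return out


# ---------------------------------------------------------------------------
# measurement emission
# ---------------------------------------------------------------------------

def _conc_noise(rng: np.random.Generator, values, cv: float):
    """Mean-preserving multiplicative lognormal noise."""
    values = np.asarray(values, dtype=float)
    if cv <= 0:
        return values.copy()
    s = math.sqrt(math.log(1.0 + cv * cv))
    return values * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=values.shape)


def _delta_noise(rng: np.random.Generator, deltas, sd: float):
    deltas = np.asarray(deltas, dtype=float)
    if sd <= 0:
        return deltas.copy()
    return deltas + rng.normal(0.0, sd, size=deltas.shape)


def _plfa_truth_rows(truth: SimTruth) -> list[dict]:
    """Noise-free per-compound PLFA concentrations and true source fractions."""
    cfg = truth.config
    tr = truth.treatment
    rows = []
    c_d0 = truth.c_daphnia[0]
    remnant = truth.c_daphnia[-1] / c_d0 if c_d0 > 0 else 0.0
    b_t = truth.biomass[-1]
    x_d = truth.b_daphnia[-1] / b_t if b_t > 0 else 0.0
    euk_growth_frac = cfg.plfa_euk_growth_frac_complex
    growth = {
        "eukaryotic": cfg.plfa_per_umol_biomass * euk_growth_frac * b_t,
        "bacterial": cfg.plfa_per_umol_biomass * (1.0 - euk_growth_frac) * b_t,
    }
    init_group = {
        "eukaryotic": cfg.plfa_euk_per_mg_daphnia * tr.daphnia_mg_l,
        "bacterial": cfg.plfa_bact_per_mg_daphnia * tr.daphnia_mg_l,
    }
    f_growth = x_d * cfg.f13_d + (1.0 - x_d) * cfg.f13_l
    for group, weights in (("eukaryotic", _EUK_WEIGHTS), ("bacterial", _BACT_WEIGHTS)):
        for comp, w in weights.items():
            init_c = init_group[group] * w
            carcass = init_c * remnant
            grown = growth[group] * w
            final_c = carcass + grown
            if final_c > 0:
                f13_final = (carcass * cfg.f13_d + grown * f_growth) / final_c
                f_daph_final = (carcass + grown * x_d) / final_c
            else:
                f13_final = np.nan
                f_daph_final = np.nan
            rows.append(
                dict(
                    compound=comp, phase="initial", conc_ng_l=init_c,
                    f13=cfg.f13_d if init_c > 0 else np.nan,
                    f_daphnia=1.0 if init_c > 0 else np.nan,
                )
            )
            rows.append(
                dict(
                    compound=comp, phase="final", conc_ng_l=final_c,
                    f13=f13_final, f_daphnia=f_daph_final,
                )
            )
    return rows


_ALL_TABLES = ("co2", "poc", "doc", "plfa", "mims", "design", "plfa_truth")


def emit_measurements(
    truth: SimTruth,
    seed: Optional[int] = None,
    noise: bool = True,
    tables: Optional[tuple[str, ...]] = None,
) -> dict[str, pd.DataFrame]:
    """Emit the measurement tables for one simulated bottle series.

    Returns a dict of DataFrames keyed ``co2``, ``poc``, ``doc``, ``plfa``,
    ``mims``, ``design`` and ``plfa_truth`` (the noise-free per-compound
    truth, for recovery tests; not part of the measured set).  With
    ``noise=False`` (or zero noise parameters) emitted values equal the
    truth exactly; with a given seed the output is fully deterministic.
    ``tables`` restricts which frames are built (all by default); the noise
    stream consumed by each table is independent of the selection.
    """
    cfg = truth.config
    tr = truth.treatment
    if seed is None:
        seed = cfg.seed
    if tables is None:
        tables = _ALL_TABLES
    unknown = set(tables) - set(_ALL_TABLES)
    if unknown:
        raise KeyError(f"unknown tables {sorted(unknown)}")
    # independent noise stream per table: the draws for one table do not
    # depend on which other tables are requested
    streams = np.random.SeedSequence(seed).spawn(4)
    cv = cfg.conc_cv if noise else 0.0
    dsd = cfg.delta_sd_permil if noise else 0.0

    final_i = len(truth.days) - 1
    conc_series, f13_series = truth.dissolved_co2()
    out: dict[str, pd.DataFrame] = {}

    if "co2" in tables:
        rng = np.random.default_rng(streams[0])
        rows = []
        for rep in range(1, tr.n_replicates + 1):
            for idx in (0, final_i):
                delta = float(atom_fraction_to_delta(f13_series[idx]))
                rows.append(
                    dict(
                        treatment_id=tr.id, replicate=rep,
                        day=int(round(truth.days[idx])),
                        co2_umol_l=float(_conc_noise(rng, conc_series[idx], cv)),
                        delta13C_permil=float(_delta_noise(rng, delta, dsd)),
                        temperature_C=cfg.temperature_c,
                    )
                )
        out["co2"] = pd.DataFrame(rows)

    if "poc" in tables:
        rng = np.random.default_rng(streams[1])
        poc_mg = truth.poc_mg_l()
        poc_delta = truth.poc_delta()
        rows = []
        for rep in range(1, tr.n_replicates + 1):
            for phase, idx in (("initial", 0), ("final", final_i)):
                pd_ = poc_delta[idx]
                rows.append(
                    dict(
                        treatment_id=tr.id, replicate=rep, phase=phase,
                        poc_mg_c_l=float(_conc_noise(rng, poc_mg[idx], cv)),
                        delta13C_permil=(
                            float(_delta_noise(rng, pd_, dsd))
                            if np.isfinite(pd_) else np.nan
                        ),
                    )
                )
        out["poc"] = pd.DataFrame(rows)

    if "doc" in tables:
        rng = np.random.default_rng(streams[2])
        doc_mg = truth.doc_mg_l()
        rows = []
        for rep in range(1, tr.n_replicates + 1):
            for phase, idx in (("initial", 0), ("final", final_i)):
                rows.append(
                    dict(
                        treatment_id=tr.id, replicate=rep, phase=phase,
                        doc_mg_c_l=float(_conc_noise(rng, doc_mg[idx], cv)),
                    )
                )
        out["doc"] = pd.DataFrame(rows)

    if "plfa" in tables:
        rng = np.random.default_rng(streams[3])
        rows = []
        for rep in range(1, tr.n_replicates + 1):
            for row in _plfa_truth_rows(truth):
                conc = float(_conc_noise(rng, row["conc_ng_l"], cv))
                if (
                    np.isfinite(row["f13"])
                    and row["conc_ng_l"] >= cfg.plfa_min_conc_for_delta
                ):
                    delta = float(
                        _delta_noise(rng, atom_fraction_to_delta(row["f13"]), dsd)
                    )
                else:
                    delta = np.nan
                rows.append(
                    dict(
                        compound=row["compound"], treatment_id=tr.id,
                        replicate=rep, phase=row["phase"],
                        conc_ng_l=conc, delta13C_permil=delta,
                    )
                )
        out["plfa"] = pd.DataFrame(rows)

    if "mims" in tables:
        # MIMS monitoring bottle: one unreplicated daily series, noise-free
        # by design (trend data)
        n13 = conc_series * f13_series
        n12 = conc_series - n13
        o2 = np.maximum(cfg.o2_init_umol - truth.co2_total, 1.0)
        g = cfg.mims_gain
        out["mims"] = pd.DataFrame(
            [
                dict(
                    day=int(round(day)), treatment_id=tr.id,
                    i32=g * o2[i], i40=g * cfg.ar_umol,
                    i44=g * n12[i], i45=g * n13[i],
                )
                for i, day in enumerate(truth.days)
            ]
        )

    if "design" in tables:
        out["design"] = pd.DataFrame(
            [
                dict(
                    treatment_id=tr.id,
                    daphnia_mg_l=tr.daphnia_mg_l,
                    leaf_mg_l=tr.leaf_mg_l,
                    community=tr.community,
                    n_replicates=tr.n_replicates,
                )
            ]
        )

    if "plfa_truth" in tables:
        out["plfa_truth"] = pd.DataFrame(_plfa_truth_rows(truth)).assign(
            treatment_id=tr.id
        )
    return out


@dataclass(frozen=True)
class StudyData:
    """All emitted measurement tables of a multi-treatment study."""

    design: pd.DataFrame
    co2: pd.DataFrame
    poc: pd.DataFrame
    doc: pd.DataFrame
    plfa: pd.DataFrame
    mims: pd.DataFrame
    plfa_truth: pd.DataFrame
    truths: Mapping[str, SimTruth]
    config: SimConfig

    def endmembers(self) -> Endmembers:
        return endmembers_from_config(self.config)

    def write(self, out_dir) -> None:
        """Write the standard CSV set (plus truth.csv) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("design", "co2", "poc", "doc", "plfa", "mims"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        truth_frames = []
        for tid, tr in self.truths.items():
            truth_frames.append(
                pd.DataFrame(
                    dict(
                        treatment_id=tid,
                        day=tr.days,
                        c_daphnia=tr.c_daphnia,
                        c_leaf=tr.c_leaf,
                        doc_daphnia=tr.doc_daphnia,
                        b_daphnia=tr.b_daphnia,
                        b_leaf=tr.b_leaf,
                        co2_daphnia=tr.co2_daphnia,
                        co2_leaf=tr.co2_leaf,
                    )
                )
            )
        pd.concat(truth_frames, ignore_index=True).to_csv(
            out / "truth.csv", index=False
        )


def run_study(
    presets: Optional[Mapping[str, ScenarioPreset]] = None,
    base_config: Optional[SimConfig] = None,
    seed: int = 0,
    noise: bool = True,
    out_dir=None,
) -> StudyData:
    """Simulate all preset treatments and emit one combined measurement set.

    One root seed is fanned out deterministically to per-treatment streams,
    so the same seed reproduces the study byte-for-byte.
    """
    if base_config is None:
        base_config = SimConfig(seed=seed)
    if presets is None:
        presets = scenario_presets(base_config)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(presets)) % (2**31)
    truths: dict[str, SimTruth] = {}
    tables: dict[str, list[pd.DataFrame]] = {
        k: [] for k in ("design", "co2", "poc", "doc", "plfa", "mims", "plfa_truth")
    }
    for (name, preset), child in zip(sorted(presets.items()), child_seeds):
        truth = simulate_incubation(preset.config, preset.treatment)
        truths[name] = truth
        emitted = emit_measurements(truth, seed=int(child), noise=noise)
        for k in tables:
            tables[k].append(emitted[k])
    study = StudyData(
        design=pd.concat(tables["design"], ignore_index=True),
        co2=pd.concat(tables["co2"], ignore_index=True),
        poc=pd.concat(tables["poc"], ignore_index=True),
        doc=pd.concat(tables["doc"], ignore_index=True),
        plfa=pd.concat(tables["plfa"], ignore_index=True),
        mims=pd.concat(tables["mims"], ignore_index=True),
        plfa_truth=pd.concat(tables["plfa_truth"], ignore_index=True),
        truths=truths,
        config=base_config,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study
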