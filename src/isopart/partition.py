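"""Source attribution of respired CO₂ and POC, control baselines and
interactive (priming) effects.

An incubation bottle receives two organic-matter pools — bioavailable
daphnia carcasses and persistent, ¹³C-labelled leaf material — at known dry
masses.  The analysis chain implemented here:

1. attribute net CO₂ production (and remaining POC) to its source via the
   two-source mixing model, then normalise per mg of substrate dry weight:

       CO₂_sourceA = C_CO₂ · f_sourceA / dryweight_sourceA

2. construct the additive expectation ("control basis") from single-source
   control bottles — either the measured sum when control masses match the
   treatment, or a *pseudocontrol* built from the controls' per-mg
   mineralisation rates scaled to the treatment's masses;

3. quantify the non-additive interactive effect

       IE (%) = 100 · (CO₂_treatment − CO₂_controls) / CO₂_controls,

   positive when the mixture respires more than the sum of its parts
   (priming of the persistent pool by the bioavailable one);

4. close the carbon budget: initial POC + consumed DOC should reappear as
   final POC (including microbial biomass) plus respired CO₂.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .gas import DissolvedCO2
from .isotopes import (
    ATOM_FRACTION,
    DELTA_SPACE,
    Endmembers,
    IsotopeValue,
    MixingResult,
    canonical_mode,
    mix_fraction,
)

__all__ = [
    "Treatment",
    "SourceSpecificCO2",
    "ControlObservation",
    "ControlBasis",
    "InteractiveEffectResult",
    "CarbonBudget",
    "partition_co2",
    "partition_poc",
    "control_basis",
    "interactive_effect",
    "mass_balance",
    "carbon_molar_mass",
    "DAPHNIA",
    "LEAF",
]

DAPHNIA = "daphnia"
LEAF = "leaf"

#: Exact isotopologue atomic masses (g mol⁻¹) for isotope-weighted carbon
#: mass conversion, and the natural-mix fallback.
M_12C = 12.0
M_13C = 13.00335
M_C_NATURAL = 12.011


def carbon_molar_mass(atom_fraction: Optional[float] = None) -> float:
    """Carbon molar mass, isotope-weighted when the ¹³C content is known.

    A 10 atom% ¹³C pool is ~0.8% heavier than natural carbon, which matters
    for closing a mass balance in mg.  With ``atom_fraction=None`` the
    natural-abundance value 12.011 is used.
    """
    if atom_fraction is None:
        return M_C_NATURAL
    if not 0.0 <= atom_fraction <= 1.0:
        raise ValueError(f"atom fraction must lie in [0,1], got {atom_fraction}")
    # weighted for any known F (exact closure between simulator emission and
    # budget); at natural abundance this reproduces ~12.011 anyway
    return M_12C + (M_13C - M_12C) * atom_fraction


@dataclass(frozen=True)
class Treatment:
    """A bottle scenario: substrate dry masses and degrading community."""

    id: str
    daphnia_mg_l: float
    leaf_mg_l: float
    community: str = "complex"
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.daphnia_mg_l < 0 or self.leaf_mg_l < 0:
            raise ValueError("substrate masses must be >= 0")
        if self.community not in ("complex", "bacterial"):
            raise ValueError(f"community must be complex|bacterial, got {self.community!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def total_om_mg_l(self) -> float:
        return self.daphnia_mg_l + self.leaf_mg_l

    @property
    def is_mixed(self) -> bool:
        return self.daphnia_mg_l > 0 and self.leaf_mg_l > 0

    @property
    def single_source(self) -> Optional[str]:
        if self.daphnia_mg_l > 0 and self.leaf_mg_l == 0:
            return DAPHNIA
        if self.leaf_mg_l > 0 and self.daphnia_mg_l == 0:
            return LEAF
        return None


@dataclass(frozen=True)
class SourceSpecificCO2:
    """CO₂ (or, mutatis mutandis, POC) attributed to one source."""

    treatment_id: str
    source: str
    co2_abs: float        # µmol C l⁻¹ (or mg C l⁻¹ for POC)
    co2_per_mg: float     # per mg substrate dry weight
    f_source: float
    mode: str
    replicate: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_source <= 1.0:
            raise ValueError(f"f_source out of [0,1]: {self.f_source}")


def _partition_quantity(
    quantity: float,
    delta13: IsotopeValue,
    ends: Endmembers,
    tr: Treatment,
    mode: str,
    replicate: int,
) -> tuple[SourceSpecificCO2, SourceSpecificCO2]:
    """Shared implementation for CO₂ and POC partitioning."""
    mode = canonical_mode(mode)
    single = tr.single_source
    if single is not None:
        # Controls contain only one carbon source: no inversion, the
        # fraction is forced to 1 for that source.
        f_d = 1.0 if single == DAPHNIA else 0.0
    elif tr.is_mixed:
        f_d = mix_fraction(delta13, ends, mode=mode).f_a
    else:
        raise ValueError(
            f"treatment {tr.id!r} has no substrate; nothing to partition"
        )

    out = []
    for source, f_s, mass in (
        (DAPHNIA, f_d, tr.daphnia_mg_l),
        (LEAF, 1.0 - f_d, tr.leaf_mg_l),
    ):
        abs_q = quantity * f_s
        if mass == 0:
            if abs_q > 1e-12 * max(quantity, 1.0):
                raise ValueError(
                    f"treatment {tr.id!r}: {abs_q:.4g} attributed to {source} "
                    "but its substrate mass is zero; per-mg normalisation undefined"
                )
            per_mg = 0.0
            abs_q = 0.0
        else:
            per_mg = abs_q / mass
        out.append(
            SourceSpecificCO2(
                treatment_id=tr.id,
                source=source,
                co2_abs=abs_q,
                co2_per_mg=per_mg,
                f_source=f_s,
                mode=mode,
                replicate=replicate,
            )
        )
    return out[0], out[1]


def partition_co2(
    obs: DissolvedCO2,
    ends: Endmembers,
    tr: Treatment,
    mode: str = DELTA_SPACE,
) -> tuple[SourceSpecificCO2, SourceSpecificCO2]:
    """Attribute net CO₂ production to daphnia- and leaf-derived carbon.

    ``obs`` must already be net of the pre-incubation baseline (see
    :func:`isopart.gas.subtract_baseline`).  Returns (daphnia, leaf); the
    two absolute amounts always sum to ``obs.conc``.
    """
    return _partition_quantity(
        obs.conc, obs.delta13, ends, tr, mode, obs.replicate
    )


def partition_poc(
    poc: float,
    delta13: IsotopeValue,
    ends: Endmembers,
    tr: Treatment,
    mode: str = DELTA_SPACE,
    replicate: int = 0,
) -> tuple[SourceSpecificCO2, SourceSpecificCO2]:
    """Attribute POC mass (mg C l⁻¹) to its sources via the bulk δ¹³C.

    Identical to :func:`partition_co2` with POC mass in place of CO₂
    concentration; single-source controls bypass the mixing model.
    """
    if poc < 0:
        raise ValueError(f"POC mass must be >= 0, got {poc}")
    return _partition_quantity(poc, delta13, ends, tr, mode, replicate)


@dataclass(frozen=True)
class ControlObservation:
    """Mean CO₂ production and substrate mass of one single-source control."""

    co2: float            # µmol C l⁻¹
    mass_mg_l: float
    community: str = "complex"

    def __post_init__(self) -> None:
        if self.mass_mg_l <= 0:
            raise ValueError("control substrate mass must be > 0")
        if self.co2 < 0:
            raise ValueError("control CO2 must be >= 0")


@dataclass(frozen=True)
class ControlBasis:
    """Additive expectation for a mixed treatment.

    ``measured_sum`` — the controls carry the same substrate masses as the
    treatment, so the basis is simply the sum of their CO₂ production.
    ``per_mg_pseudo`` — control masses differ; each control's per-mg rate is
    scaled to the treatment's mass (a *pseudocontrol*).
    """

    treatment_id: str
    co2_controls: float
    basis: str
    components: Mapping[str, float]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.basis not in ("measured_sum", "per_mg_pseudo"):
            raise ValueError(f"unknown basis {self.basis!r}")
        total = sum(self.components.values())
        if not math.isclose(total, self.co2_controls, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("co2_controls must equal the sum of its components")
        if not self.co2_controls > 0:
            raise ValueError("control basis must be > 0")


def control_basis(
    tr: Treatment,
    controls: Mapping[str, ControlObservation],
    mass_rtol: float = 1e-9,
) -> ControlBasis:
    """Build the additive control basis for a mixed treatment."""
    for source in (DAPHNIA, LEAF):
        if source not in controls:
            raise KeyError(f"missing {source} control for treatment {tr.id!r}")
    d, l = controls[DAPHNIA], controls[LEAF]
    masses_match = math.isclose(
        d.mass_mg_l, tr.daphnia_mg_l, rel_tol=mass_rtol
    ) and math.isclose(l.mass_mg_l, tr.leaf_mg_l, rel_tol=mass_rtol)
    if masses_match:
        basis = "measured_sum"
        components = {DAPHNIA: d.co2, LEAF: l.co2}
    else:
        basis = "per_mg_pseudo"
        components = {
            DAPHNIA: d.co2 / d.mass_mg_l * tr.daphnia_mg_l,
            LEAF: l.co2 / l.mass_mg_l * tr.leaf_mg_l,
        }
    flags = []
    if any(c.community != tr.community for c in (d, l)):
        flags.append("control_community_mismatch")
    return ControlBasis(
        treatment_id=tr.id,
        co2_controls=sum(components.values()),
        basis=basis,
        components=components,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class InteractiveEffectResult:
    """Non-additive interactive effect of one treatment (in %)."""

    treatment_id: str
    ie_percent: float
    co2_treatment: float
    control: ControlBasis
    replicate_stats: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        expected = (
            100.0
            * (self.co2_treatment - self.control.co2_controls)
            / self.control.co2_controls
        )
        if not math.isclose(self.ie_percent, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("ie_percent violates its defining identity")


def interactive_effect(
    co2_treatment, basis: ControlBasis
) -> InteractiveEffectResult:
    """IE = 100·(CO₂_treatment − CO₂_controls)/CO₂_controls.

    ``co2_treatment`` may be a scalar (single bottle) or a sequence of
    replicate values; replicates are evaluated individually and aggregated
    to mean ± sd, with the headline ``ie_percent`` the replicate mean.
    """
    if not basis.co2_controls > 0:
        raise ValueError("control basis must be positive")
    values = np.atleast_1d(np.asarray(co2_treatment, dtype=float))
    ies = 100.0 * (values - basis.co2_controls) / basis.co2_controls
    stats = None
    if values.size > 1:
        stats = {
            "mean": float(ies.mean()),
            "sd": float(ies.std(ddof=1)),
            "n": int(values.size),
        }
    mean_co2 = float(values.mean())
    return InteractiveEffectResult(
        treatment_id=basis.treatment_id,
        ie_percent=100.0 * (mean_co2 - basis.co2_controls) / basis.co2_controls,
        co2_treatment=mean_co2,
        control=basis,
        replicate_stats=stats,
    )


@dataclass(frozen=True)
class CarbonBudget:
    """Closure of the particulate/dissolved/respired carbon budget (mg C l⁻¹)."""

    treatment_id: str
    initial_poc: float
    final_poc: float
    co2_c: float
    doc_consumed: float
    closure_residual: float
    flagged: bool = False

    def __post_init__(self) -> None:
        expected = self.initial_poc + self.doc_consumed - self.final_poc - self.co2_c
        if not math.isclose(
            self.closure_residual, expected, rel_tol=1e-12, abs_tol=1e-12
        ):
            raise ValueError("closure_residual violates its defining identity")


def mass_balance(
    treatment_id: str,
    initial_poc_mg: float,
    final_poc_mg: float,
    co2_umol: float,
    doc_initial_mg: float = 0.0,
    doc_final_mg: float = 0.0,
    co2_atom_fraction: Optional[float] = None,
    flag_fraction: float = 0.10,
) -> CarbonBudget:
    """Close the carbon budget of one treatment.

    With DOC deliberately minimal, carbon leaving the particulate pool is
    either incorporated into biomass (still POC) or respired as CO₂, so

        residual = POC_initial + DOC_consumed − POC_final − CO₂-C ≈ 0.

    CO₂ is converted from µmol to mg using the isotope-weighted molar mass
    when its atom fraction is supplied.  Residuals exceeding
    ``flag_fraction`` of the initial carbon are flagged.
    """
    for name, v in (
        ("initial_poc", initial_poc_mg),
        ("final_poc", final_poc_mg),
        ("co2_umol", co2_umol),
        ("doc_initial", doc_initial_mg),
        ("doc_final", doc_final_mg),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    co2_mg = co2_umol * carbon_molar_mass(co2_atom_fraction) / 1000.0
    doc_consumed = doc_initial_mg - doc_final_mg
    residual = initial_poc_mg + doc_consumed - final_poc_mg - co2_mg
    initial_c = initial_poc_mg + doc_initial_mg
    flagged = initial_c > 0 and abs(residual) > flag_fraction * initial_c
    return CarbonBudget(
        treatment_id=treatment_id,
        initial_poc=initial_poc_mg,
        final_poc=final_poc_mg,
        co2_c=co2_mg,
        doc_consumed=doc_consumed,
        closure_residual=residual,
        flagged=flagged,
    )
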