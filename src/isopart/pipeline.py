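"""Study-level analysis: from measurement tables to partition / IE / budget.

These functions consume the tidy CSV schemas (see :mod:`isopart.io`) and
drive the per-observation operations of :mod:`isopart.partition` across a
whole treatment design:

* :func:`net_co2_study` — isotope-aware baseline subtraction per bottle;
* :func:`partition_study` — source-specific CO₂ per treatment × replicate,
  absolute and per mg of substrate;
* :func:`interactive_effect_study` — control bases (measured sums where the
  control masses match, per-mg pseudocontrols otherwise) and replicate-level
  interactive effects;
* :func:`mass_balance_study` — carbon-budget closure per treatment.

Every result row records the mixing mode and the V-PDB ratio constant used.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .gas import DissolvedCO2
from .isotopes import (
    ATOM_FRACTION,
    DELTA_SPACE,
    Endmembers,
    IsotopeValue,
    atom_fraction_to_delta,
    canonical_mode,
    delta_to_atom_fraction,
)
from .partition import (
    DAPHNIA,
    LEAF,
    ControlObservation,
    Treatment,
    control_basis,
    interactive_effect,
    mass_balance,
    partition_co2,
)

__all__ = [
    "treatments_from_design",
    "net_co2_study",
    "blank_ids",
    "partition_study",
    "interactive_effect_study",
    "mass_balance_study",
    "ie_monte_carlo",
]


def treatments_from_design(design: pd.DataFrame) -> dict[str, Treatment]:
    """Materialise :class:`Treatment` objects from a design table."""
    out = {}
    for row in design.itertuples(index=False):
        out[row.treatment_id] = Treatment(
            id=row.treatment_id,
            daphnia_mg_l=float(row.daphnia_mg_l),
            leaf_mg_l=float(row.leaf_mg_l),
            community=str(row.community),
            n_replicates=int(row.n_replicates),
        )
    return out


def blank_ids(design: pd.DataFrame) -> list[str]:
    """Treatments with no substrate at all (procedural blanks)."""
    m = (design["daphnia_mg_l"] == 0) & (design["leaf_mg_l"] == 0)
    return design.loc[m, "treatment_id"].tolist()


def net_co2_study(co2: pd.DataFrame) -> pd.DataFrame:
    """Net CO₂ production per treatment × replicate (final − initial day).

    The subtraction is carried out in isotopologue space (net ¹³C = total
    ¹³C difference), which removes the pre-incubation dissolved-CO₂
    background exactly whatever its signature.  Output columns:
    ``treatment_id, replicate, co2_umol_l, atom_fraction, delta13C_permil``.
    A non-positive net (possible for blanks under noise) yields NaN isotope
    columns.
    """
    required = {"treatment_id", "replicate", "day", "co2_umol_l", "delta13C_permil"}
    missing = required - set(co2.columns)
    if missing:
        raise KeyError(f"co2 table missing columns {sorted(missing)}")
    rows = []
    for (tid, rep), grp in co2.groupby(["treatment_id", "replicate"], sort=True):
        d0, d1 = grp["day"].min(), grp["day"].max()
        if d0 == d1:
            raise ValueError(
                f"treatment {tid!r} replicate {rep}: need an initial and a "
                "final day to compute net production"
            )
        ini = grp[grp["day"] == d0].iloc[0]
        fin = grp[grp["day"] == d1].iloc[0]
        f_i = float(delta_to_atom_fraction(ini["delta13C_permil"]))
        f_f = float(delta_to_atom_fraction(fin["delta13C_permil"]))
        net = float(fin["co2_umol_l"] - ini["co2_umol_l"])
        n13 = float(fin["co2_umol_l"]) * f_f - float(ini["co2_umol_l"]) * f_i
        if net > 0 and 0.0 < n13 / net < 1.0:
            f_net = n13 / net
            d_net = float(atom_fraction_to_delta(f_net))
        else:
            f_net, d_net = np.nan, np.nan
        rows.append(
            dict(
                treatment_id=tid,
                replicate=int(rep),
                co2_umol_l=net,
                atom_fraction=f_net,
                delta13C_permil=d_net,
            )
        )
    return pd.DataFrame(rows)


def _blank_corrected(net: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Subtract the blanks' mean net CO₂ concentration from every bottle.

    Net respiration in a substrate-free blank is background mineralisation;
    removing it makes the interactive-effect statistic insensitive to it.
    The concentration is corrected; the net signature is left unchanged (a
    stated approximation, exact when the blank production is zero).
    """
    blanks = blank_ids(design)
    if not blanks:
        return net
    bg = net.loc[net["treatment_id"].isin(blanks), "co2_umol_l"].mean()
    if not np.isfinite(bg):
        bg = 0.0
    out = net.copy()
    mask = ~out["treatment_id"].isin(blanks)
    out.loc[mask, "co2_umol_l"] = out.loc[mask, "co2_umol_l"] - bg
    return out


def partition_study(
    co2: pd.DataFrame,
    design: pd.DataFrame,
    ends: Endmembers,
    mode: str = DELTA_SPACE,
    blank_correct: bool = True,
) -> pd.DataFrame:
    """Source-specific CO₂ for every substrate-bearing treatment × replicate.

    Runs the mixing model per replicate (never on the replicate-mean δ) and
    normalises per mg of substrate dry weight.  Single-source controls
    bypass the model with the fraction forced to 1.  Returns a long frame:
    one row per treatment × replicate × source.
    """
    mode = canonical_mode(mode)
    treatments = treatments_from_design(design)
    net = net_co2_study(co2)
    if blank_correct:
        net = _blank_corrected(net, design)
    rows = []
    for row in net.itertuples(index=False):
        tr = treatments[row.treatment_id]
        if tr.total_om_mg_l == 0:
            continue
        conc = max(float(row.co2_umol_l), 0.0)
        if not np.isfinite(row.atom_fraction):
            continue
        obs = DissolvedCO2(
            conc=conc,
            delta13=IsotopeValue(float(row.atom_fraction), ATOM_FRACTION),
            replicate=int(row.replicate),
            treatment_id=tr.id,
        )
        for part in partition_co2(obs, ends, tr, mode=mode):
            rows.append(
                dict(
                    treatment_id=part.treatment_id,
                    replicate=part.replicate,
                    source=part.source,
                    f_source=part.f_source,
                    co2_abs_umol_l=part.co2_abs,
                    co2_per_mg=part.co2_per_mg,
                    mode=part.mode,
                    standard_r13=ends.source_a.standard.r13,
                )
            )
    return pd.DataFrame(rows)


def interactive_effect_study(
    co2: pd.DataFrame,
    design: pd.DataFrame,
    blank_correct: bool = True,
) -> pd.DataFrame:
    """Interactive effects for every mixed treatment in a study.

    Control bases come from the single-source treatments in the design:
    a measured sum where their masses match the treatment's, otherwise a
    per-mg pseudocontrol.  Replicate net CO₂ values of the treatment are
    evaluated against the (replicate-mean) basis and aggregated.  A
    ``control_community_mismatch`` flag marks treatments evaluated against
    controls of a different community (e.g. a bacterial mixture against
    complex-community controls).
    """
    treatments = treatments_from_design(design)
    net = net_co2_study(co2)
    if blank_correct:
        net = _blank_corrected(net, design)

    def mean_net(tid: str) -> float:
        return float(net.loc[net["treatment_id"] == tid, "co2_umol_l"].mean())

    control_by_source = {}
    for tid, tr in treatments.items():
        if tr.single_source is not None:
            control_by_source[tr.single_source] = (tid, tr)
    for source in (DAPHNIA, LEAF):
        if source not in control_by_source:
            raise KeyError(f"design has no single-source {source} control")

    rows = []
    for tid, tr in sorted(treatments.items()):
        if not tr.is_mixed:
            continue
        controls = {}
        for source, (ctid, ctr) in control_by_source.items():
            mass = ctr.daphnia_mg_l if source == DAPHNIA else ctr.leaf_mg_l
            controls[source] = ControlObservation(
                co2=mean_net(ctid), mass_mg_l=mass, community=ctr.community
            )
        basis = control_basis(tr, controls)
        reps = net.loc[net["treatment_id"] == tid, "co2_umol_l"].to_numpy()
        res = interactive_effect(reps, basis)
        stats = res.replicate_stats or {"mean": res.ie_percent, "sd": np.nan, "n": 1}
        rows.append(
            dict(
                treatment_id=tid,
                ie_percent=res.ie_percent,
                ie_sd=stats["sd"],
                n=stats["n"],
                co2_treatment_umol_l=res.co2_treatment,
                co2_controls_umol_l=basis.co2_controls,
                basis=basis.basis,
                flags=";".join(basis.flags),
            )
        )
    return pd.DataFrame(rows)


def mass_balance_study(
    co2: pd.DataFrame,
    poc: pd.DataFrame,
    doc: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Carbon-budget closure per treatment (replicate means, mg C l⁻¹)."""
    net = net_co2_study(co2)
    rows = []
    for tid in design["treatment_id"]:
        sub_net = net[net["treatment_id"] == tid]
        sub_poc = poc[poc["treatment_id"] == tid]
        sub_doc = doc[doc["treatment_id"] == tid]
        if sub_poc.empty or sub_net.empty:
            continue
        co2_mean = float(sub_net["co2_umol_l"].mean())
        f_vals = sub_net["atom_fraction"].to_numpy(dtype=float)
        f_co2 = float(np.nanmean(f_vals)) if np.isfinite(f_vals).any() else None
        poc_i = float(
            sub_poc.loc[sub_poc["phase"] == "initial", "poc_mg_c_l"].mean()
        )
        poc_f = float(sub_poc.loc[sub_poc["phase"] == "final", "poc_mg_c_l"].mean())
        doc_i = float(
            sub_doc.loc[sub_doc["phase"] == "initial", "doc_mg_c_l"].mean()
        ) if not sub_doc.empty else 0.0
        doc_f = float(
            sub_doc.loc[sub_doc["phase"] == "final", "doc_mg_c_l"].mean()
        ) if not sub_doc.empty else 0.0
        budget = mass_balance(
            treatment_id=tid,
            initial_poc_mg=poc_i,
            final_poc_mg=poc_f,
            co2_umol=max(co2_mean, 0.0),
            doc_initial_mg=doc_i,
            doc_final_mg=doc_f,
            co2_atom_fraction=f_co2,
        )
        rows.append(
            dict(
                treatment_id=tid,
                initial_poc_mg=budget.initial_poc,
                final_poc_mg=budget.final_poc,
                co2_mg=budget.co2_c,
                doc_consumed_mg=budget.doc_consumed,
                closure_residual_mg=budget.closure_residual,
                flagged=budget.flagged,
            )
        )
    return pd.DataFrame(rows)


def ie_monte_carlo(
    base_config,
    n_seeds: int = 200,
    seed: int = 0,
    treatment_id: str = "DL1:1",
) -> np.ndarray:
    """Sampling distribution of the recovered IE under measurement noise.

    Simulates the mixed treatment plus its single-source controls and blank
    once (the truth is deterministic), then draws ``n_seeds`` independent
    noisy measurement sets from it and runs the full IE pipeline on each.
    Returns the replicate-mean IE (%) per Monte-Carlo draw; comparing its
    mean with the noise-free IE quantifies the estimator's bias.
    """
    from .simulate import emit_measurements, scenario_presets, simulate_incubation

    presets = scenario_presets(base_config)
    names = (treatment_id, "Daphnia", "Leaves", "Blank")
    truths = {
        name: simulate_incubation(presets[name].config, presets[name].treatment)
        for name in names
    }
    design = pd.concat(
        [
            emit_measurements(t, noise=False, tables=("design",))["design"]
            for t in truths.values()
        ],
        ignore_index=True,
    )
    child = np.random.SeedSequence(seed).generate_state(n_seeds * len(names)) % (
        2**31
    )
    ies = np.empty(n_seeds)
    k = 0
    for i in range(n_seeds):
        co2 = []
        for name in names:
            co2.append(
                emit_measurements(
                    truths[name], seed=int(child[k]), tables=("co2",)
                )["co2"]
            )
            k += 1
        ie = interactive_effect_study(pd.concat(co2, ignore_index=True), design)
        ies[i] = float(ie.loc[ie["treatment_id"] == treatment_id, "ie_percent"].item())
    return ies
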