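"""PLFA marker grouping and compound-specific carbon partitioning."""

import numpy as np
import pandas as pd
import pytest

import isopart as ip
from isopart.plfa import BACTERIAL, EUKARYOTIC


def plfa_df(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "compound", "treatment_id", "replicate", "phase",
            "conc_ng_l", "delta13C_permil",
        ],
    )


class TestConcentrationChange:
    def test_no_change_when_phases_equal(self):
        df = plfa_df(
            [
                ("i15:0", "A", 1, "initial", 10.0, np.nan),
                ("i15:0", "A", 1, "final", 10.0, np.nan),
            ]
        )
        ch = ip.concentration_change(df)
        assert ch.loc["i15:0", "A"] == 0.0

    def test_compound_absent_initially_counts_from_zero(self):
        df = plfa_df(
            [
                ("a15:0", "A", 1, "initial", 5.0, np.nan),
                ("a15:0", "A", 1, "final", 5.0, np.nan),
                ("i15:0", "A", 1, "final", 7.0, np.nan),
            ]
        )
        ch = ip.concentration_change(df)
        assert ch.loc["i15:0", "A"] == 7.0

    def test_replicates_averaged_within_phase(self):
        df = plfa_df(
            [
                ("i15:0", "A", 1, "initial", 10.0, np.nan),
                ("i15:0", "A", 2, "initial", 14.0, np.nan),
                ("i15:0", "A", 1, "final", 20.0, np.nan),
                ("i15:0", "A", 2, "final", 24.0, np.nan),
            ]
        )
        assert ip.concentration_change(df).loc["i15:0", "A"] == pytest.approx(10.0)

    def test_missing_phase_rejected(self):
        df = plfa_df([("i15:0", "A", 1, "final", 1.0, np.nan)])
        with pytest.raises(ValueError, match="initial and final"):
            ip.concentration_change(df)


class TestClusterMarkers:
    def test_anticorrelated_profiles_split(self):
        change = pd.DataFrame(
            {
                "A": [1.0, -1.0], "B": [2.0, -2.0], "C": [3.0, -3.0],
            },
            index=["18:2ω6,9", "i15:0"],
        )
        asg = ip.cluster_markers(change)
        assert asg.groups["18:2ω6,9"] == EUKARYOTIC
        assert asg.groups["i15:0"] == BACTERIAL

    def test_reproduces_study_grouping_on_simulated_fixture(self, noisy_study):
        ch = ip.concentration_change(noisy_study.plfa)
        asg = ip.cluster_markers(ch)
        assert asg.compounds(EUKARYOTIC) == ("18:1ω9t/7c", "18:2ω6,9")
        assert asg.compounds(BACTERIAL) == (
            "16:1ω9", "18:1ω9c", "a15:0", "cy-17:0", "i15:0"
        )

    def test_invariant_to_input_permutation_and_rescaling(self, noisy_study):
        ch = ip.concentration_change(noisy_study.plfa)
        base = ip.cluster_markers(ch)
        shuffled = ch.sample(frac=1.0, random_state=3)
        assert ip.cluster_markers(shuffled).groups == base.groups
        assert ip.cluster_markers(ch * 7.5).groups == base.groups

    def test_ambiguous_anchor_split_raises(self):
        # eukaryotic anchor co-varies with a bacterial anchor
        change = pd.DataFrame(
            {
                "A": [1.0, 1.1, -1.0], "B": [2.0, 2.1, -2.0], "C": [3.0, 3.1, -3.0],
            },
            index=["18:2ω6,9", "i15:0", "a15:0"],
        )
        with pytest.raises(ValueError, match="anchor"):
            ip.cluster_markers(change)


class TestGroupBiomass:
    def test_group_totals_are_additive(self, noisy_study):
        ch = ip.concentration_change(noisy_study.plfa)
        asg = ip.cluster_markers(ch)
        totals = ip.group_biomass(noisy_study.plfa, asg)
        per_comp = (
            noisy_study.plfa.groupby(["treatment_id", "phase", "replicate"])
            ["conc_ng_l"].sum().groupby(["treatment_id", "phase"]).mean()
        )
        summed = totals[EUKARYOTIC] + totals[BACTERIAL]
        for key, val in summed.items():
            assert val == pytest.approx(per_comp.loc[key], rel=1e-9)

    def test_unassigned_compound_rejected(self):
        df = plfa_df([("cy-17:0", "A", 1, "final", 1.0, np.nan)])
        asg = ip.MarkerAssignment(groups={"i15:0": BACTERIAL})
        with pytest.raises(KeyError, match="cy-17:0"):
            ip.group_biomass(df, asg)


class TestPartitionPLFACarbon:
    def test_compound_at_daphnia_endmember_is_pure_daphnia(self, enriched_ends):
        df = plfa_df(
            [("18:2ω6,9", "A", 1, "final", 50.0, enriched_ends.source_a.as_delta())]
        )
        out = ip.partition_plfa_carbon(df, enriched_ends)
        assert out.pct_daphnia.iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_midpoint_signature_splits_evenly(self, enriched_ends):
        mid = ip.forward_mix(0.5, enriched_ends, mode="atom").as_delta()
        df = plfa_df([("16:1ω9", "A", 1, "final", 50.0, mid)])
        out = ip.partition_plfa_carbon(df, enriched_ends, mode="atom")
        assert out.pct_daphnia.iloc[0] == pytest.approx(50.0, rel=1e-9)
        assert out.pct_daphnia.iloc[0] + out.pct_leaf.iloc[0] == pytest.approx(100.0)

    def test_known_64_percent_mixture_recovered_in_atom_mode(self, enriched_ends):
        sig = ip.forward_mix(0.64, enriched_ends, mode="atom").as_delta()
        df = plfa_df([("i15:0", "A", 1, "final", 50.0, sig)])
        out = ip.partition_plfa_carbon(df, enriched_ends, mode="atom")
        assert out.pct_daphnia.iloc[0] == pytest.approx(64.0, rel=1e-9)

    def test_simulator_compound_truth_recovered(self, noise_free_study):
        """Atom-mode inversion of emitted compound δ matches the simulator's
        per-compound source fraction exactly."""
        ends = noise_free_study.endmembers()
        out = ip.partition_plfa_carbon(noise_free_study.plfa, ends, mode="atom")
        truth = noise_free_study.plfa_truth
        merged = out.merge(truth, on=["compound", "treatment_id", "phase"])
        ok = merged[~merged.no_delta & np.isfinite(merged.f_daphnia)]
        assert len(ok) > 10
        assert np.allclose(ok.pct_daphnia, 100.0 * ok.f_daphnia, atol=1e-8)

    def test_missing_delta_emits_null_with_flag(self, enriched_ends):
        df = plfa_df([("a15:0", "A", 1, "final", 2.0, np.nan)])
        out = ip.partition_plfa_carbon(df, enriched_ends)
        assert out.no_delta.iloc[0]
        assert np.isnan(out.pct_daphnia.iloc[0])


class TestPooling:
    def test_concentration_weighted_pooling(self):
        # pooled atom fraction is the conc-weighted mean of the replicates'
        f1 = ip.IsotopeValue(100.0).as_atom_fraction()
        f2 = ip.IsotopeValue(500.0).as_atom_fraction()
        pooled = ip.pool_replicate_delta([30.0, 10.0], [100.0, 500.0])
        expected_f = (30.0 * f1 + 10.0 * f2) / 40.0
        assert ip.IsotopeValue(pooled).as_atom_fraction() == pytest.approx(
            expected_f, rel=1e-12
        )

    def test_missing_replicates_excluded(self):
        pooled = ip.pool_replicate_delta([10.0, 10.0], [100.0, np.nan])
        assert pooled == pytest.approx(100.0, rel=1e-9)
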