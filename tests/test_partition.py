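"""Source attribution, control bases, interactive effects, carbon budget."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import isopart as ip
from isopart.partition import DAPHNIA, LEAF


@pytest.fixture
def mixed_treatment():
    return ip.Treatment("DL1:1", daphnia_mg_l=1.5, leaf_mg_l=4.5)


class TestPartitionCO2:
    def test_normalisation_arithmetic(self, enriched_ends):
        # 120 umol/l at f_daphnia = 0.25 with 1.5 mg/l daphnia
        # -> 30 umol/l absolute, 20 umol/l/mg normalised
        tr = ip.Treatment("t", daphnia_mg_l=1.5, leaf_mg_l=4.5)
        sample = ip.forward_mix(0.25, enriched_ends, mode="atom")
        obs = ip.DissolvedCO2(120.0, sample)
        daph, leaf = ip.partition_co2(obs, enriched_ends, tr, mode="atom")
        assert daph.co2_abs == pytest.approx(30.0, rel=1e-12)
        assert daph.co2_per_mg == pytest.approx(20.0, rel=1e-12)
        assert leaf.co2_abs == pytest.approx(90.0, rel=1e-12)
        assert daph.co2_abs + leaf.co2_abs == pytest.approx(obs.conc, rel=1e-12)

    def test_sample_at_leaf_endmember_is_all_leaf(self, enriched_ends):
        tr = ip.Treatment("t", daphnia_mg_l=3.0, leaf_mg_l=3.0)
        obs = ip.DissolvedCO2(50.0, enriched_ends.source_b)
        daph, leaf = ip.partition_co2(obs, enriched_ends, tr, mode="atom")
        assert leaf.f_source == pytest.approx(1.0, abs=1e-12)
        assert daph.co2_abs == pytest.approx(0.0, abs=1e-10)

    def test_absolute_amounts_sum_to_input_any_mode(self, enriched_ends):
        tr = ip.Treatment("t", daphnia_mg_l=2.0, leaf_mg_l=4.0)
        obs = ip.DissolvedCO2(77.7, ip.IsotopeValue(0.05, ip.ATOM_FRACTION))
        for mode in ("delta", "atom"):
            daph, leaf = ip.partition_co2(obs, enriched_ends, tr, mode=mode)
            assert daph.co2_abs + leaf.co2_abs == pytest.approx(77.7, rel=1e-12)

    def test_single_source_control_bypasses_model(self, enriched_ends):
        tr = ip.Treatment("Daphnia", daphnia_mg_l=3.0, leaf_mg_l=0.0)
        # deliberately inconsistent delta: must be ignored for controls
        obs = ip.DissolvedCO2(40.0, ip.IsotopeValue(0.08, ip.ATOM_FRACTION))
        daph, leaf = ip.partition_co2(obs, enriched_ends, tr)
        assert daph.f_source == 1.0
        assert daph.co2_abs == 40.0
        assert leaf.co2_abs == 0.0

    def test_no_substrate_rejected(self, enriched_ends):
        tr = ip.Treatment("Blank", daphnia_mg_l=0.0, leaf_mg_l=0.0)
        obs = ip.DissolvedCO2(5.0, ip.IsotopeValue(-10.0))
        with pytest.raises(ValueError, match="no substrate"):
            ip.partition_co2(obs, enriched_ends, tr)


class TestPartitionPOC:
    def test_midpoint_splits_poc_evenly(self, enriched_ends):
        tr = ip.Treatment("t", daphnia_mg_l=3.0, leaf_mg_l=3.0)
        mid = ip.forward_mix(0.5, enriched_ends, mode="atom")
        daph, leaf = ip.partition_poc(2.4, mid, enriched_ends, tr, mode="atom")
        assert daph.co2_abs == pytest.approx(1.2, rel=1e-12)
        assert leaf.co2_abs == pytest.approx(1.2, rel=1e-12)

    def test_single_source_fraction_forced_without_inversion(self, enriched_ends):
        tr = ip.Treatment("Leaves", daphnia_mg_l=0.0, leaf_mg_l=3.0)
        daph, leaf = ip.partition_poc(
            1.1, ip.IsotopeValue(500.0), enriched_ends, tr
        )
        assert leaf.f_source == 1.0 and daph.f_source == 0.0


class TestControlBasis:
    def test_matching_masses_use_measured_sum(self):
        tr = ip.Treatment("DL1:1", daphnia_mg_l=3.0, leaf_mg_l=3.0)
        basis = ip.control_basis(
            tr,
            {
                DAPHNIA: ip.ControlObservation(co2=90.0, mass_mg_l=3.0),
                LEAF: ip.ControlObservation(co2=12.0, mass_mg_l=3.0),
            },
        )
        assert basis.basis == "measured_sum"
        assert basis.co2_controls == pytest.approx(102.0)

    def test_pseudocontrol_hand_arithmetic(self):
        # daphnia 90/3 mg = 30 per mg; leaf 12/3 = 4 per mg
        # DL1:5 (1 + 5 mg) -> 30*1 + 4*5 = 50
        tr = ip.Treatment("DL1:5", daphnia_mg_l=1.0, leaf_mg_l=5.0)
        basis = ip.control_basis(
            tr,
            {
                DAPHNIA: ip.ControlObservation(co2=90.0, mass_mg_l=3.0),
                LEAF: ip.ControlObservation(co2=12.0, mass_mg_l=3.0),
            },
        )
        assert basis.basis == "per_mg_pseudo"
        assert basis.components[DAPHNIA] == pytest.approx(30.0)
        assert basis.components[LEAF] == pytest.approx(20.0)
        assert basis.co2_controls == pytest.approx(50.0)

    def test_pseudo_and_measured_coincide_at_equal_masses(self):
        tr = ip.Treatment("t", daphnia_mg_l=2.0, leaf_mg_l=4.0)
        obs = {
            DAPHNIA: ip.ControlObservation(co2=60.0, mass_mg_l=2.0),
            LEAF: ip.ControlObservation(co2=16.0, mass_mg_l=4.0),
        }
        basis = ip.control_basis(tr, obs)
        assert basis.basis == "measured_sum"
        # per-mg arithmetic gives the identical number
        assert basis.co2_controls == pytest.approx(60.0 / 2 * 2 + 16.0 / 4 * 4)

    def test_missing_control_rejected(self):
        tr = ip.Treatment("t", daphnia_mg_l=1.0, leaf_mg_l=1.0)
        with pytest.raises(KeyError, match="leaf"):
            ip.control_basis(
                tr, {DAPHNIA: ip.ControlObservation(co2=1.0, mass_mg_l=1.0)}
            )

    def test_community_mismatch_flagged(self):
        tr = ip.Treatment("b-DL1:1", 3.0, 3.0, community="bacterial")
        basis = ip.control_basis(
            tr,
            {
                DAPHNIA: ip.ControlObservation(90.0, 3.0, community="complex"),
                LEAF: ip.ControlObservation(12.0, 3.0, community="complex"),
            },
        )
        assert "control_community_mismatch" in basis.flags


class TestInteractiveEffect:
    def _basis(self, co2, tid="t"):
        return ip.ControlBasis(
            treatment_id=tid,
            co2_controls=co2,
            basis="measured_sum",
            components={DAPHNIA: co2 / 2, LEAF: co2 / 2},
        )

    def test_additive_system_gives_zero(self):
        assert ip.interactive_effect(150.0, self._basis(150.0)).ie_percent == 0.0

    def test_doubling_is_98_percent(self):
        res = ip.interactive_effect(297.0, self._basis(150.0))
        assert res.ie_percent == pytest.approx(98.0, rel=1e-12)

    def test_pseudocontrol_worked_example_178_percent(self):
        tr = ip.Treatment("DL1:5", daphnia_mg_l=1.0, leaf_mg_l=5.0)
        basis = ip.control_basis(
            tr,
            {
                DAPHNIA: ip.ControlObservation(co2=90.0, mass_mg_l=3.0),
                LEAF: ip.ControlObservation(co2=12.0, mass_mg_l=3.0),
            },
        )
        res = ip.interactive_effect(139.0, basis)
        assert res.ie_percent == pytest.approx(178.0, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        base = ip.interactive_effect(200.0, self._basis(120.0)).ie_percent
        scaled = ip.interactive_effect(200.0 * c, self._basis(120.0 * c)).ie_percent
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_replicates_aggregated(self):
        res = ip.interactive_effect([140.0, 160.0, 150.0, 150.0], self._basis(100.0))
        assert res.replicate_stats["n"] == 4
        assert res.ie_percent == pytest.approx(50.0)
        assert res.replicate_stats["sd"] == pytest.approx(
            np.std([40.0, 60.0, 50.0, 50.0], ddof=1)
        )

    def test_nonpositive_basis_rejected(self):
        with pytest.raises(ValueError):
            ip.ControlBasis("t", 0.0, "measured_sum", {DAPHNIA: 0.0, LEAF: 0.0})


class TestMassBalance:
    def test_static_system_closes_exactly(self):
        b = ip.mass_balance("t", initial_poc_mg=2.0, final_poc_mg=2.0, co2_umol=0.0)
        assert b.closure_residual == 0.0
        assert not b.flagged

    def test_isotope_weighted_molar_mass(self):
        assert ip.carbon_molar_mass(None) == 12.011
        assert ip.carbon_molar_mass(0.10) == pytest.approx(
            0.9 * 12.0 + 0.1 * 13.00335, rel=1e-12
        )

    def test_large_residual_flagged(self):
        b = ip.mass_balance("t", 2.0, 0.5, co2_umol=10.0, co2_atom_fraction=0.011)
        assert b.flagged

    def test_negative_masses_rejected(self):
        with pytest.raises(ValueError):
            ip.mass_balance("t", -1.0, 0.0, 0.0)
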