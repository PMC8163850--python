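"""Mechanistic incubation simulator: dynamics, conservation, emission."""

import io as _io
from dataclasses import replace

import numpy as np
import pytest

import isopart as ip


def preset(name="DL1:1", **cfg_overrides):
    base = ip.SimConfig(**cfg_overrides) if cfg_overrides else ip.SimConfig()
    p = ip.scenario_presets(base)[name]
    return p.config, p.treatment


class TestDynamics:
    def test_no_priming_leaf_pool_decays_exponentially(self):
        cfg, tr = preset(priming_p=0.0)
        truth = ip.simulate_incubation(cfg, tr)
        expected = truth.c_leaf[0] * np.exp(-cfg.k_l * truth.days)
        assert np.allclose(truth.c_leaf, expected, rtol=1e-9)

    def test_zero_rates_freeze_all_pools(self):
        cfg, tr = preset(k_d=0.0, k_l=0.0, k_doc=0.0, priming_p=0.0)
        truth = ip.simulate_incubation(cfg, tr)
        assert np.allclose(truth.c_daphnia, truth.c_daphnia[0])
        assert np.allclose(truth.c_leaf, truth.c_leaf[0])
        assert np.all(truth.co2_total == 0.0)

    def test_priming_yields_positive_interactive_effect_vs_twin(self):
        cfg, tr = preset()
        truth = ip.simulate_incubation(cfg, tr)
        assert truth.ie_true_percent is not None
        assert truth.ie_true_percent > 0

    def test_priming_accelerates_leaf_decay_only(self):
        cfg0, tr = preset(priming_p=0.0)
        cfg2, _ = preset(priming_p=2.0)
        t0 = ip.simulate_incubation(cfg0, tr)
        t2 = ip.simulate_incubation(cfg2, tr)
        assert t2.co2_leaf[-1] > t0.co2_leaf[-1]
        assert t2.co2_daphnia[-1] == pytest.approx(t0.co2_daphnia[-1], rel=1e-9)

    def test_isotope_mass_conserved(self):
        for name in ("DL1:1", "DL1:5", "b-DL1:1", "Daphnia", "Leaves", "Blank"):
            cfg, tr = preset(name)
            truth = ip.simulate_incubation(cfg, tr)
            assert truth.conservation_error() <= 1e-9

    def test_integrator_converged_at_default_step(self):
        cfg, tr = preset()
        coarse = ip.simulate_incubation(cfg, tr)
        fine = ip.simulate_incubation(replace(cfg, dt=cfg.dt / 2), tr)
        rel = abs(fine.co2_total[-1] - coarse.co2_total[-1]) / fine.co2_total[-1]
        assert rel < 1e-6

    def test_dissolved_delta_between_endmembers(self):
        cfg, tr = preset()
        truth = ip.simulate_incubation(cfg, tr)
        f = truth.co2_atom_fraction()[1:]  # day 0 has no production
        assert np.all(f > min(cfg.f13_d, cfg.f13_l))
        assert np.all(f < max(cfg.f13_d, cfg.f13_l))

    def test_oversized_step_aborts_with_guidance(self):
        cfg, tr = preset(k_d=50.0, dt=0.5, duration_days=11.0)
        with pytest.raises(RuntimeError, match="reduce dt"):
            ip.simulate_incubation(cfg, tr)


class TestPresets:
    def test_table_masses(self):
        presets = ip.scenario_presets()
        expect = {
            "DL1:1": (3.0, 3.0), "b-DL1:1": (3.0, 3.0), "DL1:3": (1.5, 4.5),
            "DL1:5": (1.0, 5.0), "Daphnia": (3.0, 0.0), "Leaves": (0.0, 3.0),
            "Blank": (0.0, 0.0),
        }
        for name, (d, l) in expect.items():
            tr = presets[name].treatment
            assert (tr.daphnia_mg_l, tr.leaf_mg_l) == (d, l)
            assert tr.total_om_mg_l <= 6.0

    def test_blank_produces_no_co2(self):
        cfg, tr = preset("Blank")
        truth = ip.simulate_incubation(cfg, tr)
        assert np.all(truth.co2_total == 0.0)

    def test_bacterial_preset_weaker_than_complex(self):
        presets = ip.scenario_presets()
        assert presets["b-DL1:1"].config.k_l < presets["DL1:1"].config.k_l
        assert presets["b-DL1:1"].config.priming_p < presets["DL1:1"].config.priming_p


class TestEmission:
    def test_noise_free_emission_equals_truth(self):
        cfg, tr = preset()
        truth = ip.simulate_incubation(cfg, tr)
        out = ip.emit_measurements(truth, noise=False)
        conc, f13 = truth.dissolved_co2()
        fin = out["co2"][(out["co2"].day == 11)]
        assert np.allclose(fin.co2_umol_l, conc[-1], rtol=1e-12)
        d_true = ip.IsotopeValue(f13[-1], ip.ATOM_FRACTION).as_delta()
        assert np.allclose(fin.delta13C_permil, d_true, rtol=1e-12)
        poc_fin = out["poc"][out["poc"].phase == "final"]
        assert np.allclose(poc_fin.poc_mg_c_l, truth.poc_mg_l()[-1], rtol=1e-12)

    def test_same_seed_gives_byte_identical_files(self):
        s1 = ip.run_study(seed=42)
        s2 = ip.run_study(seed=42)
        for name in ("design", "co2", "poc", "doc", "plfa", "mims"):
            b1, b2 = _io.StringIO(), _io.StringIO()
            getattr(s1, name).to_csv(b1, index=False)
            getattr(s2, name).to_csv(b2, index=False)
            assert b1.getvalue() == b2.getvalue()

    def test_different_seeds_differ(self):
        s1 = ip.run_study(seed=1)
        s2 = ip.run_study(seed=2)
        assert not np.allclose(s1.co2.co2_umol_l, s2.co2.co2_umol_l)

    def test_delta_noise_matches_configured_accuracy(self):
        """Monte-Carlo: emitted δ scatters around truth with sd ≈ 0.2 ‰."""
        cfg, tr = preset()
        truth = ip.simulate_incubation(cfg, tr)
        _, f13 = truth.dissolved_co2()
        d_true = ip.IsotopeValue(f13[-1], ip.ATOM_FRACTION).as_delta()
        resid = []
        for seed in range(200):
            out = ip.emit_measurements(truth, seed=seed)
            fin = out["co2"][out["co2"].day == 11]
            resid.extend(fin.delta13C_permil - d_true)
        assert np.std(resid) == pytest.approx(0.2, abs=0.02)

    def test_config_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("priming_p: 0.5\nk_l: 0.01\n")
        cfg = ip.SimConfig.from_yaml(p)
        assert cfg.priming_p == 0.5 and cfg.k_l == 0.01
        p.write_text("not_a_field: 1\n")
        with pytest.raises(KeyError):
            ip.SimConfig.from_yaml(p)

    def test_study_write_produces_csv_set(self, tmp_path):
        study = ip.run_study(seed=3, noise=False)
        study.write(tmp_path)
        for name in ("design", "co2", "poc", "doc", "plfa", "mims", "truth"):
            assert (tmp_path / f"{name}.csv").exists()
        df = ip.io.read_co2(tmp_path / "co2.csv")
        assert set(df.treatment_id) == set(study.design.treatment_id)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dt=0.3),                 # does not divide 11 days
            dict(yield_y=1.0),
            dict(k_d=-0.1),
            dict(f13_l=1.5),
            dict(doc_frac=1.0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ip.SimConfig(**kwargs)
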