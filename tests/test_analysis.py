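"""Observables: hooking fraction, regimes, correlations, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zwitterslide import analysis
from zwitterslide.analysis import (hooking_fraction, interlayer_distance,
                                   pearson_rho, classify_regime,
                                   detect_slips, critical_velocity,
                                   transient_bond_energy, thermal_energy,
                                   HookingDefinition, SlipDetection,
                                   summarize_trace)
from zwitterslide.fixtures import synthetic_trace, correlated_series
from zwitterslide import fixtures

from helpers import toy_config


def two_layer_frame(n_per_layer=10, hooked_sub=0, hooked_sup=0):
    """CA-only frame: SUB CA plane at z=1, SUP CA plane at z=2; 'hooked'
    molecules poke 0.5 nm past the opposing plane."""
    pos, species, layer = [], [], []
    for k in range(n_per_layer):
        z = 2.5 if k < hooked_sub else 1.0
        pos.append([0.3 * k, 0.1, z])
        species.append(0)
        layer.append(0)
    for k in range(n_per_layer):
        z = 0.5 if k < hooked_sup else 2.0
        pos.append([0.3 * k, 0.5, z])
        species.append(0)
        layer.append(1)
    return toy_config(pos, species=species, layer=layer, box=(10.0, 10.0))


class TestHookingFraction:
    def test_hand_built_frame_counts(self):
        """1 of 10 SUB chains above the SUP CA plane, none reversed:
        h = 1/20 = 5%."""
        cfg = two_layer_frame(10, hooked_sub=1)
        assert hooking_fraction(cfg) == pytest.approx(5.0)
        cfg2 = two_layer_frame(10, hooked_sub=2, hooked_sup=3)
        assert hooking_fraction(cfg2) == pytest.approx(100 * 5 / 20)

    def test_separated_layers_zero(self):
        fx = fixtures.mini_system(8, charge_on=False, seed=0,
                                  initial_gap=5.0)
        assert hooking_fraction(fx.config) == 0.0

    def test_invariant_under_layer_translation(self):
        cfg = two_layer_frame(10, hooked_sub=3)
        h0 = hooking_fraction(cfg)
        pos = cfg.positions.copy()
        pos[np.asarray(cfg.layer) == 0, 0] += 1.7
        pos[np.asarray(cfg.layer) == 0, 1] -= 0.9
        assert hooking_fraction(cfg, pos) == h0
        # and under molecule relabeling (permutation within a layer)
        perm = np.random.default_rng(0).permutation(len(pos))
        cfg2 = toy_config(pos[perm],
                          species=np.asarray(cfg.species)[perm],
                          layer=np.asarray(cfg.layer)[perm],
                          box=(10.0, 10.0))
        assert hooking_fraction(cfg2) == h0

    def test_margin_parameter(self):
        cfg = two_layer_frame(10, hooked_sub=1)   # pokes 0.5 past plane
        assert hooking_fraction(
            cfg, definition=HookingDefinition(delta_z=0.6)) == 0.0


class TestInterlayerDistance:
    def test_built_planes(self):
        fx = fixtures.mini_system(8, charge_on=False, seed=0)
        cfg = fx.config
        z = cfg.positions[:, 2]
        expect = (z[cfg.rigid_translating].mean() - z[cfg.frozen].mean())
        assert interlayer_distance(cfg) == pytest.approx(expect, abs=1e-12)
        assert expect > 0


class TestPearson:
    def test_perfect_anticorrelation(self):
        u = np.linspace(0, 1, 50)
        h = -2.0 * u + 3.0
        assert pearson_rho(u, h) == pytest.approx(-1.0, abs=1e-12)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(5)
        u = rng.standard_normal(10_000)
        h = rng.standard_normal(10_000)
        assert abs(pearson_rho(u, h)) < 0.05

    def test_streaming_equals_two_pass(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            u = rng.standard_normal(300) * rng.uniform(0.1, 10)
            h = rng.standard_normal(300) + 0.3 * u
            assert pearson_rho(u, h) == pytest.approx(
                pearson_rho(u, h, method="twopass"), abs=1e-12)

    def test_zero_variance_undefined(self):
        u = np.arange(10.0)
        assert np.isnan(pearson_rho(u, np.zeros(10)))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson_rho([1, 2, 3], [1, 2])

    @given(rho=st.floats(-0.95, 0.95))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_constructed_correlation_recovered(self, rho):
        u, h = correlated_series(rho, 40_000, seed=3)
        assert pearson_rho(u, h) == pytest.approx(rho, abs=2 / 200.0)


class TestRegimeClassification:
    def test_flat_trace_smooth(self):
        tr = synthetic_trace("flat", s_max=3.0)
        regime, events = classify_regime(tr)
        assert regime == "smooth" and events == []

    def test_noisy_trace_smooth(self):
        tr = synthetic_trace("noisy", s_max=1.0, noise_sigma=0.3, seed=2)
        regime, events = classify_regime(tr)
        assert regime == "smooth"

    def test_sawtooth_stick_slip_event_count(self):
        tr = synthetic_trace("sawtooth", length_nm=10.0, period_nm=2.0,
                             s_max=5.0)
        regime, events = classify_regime(tr)
        assert regime == "stick-slip"
        assert len(events) == tr.attrs["ground_truth"]["n_slips"]
        # events sit near the sawtooth resets
        assert np.allclose(np.diff(events), 2.0, atol=0.3)

    def test_stride_halving_stable(self):
        tr = synthetic_trace("sawtooth", length_nm=10.0, period_nm=2.0)
        sub = tr.iloc[::2].reset_index(drop=True)
        sub.attrs.update(tr.attrs)
        assert classify_regime(tr)[0] == classify_regime(sub)[0]

    def test_too_short_window_unconverged(self):
        tr = synthetic_trace("flat", length_nm=1.0)
        assert classify_regime(tr)[0] == "unconverged"


class TestCriticalVelocity:
    def test_bracketed_grid(self):
        regimes = {1.0: "stick-slip", 3.0: "stick-slip",
                   6.0: "smooth", 8.0: "smooth"}
        vc, bracket = critical_velocity(regimes)
        assert vc == pytest.approx(4.5)
        assert bracket == (3.0, 6.0)

    def test_all_smooth_not_bracketed(self):
        with pytest.raises(ValueError, match="not bracketed"):
            critical_velocity({2.0: "smooth", 5.0: "smooth"})

    def test_synthetic_boundary_recovered(self):
        boundary = 4.0
        grid = {v: ("stick-slip" if v < boundary else "smooth")
                for v in [1.0, 2.0, 3.5, 4.5, 6.0]}
        vc, _ = critical_velocity(grid)
        assert abs(vc - boundary) <= 0.5


class TestSummaries:
    def test_flat_and_sawtooth_statistics(self):
        flat = synthetic_trace("flat", s_max=4.0)
        s = summarize_trace(flat, discard_nm=0.0)
        assert s.mean_shear_mpa == pytest.approx(4.0)
        assert s.rms_shear_mpa == pytest.approx(0.0, abs=1e-12)
        saw = synthetic_trace("sawtooth", length_nm=20.0, period_nm=2.0,
                              s_max=6.0)
        s2 = summarize_trace(saw, discard_nm=0.0)
        assert s2.regime == "stick-slip"
        assert s2.mean_shear_mpa == pytest.approx(3.0, rel=0.05)
        assert s2.rms_shear_mpa == pytest.approx(6.0 / np.sqrt(12),
                                                 rel=0.08)

    def test_discard_rule_applies_first_slip(self):
        saw = synthetic_trace("sawtooth", length_nm=20.0, period_nm=3.0)
        s = summarize_trace(saw, discard_nm=1.0)
        # first slip is near 3 nm > discard 1 nm: retained window starts there
        assert s.discard_nm >= 2.5

    def test_rho_only_for_stick_slip(self):
        flat = synthetic_trace("flat", s_max=4.0)
        assert np.isnan(summarize_trace(flat, 0.0).rho_uh)
        saw = synthetic_trace("sawtooth", length_nm=20.0, period_nm=2.0)
        s = summarize_trace(saw, 0.0)
        # fixture builds U = -c * h exactly anticorrelated
        assert s.rho_uh == pytest.approx(-1.0, abs=1e-9)


class TestClosedFormEstimates:
    def test_transient_bond_energy_published_value(self):
        """Cation bridging two opposing anions at 0.41 nm vs the 0.51 nm
        flat arrangement: ~85 meV, comparable to k_B T at ~1000 K."""
        de = transient_bond_energy(0.25, 0.41, 0.51)
        assert 83.0 <= de <= 88.0
        from zwitterslide.units import KC
        assert de == pytest.approx(
            2 * KC * 0.0625 * (1 / 0.41 - 1 / 0.51) * 1e3, rel=1e-12)
        assert transient_bond_energy(0.0, 0.41, 0.51) == 0.0
        assert transient_bond_energy(0.25, 0.47, 0.47) == 0.0

    def test_thermal_energy_values(self):
        assert thermal_energy(1000.0) == pytest.approx(86.17, abs=0.1)
        assert thermal_energy(0.0) == 0.0
        assert thermal_energy(300.0) == pytest.approx(25.85, abs=0.03)
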