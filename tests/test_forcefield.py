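"""Force field: closed forms, gradient consistency, masks, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zwitterslide.forcefield import (ForceField, ForceFieldParams,
                                     morse_energy_force,
                                     transient_coulomb_pair_energy)
from zwitterslide.units import KC, N_M_TO_EV_NM2

from helpers import (toy_config, brute_morse_energy, brute_coulomb_real,
                     check_force_consistency)


K_BOND = 480.0 * N_M_TO_EV_NM2   # eV/nm^2


class TestBonds:
    def test_equilibrium_bond_is_zero(self):
        cfg = toy_config([[1.0, 1.0, 1.0], [1.16, 1.0, 1.0]],
                         species=[0, 1], layer=[0, 0],
                         molecule_id=[0, 0], bonds=[[0, 1]], bond_slot=[0])
        e, f = ForceField(cfg).bond_energy_forces()
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() < 1e-9

    def test_stretched_bond_closed_form_and_gradient(self):
        """CA-R1 at 0.17 nm vs r_eq 0.16 nm: E = (k/2) dr^2 with the printed
        480 N/m as the literal second derivative."""
        cfg = toy_config([[1.0, 1.0, 1.0], [1.17, 1.0, 1.0]],
                         species=[0, 1], layer=[0, 0],
                         molecule_id=[0, 0], bonds=[[0, 1]], bond_slot=[0])
        ff = ForceField(cfg)
        e, f = ff.bond_energy_forces()
        assert e == pytest.approx(0.5 * K_BOND * 0.01 ** 2, rel=1e-9)
        rng = np.random.default_rng(1)
        check_force_consistency(lambda p: ff.bond_energy_forces(p)[0],
                                lambda p: ff.bond_energy_forces(p)[1],
                                cfg.positions, rng, n_checks=2, rtol=1e-6)

    def test_fresh_system_bonds_at_equilibrium(self, mini12_neutral):
        ff = ForceField(mini12_neutral)
        e, _ = ff.bond_energy_forces()
        assert e == pytest.approx(0.0, abs=1e-16)

    def test_degenerate_bond_raises(self):
        cfg = toy_config([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
                         species=[0, 1], layer=[0, 0],
                         molecule_id=[0, 0], bonds=[[0, 1]], bond_slot=[0])
        with pytest.raises(FloatingPointError):
            ForceField(cfg).bond_energy_forces()


def bent_angle_config(theta_deg):
    """NP2-NP1-AN triplet with interior angle theta, bent in the xz plane."""
    th = math.radians(theta_deg)
    # NP1->NP2 points down; NP1->AN makes the interior angle with it
    pos = [[1.0, 1.0, 1.0],                                    # NP2
           [1.0, 1.0, 1.67],                                   # NP1
           [1.0 + 0.16 * math.sin(th), 1.0,
            1.67 - 0.16 * math.cos(th)]]                       # AN
    return toy_config(pos, species=[6, 5, 4], layer=[0, 0, 0],
                      molecule_id=[0, 0, 0],
                      bonds=[[0, 1], [1, 2]], bond_slot=[5, 4],
                      angles=[[2, 1, 0]], angle_slot=[4])


class TestAngles:
    def test_equilibrium_angle_zero_energy(self):
        # template slot 4 is the NP2-NP1-AN kink at 111 deg
        cfg = bent_angle_config(111.0)
        e, _ = ForceField(cfg).angle_energy_forces()
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_bent_angle_positive_energy_and_restoring(self):
        """Built at 100 deg (eq 111): positive energy, and a short descent
        along the force direction lowers the energy (restoring torque)."""
        cfg = bent_angle_config(100.0)
        ff = ForceField(cfg)
        e0, f = ff.angle_energy_forces()
        assert e0 == pytest.approx(
            0.5 * 3.0 * math.radians(11.0) ** 2, rel=1e-6)
        step = f / max(np.abs(f).max(), 1e-12)
        for eps in (1e-4, 1e-3):
            e1, _ = ff.angle_energy_forces(cfg.positions + eps * step)
            assert e1 < e0
        rng = np.random.default_rng(2)
        check_force_consistency(lambda p: ff.angle_energy_forces(p)[0],
                                lambda p: ff.angle_energy_forces(p)[1],
                                cfg.positions, rng, n_checks=3, rtol=1e-5)

    def test_angle_forces_sum_to_zero(self):
        cfg = bent_angle_config(47.0)
        _, f = ForceField(cfg).angle_energy_forces()
        assert np.abs(f.sum(axis=0)).max() < 1e-12

    def test_tilt_restraint_vertical_zero_and_restoring(self):
        """The tail-verticality restraint vanishes for a vertical NP2->NP1
        bond, penalizes tilt quadratically, and its force is the exact
        gradient."""
        import zwitterslide as zw
        from zwitterslide.fixtures import mini_system
        cfg = mini_system(8, charge_on=False, seed=0).config
        ff = ForceField(cfg)
        e0, f0 = ff.tilt_energy_forces()   # built pose: NP bonds vertical
        assert e0 == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f0).max() < 1e-9
        rng = np.random.default_rng(4)
        pos = cfg.positions + 0.05 * rng.standard_normal(
            cfg.positions.shape)
        e1, _ = ff.tilt_energy_forces(pos)
        assert e1 > 0.0
        check_force_consistency(lambda p: ff.tilt_energy_forces(p)[0],
                                lambda p: ff.tilt_energy_forces(p)[1],
                                pos, rng, n_checks=3, rtol=1e-5)

    def test_coincident_beads_raise(self):
        cfg = toy_config([[1, 1, 1], [1, 1, 1], [1, 1, 2]],
                         species=[6, 5, 4], layer=[0, 0, 0],
                         molecule_id=[0, 0, 0], angles=[[2, 1, 0]],
                         angle_slot=[4])
        with pytest.raises(FloatingPointError):
            ForceField(cfg).angle_energy_forces()


class TestMorseScalar:
    def test_zero_at_cutoff(self):
        v, f = morse_energy_force(1.0, 0.010, 0.41)
        assert v == 0.0 and f == 0.0
        v, f = morse_energy_force(1.5, 0.010, 0.41)
        assert v == 0.0 and f == 0.0

    def test_value_at_minimum_matches_closed_form(self):
        """V(r0) = -D0 - M(Rc) - (r0-Rc) M'(Rc); force equals -dV/dr by
        central difference."""
        D0, r0, a, rc = 0.010, 0.41, 15.0, 1.0
        ec = math.exp(-a * (rc - r0))
        mc = D0 * (ec * ec - 2 * ec)
        dmc = D0 * 2 * a * (ec - ec * ec)
        v, f = morse_energy_force(r0, D0, r0, a, rc)
        assert v == pytest.approx(-D0 - mc - (r0 - rc) * dmc, rel=1e-12)
        eps = 1e-7
        vp, _ = morse_energy_force(r0 + eps, D0, r0, a, rc)
        vm, _ = morse_energy_force(r0 - eps, D0, r0, a, rc)
        assert f == pytest.approx(-(vp - vm) / (2 * eps), abs=1e-6)

    def test_masked_pair_is_identically_zero(self):
        r = np.linspace(0.05, 1.5, 200)
        v, f = morse_energy_force(r, 0.0, 0.41)
        assert np.all(v == 0.0) and np.all(f == 0.0)

    @given(D0=st.floats(1e-4, 10.0), r0=st.floats(0.2, 0.9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_continuity_at_cutoff(self, D0, r0):
        """|V(Rc - eps)| and |F(Rc - eps)| tend to zero as eps -> 0 for any
        well parameters (shift + linear tail make the cutoff C1)."""
        eps = np.array([1e-2, 1e-4, 1e-6, 1e-8])
        v, f = morse_energy_force(1.0 - eps, D0, r0)
        assert np.all(np.abs(v[1:]) <= np.abs(v[:-1]) + 1e-15)
        assert np.all(np.abs(f[1:]) <= np.abs(f[:-1]) + 1e-12)
        assert abs(v[-1]) < 1e-6 * max(D0, 1.0)
        assert abs(f[-1]) < 1e-4 * max(D0, 1.0)


class TestPairSums:
    def test_neighbor_list_matches_all_pairs_oracle(self, mini8_charged,
                                                    jiggled_mini12,
                                                    mini12_neutral):
        """Tabulated neighbour-list sums equal a brute-force O(N^2) numpy
        re-implementation of the masked Morse + erfc Coulomb energies."""
        ff = ForceField(mini8_charged)
        e_m, _ = ff.morse_energy_forces()
        assert e_m == pytest.approx(brute_morse_energy(mini8_charged, ff),
                                    rel=1e-6, abs=1e-7)
        e_c, _ = ff.coulomb_real_space()
        assert e_c == pytest.approx(brute_coulomb_real(mini8_charged, ff),
                                    rel=1e-6, abs=1e-9)
        ff2 = ForceField(mini12_neutral)
        e_m2, _ = ff2.morse_energy_forces(jiggled_mini12)
        assert e_m2 == pytest.approx(
            brute_morse_energy(mini12_neutral, ff2, jiggled_mini12),
            rel=1e-6, abs=1e-7)


class TestGradients:
    """Criterion-style check: every term's force equals the central
    difference of its energy to better than 1e-5 relative."""

    def test_each_term_matches_numerical_gradient(self, mini8_charged,
                                                  jiggled_mini12,
                                                  mini12_neutral):
        rng = np.random.default_rng(3)
        ff = ForceField(mini12_neutral)
        pos = jiggled_mini12
        for efn, ffn in [
            (lambda p: ff.bond_energy_forces(p)[0],
             lambda p: ff.bond_energy_forces(p)[1]),
            (lambda p: ff.angle_energy_forces(p)[0],
             lambda p: ff.angle_energy_forces(p)[1]),
            (lambda p: ff.morse_energy_forces(p)[0],
             lambda p: ff.morse_energy_forces(p)[1]),
        ]:
            check_force_consistency(efn, ffn, pos, rng, n_checks=4,
                                    rtol=1e-5)
        ffq = ForceField(mini8_charged)
        posq = mini8_charged.positions + 0.01 * rng.standard_normal(
            mini8_charged.positions.shape)
        check_force_consistency(
            lambda p: ffq.coulomb_real_space(p)[0],
            lambda p: ffq.coulomb_real_space(p)[1],
            posq, rng, n_checks=3, rtol=1e-5)
        check_force_consistency(
            lambda p: ffq.coulomb_reciprocal(p)[0],
            lambda p: ffq.coulomb_reciprocal(p)[1],
            posq, rng, n_checks=3, rtol=1e-4, min_force=1e-3)


class TestMasksAndTotals:
    def test_rigid_rigid_pairs_masked(self):
        """Moving a SUP rigid bead near a SUB rigid bead changes nothing
        (D0 = 0 for all rigid-rigid combinations)."""
        cfg = toy_config([[1.0, 1.0, 0.0], [1.5, 1.0, 0.3]],
                         species=[-1, -1], layer=[0, 1],
                         molecule_id=[-1, -1])
        ff = ForceField(cfg)
        e1, _ = ff.morse_energy_forces()
        pos = cfg.positions.copy()
        pos[1] = [1.05, 1.0, 0.05]
        e2, _ = ff.morse_energy_forces(pos)
        assert e1 == 0.0 and e2 == 0.0

    def test_cross_layer_restricted_to_heads(self):
        """A SUB NP1 bead and a SUP head bead do not interact; two head
        beads across layers do."""
        np1_vs_head = toy_config([[1.0, 1.0, 0.0], [1.0, 1.0, 0.41]],
                                 species=[5, 0], layer=[0, 1],
                                 molecule_id=[0, 1])
        e1, _ = ForceField(np1_vs_head).morse_energy_forces()
        assert e1 == 0.0
        head_vs_head = toy_config([[1.0, 1.0, 0.0], [1.0, 1.0, 0.41]],
                                  species=[0, 0], layer=[0, 1],
                                  molecule_id=[0, 1])
        e2, _ = ForceField(head_vs_head).morse_energy_forces()
        assert e2 < -0.009   # near the -D0 = -0.010 eV well

    def test_intramolecular_exclusions(self):
        """1-2, 1-3, 1-4 pairs carry no Morse term; the 1-5 (CA..AN) pair
        does."""
        # linear 5-bead chain, 0.2 nm spacing along z
        pos = [[1.0, 1.0, 0.2 * k] for k in range(5)]
        cfg = toy_config(pos, species=[0, 1, 2, 3, 4], layer=[0] * 5,
                         molecule_id=[0] * 5,
                         bonds=[[0, 1], [1, 2], [2, 3], [3, 4]],
                         bond_slot=[0, 1, 2, 3])
        ff = ForceField(cfg)
        e, _ = ff.morse_energy_forces()
        # only the CA(0)..AN(4) 1-5 pair at 0.8 nm contributes
        expect, _ = morse_energy_force(0.8, 0.010, 0.41)
        assert e == pytest.approx(expect, rel=1e-5)

    def test_two_opposite_charges_bare_energy(self):
        """+-0.25 e at 0.41 nm, unscreened: E = -kC q^2 / r ~ -0.2195 eV."""
        e = transient_coulomb_pair_energy(0.25, -0.25, 0.41)
        assert e == pytest.approx(-0.2195, abs=2e-4)
        assert e == pytest.approx(-KC * 0.0625 / 0.41, rel=1e-12)

    def test_net_force_vanishes_without_drive(self, mini8_charged,
                                              mini12_neutral,
                                              jiggled_mini12):
        for cfg, pos in ((mini8_charged, None),
                         (mini12_neutral, jiggled_mini12)):
            ff = ForceField(cfg)
            _, frc, _ = ff.total_energy_forces(pos)
            assert abs(frc[:, 0].sum()) < 1e-8
            assert abs(frc[:, 1].sum()) < 1e-8

    def test_total_is_sum_of_parts(self, mini8_charged):
        ff = ForceField(mini8_charged)
        u, frc, comps = ff.total_energy_forces()
        assert u == pytest.approx(sum(comps.values()), rel=1e-12)
        e_b, f_b = ff.bond_energy_forces()
        e_a, f_a = ff.angle_energy_forces()
        e_t, f_t = ff.tilt_energy_forces()
        e_m, f_m = ff.morse_energy_forces()
        e_cr, f_cr = ff.coulomb_real_space()
        e_ck, f_ck = ff.coulomb_reciprocal()
        assert u == pytest.approx(e_b + e_a + e_t + e_m + e_cr + e_ck,
                                  rel=1e-10)
        assert np.allclose(frc, f_b + f_a + f_t + f_m + f_cr + f_ck,
                           atol=1e-9)
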