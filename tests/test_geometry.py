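"""Geometry: commensuration search, layer construction, system assembly."""

import math

import numpy as np
import pytest

from zwitterslide import geometry as G
from zwitterslide.fixtures import mini_system


def brute_force_commensurate(sol, n_points=40):
    """Oracle: every lattice point of both rotated lattices, translated by
    each cell vector, must land on a lattice point again (integer basis
    coordinates)."""
    a = sol.molecule_spacing
    for sign in (-0.5, +0.5):
        th = math.radians(sign * sol.phi_deg)
        c, s = math.cos(th), math.sin(th)
        e1 = np.array([a * c, a * s])
        e2 = np.array([a * (0.5 * c - 0.5 * math.sqrt(3) * s),
                       a * (0.5 * s + 0.5 * math.sqrt(3) * c)])
        basis = np.column_stack([e1, e2])
        rng = np.random.default_rng(0)
        ij = rng.integers(-30, 30, size=(n_points, 2))
        pts = (basis @ ij.T).T
        for vec in ([sol.l_x, 0.0], [0.0, sol.l_y]):
            shifted = pts + np.array(vec)
            coords = np.linalg.solve(basis, shifted.T)
            assert np.max(np.abs(coords - np.round(coords))) < 1e-8
    return True


class TestCommensurationSearch:
    def test_recovers_published_supercell(self):
        """The coincidence search reproduces the printed rotation angle and
        rectangular cell (phi = 19.65 deg, 8.32 x 14.41 nm, 206 molecules)."""
        sol = G.find_commensurate_supercell(
            0.82, (15.0, 25.0), 15.0, 1e-3, target_cell=(8.32, 14.41))
        assert sol.phi_deg == pytest.approx(19.65, abs=0.01)
        assert sol.l_x == pytest.approx(8.32, abs=0.01)
        assert sol.l_y == pytest.approx(14.41, abs=0.01)
        assert sol.n_molecules == 206
        assert sol.mismatch <= 1e-3

    def test_aligned_lattices_minimal_cell(self):
        """With rotation disabled the minimal rectangle is a x sqrt(3) a."""
        sol = G.find_commensurate_supercell(0.82, (0.0, 1.0), 5.0, 1e-3)
        assert sol.phi_deg == 0.0
        assert sol.l_x == pytest.approx(0.82, rel=1e-9)
        assert sol.l_y == pytest.approx(0.82 * math.sqrt(3.0), rel=1e-9)
        assert sol.n_molecules == 2

    @pytest.mark.parametrize("spacing", [0.82, 1.0])
    def test_solutions_verified_by_lattice_overlap_oracle(self, spacing):
        """Every returned cell exactly tiles both rotated lattices
        (brute-force translated-image check)."""
        sols = G.enumerate_commensurate_cells(spacing, (15.0, 25.0), 18.0,
                                              1e-3)
        assert sols
        for sol in sols[:6]:
            assert brute_force_commensurate(sol)

    def test_no_solution_raises(self):
        with pytest.raises(G.CommensurationError):
            G.find_commensurate_supercell(0.82, (16.9, 17.0), 3.0, 1e-3)

    def test_smallest_cell_wins_and_desk_scale(self):
        best = G.find_commensurate_supercell(0.82, (15.0, 25.0), 15.0, 1e-3)
        all_cells = G.enumerate_commensurate_cells(0.82, (15.0, 25.0), 15.0,
                                                   1e-3)
        assert best.l_x * best.l_y == min(c.l_x * c.l_y for c in all_cells)
        desk = G.desk_cell()
        assert 30 <= desk.n_molecules <= 50
        assert min(desk.l_x, desk.l_y) > 3.7   # room for minimum image


class TestBuildLayer:
    def test_published_counts(self):
        """824 rigid beads and 206 anchors per layer in the full-scale cell."""
        sol = G.full_cell()
        spec = G.LatticeSpec(rotation_phi=sol.phi_deg)
        layer = G.build_layer(spec, sol.cell, G.SUB, 0.0)
        assert layer.n_rigid == 824
        assert layer.n_anchors == 206

    def test_rigid_is_four_times_anchors_smallest_cell(self):
        """The anchor sublattice takes 1 of 4 nodes in any rectangular cell
        (a 1-anchor rectangle does not exist for a triangular lattice; the
        smallest rectangle holds 2 anchors and 8 nodes)."""
        spec = G.LatticeSpec(rotation_phi=0.0)
        cell = G.Supercell(0.82, 0.82 * math.sqrt(3.0))
        layer = G.build_layer(spec, cell, G.SUB, 0.0)
        assert layer.n_rigid == 8
        assert layer.n_anchors == 2

    def test_anchor_nearest_neighbor_distance(self):
        """All-pairs scan: anchor NN distance equals a = 0.82 nm to 1e-6."""
        sol = G.desk_cell()
        spec = G.LatticeSpec(rotation_phi=sol.phi_deg)
        layer = G.build_layer(spec, sol.cell, G.SUP, 0.0)
        xy = layer.anchor_xy
        d = xy[:, None, :] - xy[None, :, :]
        d[..., 0] -= sol.l_x * np.round(d[..., 0] / sol.l_x)
        d[..., 1] -= sol.l_y * np.round(d[..., 1] / sol.l_y)
        r = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(r, np.inf)
        assert abs(r.min() - 0.82) < 1e-6

    def test_periodicity_of_rigid_lattice(self):
        """Translating any rigid bead by a cell vector lands on a bead."""
        sol = G.desk_cell()
        spec = G.LatticeSpec(rotation_phi=sol.phi_deg)
        layer = G.build_layer(spec, sol.cell, G.SUB, 0.0)
        xy = layer.rigid_xy
        for vec in ([sol.l_x, 0.0], [0.0, sol.l_y]):
            shifted = xy + vec
            shifted[:, 0] %= sol.l_x
            shifted[:, 1] %= sol.l_y
            d = shifted[:, None, :] - xy[None, :, :]
            d[..., 0] -= sol.l_x * np.round(d[..., 0] / sol.l_x)
            d[..., 1] -= sol.l_y * np.round(d[..., 1] / sol.l_y)
            nearest = np.sqrt((d ** 2).sum(-1)).min(axis=1)
            assert nearest.max() < 1e-6

    def test_incommensurate_cell_rejected(self):
        spec = G.LatticeSpec(rotation_phi=19.652859631664562)
        with pytest.raises(G.GeometryError, match="mismatch"):
            G.build_layer(spec, G.Supercell(5.0, 5.0), G.SUB, 0.0)


class TestAssembleSystem:
    def test_published_system_counts_and_neutrality(self):
        system = G.build_system()
        assert system.n_particles == 2 * (206 * 7 + 824) == 4532
        assert system.n_molecules_per_layer == 206
        assert abs(float(system.charges.sum())) < 1e-12
        assert int(system.frozen.sum()) == 824
        assert int(system.rigid_translating.sum()) == 824

    def test_areal_density_matches_model(self):
        system = G.build_system(G.desk_cell())
        rho = system.molecule_areal_density()
        assert rho == pytest.approx(1.72, abs=0.01)
        # identical to the closed form 2/(sqrt3 a^2) within 0.5%
        assert rho == pytest.approx(2 / (math.sqrt(3) * 0.82 ** 2),
                                    rel=5e-3)

    def test_charge_free_control_identical_geometry(self):
        a = G.build_system(G.desk_cell(), charge_on=True, seed=3)
        b = G.build_system(G.desk_cell(), charge_on=False, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.all(b.charges == 0.0)
        assert abs(a.charges[a.species == 0] - 0.25).max() < 1e-12

    def test_mirror_construction(self):
        """Before dynamics the SUP molecule set is the z mirror of SUB:
        per-bead z offsets from the respective rigid plane are equal and
        opposite, bead for bead."""
        system = G.build_system(G.desk_cell(), seed=5)
        z = system.positions[:, 2]
        z_sub_plane = z[system.frozen].mean()
        z_sup_plane = z[system.rigid_translating].mean()
        for sp in range(7):
            sub = np.sort(z[(system.species == sp) & (system.layer == 0)]
                          - z_sub_plane)
            sup = np.sort(z_sup_plane
                          - z[(system.species == sp) & (system.layer == 1)])
            assert np.allclose(sub, sup, atol=1e-9)

    def test_min_separation_guard(self):
        """Collapsing the gap until the rigid planes coincide puts beads on
        top of each other and must be rejected."""
        spec = G.LatticeSpec(rotation_phi=0.0)
        cell = G.Supercell(2 * 0.82, 0.82 * math.sqrt(3.0))
        tmpl = G.MoleculeTemplate()
        sub = G.build_layer(spec, cell, G.SUB, 0.0)
        sup = G.build_layer(spec, cell, G.SUP, 0.0, x_offset=0.0)
        gap = -2.0 * G.chain_extent(tmpl)
        with pytest.raises(G.GeometryError, match="min distance"):
            G.assemble_system(tmpl, sub, sup, cell, initial_gap=gap)

    def test_mini_fixture_counts(self):
        fx = mini_system(4, charge_on=True, seed=0)
        assert fx.config.n_particles == 88
        assert float(fx.config.charges.sum()) == 0.0
        assert fx.config.n_molecules_per_layer == 4
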