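"""Shared test utilities: hand-built configurations and brute-force oracles.

Every oracle here is implemented independently of the package kernels
(plain numpy, closed forms, direct lattice sums) so the tests compare two
separate routes to the same physics.
"""

import numpy as np

from zwitterslide.geometry import (SystemConfiguration, Supercell,
                                   MoleculeTemplate)
from zwitterslide.units import KC


def toy_config(positions, species, layer, charges=None, molecule_id=None,
               bonds=None, bond_slot=None, angles=None, angle_slot=None,
               box=(4.0, 4.0), masses=None, template=None):
    """Assemble a hand-specified SystemConfiguration for kernel tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    species = np.asarray(species, dtype=np.int64)
    layer = np.asarray(layer, dtype=np.int64)
    charges = (np.zeros(n) if charges is None
               else np.asarray(charges, dtype=float))
    molecule_id = (np.where(species >= 0, np.arange(n), -1)
                   if molecule_id is None
                   else np.asarray(molecule_id, dtype=np.int64))
    bonds = (np.empty((0, 2), dtype=np.int64) if bonds is None
             else np.asarray(bonds, dtype=np.int64).reshape(-1, 2))
    bond_slot = (np.zeros(len(bonds), dtype=np.int64) if bond_slot is None
                 else np.asarray(bond_slot, dtype=np.int64))
    angles = (np.empty((0, 3), dtype=np.int64) if angles is None
              else np.asarray(angles, dtype=np.int64).reshape(-1, 3))
    angle_slot = (np.zeros(len(angles), dtype=np.int64) if angle_slot is None
                  else np.asarray(angle_slot, dtype=np.int64))
    masses = (np.full(n, 50.0) if masses is None
              else np.asarray(masses, dtype=float))
    zext = float(np.ptp(positions[:, 2])) if n else 1.0
    return SystemConfiguration(
        positions=positions, species=species, layer=layer,
        molecule_id=molecule_id, charges=charges, masses_amu=masses,
        bonds=bonds, bond_slot=bond_slot, angles=angles,
        angle_slot=angle_slot,
        box=Supercell(box[0], box[1], z_extent=zext),
        template=template or MoleculeTemplate())


# ---------------------------------------------------------------------------
# independent energy/force oracles
# ---------------------------------------------------------------------------

def min_image(d, lx, ly):
    d = np.array(d, dtype=float)
    d[..., 0] -= lx * np.round(d[..., 0] / lx)
    d[..., 1] -= ly * np.round(d[..., 1] / ly)
    return d


def brute_morse_energy(config, ff, positions=None):
    """All-pairs shifted-Morse sum with the force-field mask (pure numpy)."""
    pos = config.positions if positions is None else positions
    box = config.box
    cid = config.class_id
    D0m, r0m = ff.morse_matrix
    alpha = ff.params.morse_alpha
    rc = ff.params.morse_cutoff
    excl = {tuple(p) for p in ff.excl_pairs}
    e = 0.0
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            d0 = D0m[cid[i], cid[j]]
            if d0 == 0.0:
                continue
            d = min_image(pos[i] - pos[j], box.l_x, box.l_y)
            r = np.sqrt(d @ d)
            if r >= rc:
                continue
            r0 = r0m[cid[i], cid[j]]
            em = np.exp(-alpha * (r - r0))
            ec = np.exp(-alpha * (rc - r0))
            m = d0 * (em * em - 2 * em)
            mc = d0 * (ec * ec - 2 * ec)
            dmc = d0 * (-2 * alpha * ec * ec + 2 * alpha * ec)
            e += m - mc - (r - rc) * dmc
    return e


def brute_coulomb_real(config, ff, positions=None):
    """All-pairs erfc-damped sum within the Coulomb cutoff (pure scipy)."""
    from scipy.special import erfc
    pos = config.positions if positions is None else positions
    box = config.box
    q = config.charges
    a = ff.ewald_alpha
    rc = ff.r_cut_coul
    excl = {tuple(p) for p in ff.excl_pairs}
    e = 0.0
    n = len(pos)
    for i in range(n):
        if q[i] == 0.0:
            continue
        for j in range(i + 1, n):
            if q[j] == 0.0 or (i, j) in excl:
                continue
            d = min_image(pos[i] - pos[j], box.l_x, box.l_y)
            r = np.sqrt(d @ d)
            if r >= rc:
                continue
            e += KC * q[i] * q[j] * erfc(a * r) / r
    return e


def direct_coulomb_periodic(positions, charges, lx, ly, radius=300.0,
                            with_forces=False):
    """Direct Coulomb lattice sum, xy-periodic, z open.

    Whole image cells are included out to ``radius`` (cutting the shift
    vector, not pair distances, which preserves cell neutrality); converges
    ~1/R for neutral cells with zero net in-plane dipole.
    """
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    nx = int(radius / lx)
    ny = int(radius / ly)
    sx = np.arange(-nx, nx + 1) * lx
    sy = np.arange(-ny, ny + 1) * ly
    gx, gy = np.meshgrid(sx, sy, indexing="ij")
    shifts = np.column_stack([gx.ravel(), gy.ravel(),
                              np.zeros(gx.size)])
    shifts = shifts[(shifts[:, 0] ** 2 + shifts[:, 1] ** 2)
                    < radius * radius]
    n = len(q)
    energy = 0.0
    forces = np.zeros((n, 3))
    for i in range(n):
        for j in range(n):
            dv = (pos[i] - pos[j])[None, :] + shifts
            r = np.sqrt((dv ** 2).sum(axis=1))
            if i == j:
                r[r < 1e-9] = np.inf
            energy += 0.5 * KC * q[i] * q[j] * np.sum(1.0 / r)
            if with_forces:
                forces[i] += KC * q[i] * q[j] * np.sum(
                    dv / r[:, None] ** 3, axis=0)
    if with_forces:
        return energy, forces
    return energy


def numerical_gradient(f, positions, indices, eps=1e-6):
    """Central-difference -dE/dr at selected (particle, axis) pairs."""
    out = {}
    for idx, ax in indices:
        p1 = positions.copy()
        p1[idx, ax] += eps
        p2 = positions.copy()
        p2[idx, ax] -= eps
        out[(idx, ax)] = -(f(p1) - f(p2)) / (2 * eps)
    return out


def check_force_consistency(energy_fn, force_fn, positions, rng,
                            n_checks=6, eps=1e-6, rtol=1e-5,
                            min_force=1e-4):
    """Assert analytic forces match central differences of the energy.

    Relative error is measured against max(|F|, min_force) to avoid
    amplifying round-off where the true force is essentially zero.
    """
    n = len(positions)
    f_ana = force_fn(positions)
    checks = 0
    tries = 0
    while checks < n_checks and tries < 20 * n_checks:
        tries += 1
        idx = int(rng.integers(n))
        ax = int(rng.integers(3))
        if abs(f_ana[idx, ax]) < min_force:
            continue
        num = numerical_gradient(energy_fn, positions, [(idx, ax)],
                                 eps)[(idx, ax)]
        denom = max(abs(num), min_force)
        assert abs(f_ana[idx, ax] - num) / denom < rtol, (
            f"force mismatch at particle {idx} axis {ax}: "
            f"analytic {f_ana[idx, ax]} vs numeric {num}")
        checks += 1
    assert checks == n_checks, "could not find enough non-zero forces"
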