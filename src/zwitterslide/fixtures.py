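"""Deterministic miniature systems and synthetic traces for fast testing.

``mini_system`` builds a small aligned-lattice (phi = 0) bilayer with the
same molecule template, anchoring rule and topology as the full system, so
every geometric and force-field invariant can be exercised in milliseconds.
``synthetic_trace`` fabricates friction traces with analytically known
statistics (mean, RMS, slip-event count) for the analysis module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (LatticeSpec, Supercell, MoleculeTemplate,
                       SystemConfiguration, build_layer, assemble_system,
                       GeometryError, SUB, SUP)
from .protocol import TRACE_COLUMNS


@dataclass
class Fixture:
    """A named miniature system/trace with brute-force ground truth."""
    name: str
    config: SystemConfiguration | None
    ground_truth: dict


def _factor_pairs(n_cells: int):
    """Tile factors (k, m) maximizing the smallest box edge (k a, m sqrt3 a)."""
    best = None
    for k in range(1, n_cells + 1):
        if n_cells % k:
            continue
        m = n_cells // k
        score = min(k * 1.0, m * math.sqrt(3.0))
        if best is None or score > best[0]:
            best = (score, k, m)
    return best[1], best[2]


def mini_system(n_mol_per_layer: int, charge_on: bool = True,
                seed: int = 0, a: float = 0.82,
                initial_gap: float = 0.5, tilt_deg: float = 15.0) -> Fixture:
    """Aligned-lattice miniature bilayer with ``n_mol_per_layer`` molecules.

    The primitive rectangular tile of a triangular lattice (a x sqrt(3) a)
    holds 2 molecules, so n must be even; the tile grid is chosen as close
    to square as possible.  Total particle count is 2 (7 n + 4 n) = 22 n.
    """
    if n_mol_per_layer < 2 or n_mol_per_layer % 2:
        raise GeometryError("n_mol_per_layer must be even and >= 2")
    n_cells = n_mol_per_layer // 2
    k, m = _factor_pairs(n_cells)
    cell = Supercell(k * a, m * a * math.sqrt(3.0))
    spec = LatticeSpec(node_spacing=0.5 * a, molecule_spacing=a,
                       rotation_phi=0.0)
    template = MoleculeTemplate(q=0.25 if charge_on else 0.0)
    sub = build_layer(spec, cell, SUB, 0.0)
    sup = build_layer(spec, cell, SUP, 0.0, x_offset=0.25 * a)
    config = assemble_system(template, sub, sup, cell,
                             initial_gap=initial_gap, charge_on=charge_on,
                             seed=seed, tilt_deg=tilt_deg)
    truth = {
        "n_particles": 22 * n_mol_per_layer,
        "n_molecules_per_layer": n_mol_per_layer,
        "n_rigid_per_layer": 4 * n_mol_per_layer,
        "net_charge": 0.0,
        "areal_density": n_mol_per_layer / cell.area,
    }
    return Fixture(name=f"mini-{n_mol_per_layer}"
                        f"{'q' if charge_on else '0'}-s{seed}",
                   config=config, ground_truth=truth)


def single_chain_system(charge_on: bool = False, seed: int = 0,
                        a: float = 0.82, tilt_deg: float = 15.0) -> Fixture:
    """One anchored molecule over a small rigid patch (thermostat tests).

    A single 7-bead chain is planted on one anchor of a 3 x 2-tile SUB
    lattice; the SUP layer is reduced to a lone far-away rigid bead so the
    chain is effectively isolated.  55 particles total.
    """
    k, m = 3, 2
    cell = Supercell(k * a, m * a * math.sqrt(3.0))
    spec = LatticeSpec(node_spacing=0.5 * a, molecule_spacing=a,
                       rotation_phi=0.0)
    template = MoleculeTemplate(q=0.25 if charge_on else 0.0)
    layer = build_layer(spec, cell, SUB, 0.0)
    rng = np.random.default_rng(seed)
    n_r = layer.n_rigid
    anchor = layer.anchor_xy[0]
    from .geometry import _chain_offsets, N_BEADS
    off = _chain_offsets(template, tilt_deg,
                         rng.uniform(0, 2 * math.pi), up=True)
    chain = np.array([anchor[0], anchor[1], 0.0]) + off
    positions = np.vstack([
        np.column_stack([layer.rigid_xy, np.zeros(n_r)]),
        chain,
        np.array([[0.5 * cell.l_x, 0.5 * cell.l_y, 40.0]]),  # lone SUP bead
    ])
    n = n_r + N_BEADS + 1
    species = np.concatenate([np.full(n_r, -1), np.arange(N_BEADS), [-1]])
    layer_tag = np.concatenate([np.zeros(n_r), np.zeros(N_BEADS), [1]])
    mol = np.concatenate([np.full(n_r, -1), np.zeros(N_BEADS), [-1]])
    charges = np.concatenate([np.zeros(n_r),
                              template.charges if charge_on
                              else np.zeros(N_BEADS), [0.0]])
    masses = np.concatenate([np.full(n_r, 50.0),
                             np.asarray(template.masses_amu), [50.0]])
    start = n_r
    bonds = np.array([(start + i, start + j)
                      for i, j in template.bond_pairs], dtype=np.int64)
    angles = np.array([(start + i, start + j, start + k3)
                       for i, j, k3 in template.angle_triplets],
                      dtype=np.int64)
    config = SystemConfiguration(
        positions=positions, species=species.astype(np.int64),
        layer=layer_tag.astype(np.int64), molecule_id=mol.astype(np.int64),
        charges=charges, masses_amu=masses,
        bonds=bonds, bond_slot=np.arange(6, dtype=np.int64),
        angles=angles, angle_slot=np.arange(5, dtype=np.int64),
        box=Supercell(cell.l_x, cell.l_y, z_extent=41.0),
        template=template)
    return Fixture(name=f"chain-{'q' if charge_on else '0'}-s{seed}",
                   config=config,
                   ground_truth={"n_particles": n,
                                 "damped_dof": 2 * N_BEADS})


def synthetic_trace(pattern: str, *, length_nm: float = 10.0,
                    sample_dx: float = 0.01, s_max: float = 5.0,
                    period_nm: float = 2.0, noise_sigma: float = 0.2,
                    seed: int = 0) -> Fixture:
    """Fabricated friction trace with known statistics.

    Patterns: ``flat`` (mean s_max, RMS 0), ``sawtooth`` (mean s_max/2,
    RMS s_max/sqrt(12), floor(length/period) slip events) and ``noisy``
    (white noise around s_max).
    """
    x = np.arange(0.0, length_nm, sample_dx)
    n = len(x)
    rng = np.random.default_rng(seed)
    if pattern == "flat":
        shear = np.full(n, s_max)
        truth = {"mean": s_max, "rms": 0.0, "n_slips": 0}
    elif pattern == "sawtooth":
        phase = (x / period_nm) % 1.0
        shear = s_max * phase
        # resets strictly inside the trace (the final ramp has no drop)
        truth = {"mean": 0.5 * s_max, "rms": s_max / math.sqrt(12.0),
                 "n_slips": int((length_nm - sample_dx) / period_nm)}
    elif pattern == "noisy":
        shear = s_max + noise_sigma * rng.standard_normal(n)
        truth = {"mean": s_max, "rms": noise_sigma, "n_slips": 0}
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    # companion observables: hooking tracks stress, U anticorrelates
    h = np.clip(shear, 0.0, None) / max(s_max, 1e-12) * 10.0
    df = pd.DataFrame({
        "time_ps": x * 200.0, "x_stage": x, "x_sup": x - shear * 1e-3,
        "shear_mpa": shear, "hooking_pct": h, "U_ev": -0.05 * h,
        "d_nm": np.full(n, 3.0), "T_inst_K": np.full(n, 300.0),
    }, columns=list(TRACE_COLUMNS))
    df.attrs["area_nm2"] = 24.46
    df.attrs["k_spring"] = 1.0
    df.attrs["ground_truth"] = truth
    df.attrs["name"] = f"trace-{pattern}-s{seed}"
    return df


def correlated_series(rho: float, n: int, seed: int = 0):
    """Gaussian (U, h) pair with target correlation rho (oracle by design)."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    u = a
    h = rho * a + math.sqrt(1.0 - rho * rho) * b
    return u, h
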