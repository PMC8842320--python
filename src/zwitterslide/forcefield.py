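"""Force field: harmonic bonds/angles, shifted Morse pairs, split Coulomb.

Interactions
------------
* Intramolecular harmonic bonds E = (k/2)(r - r_eq)^2 with k_bond = 480 N/m
  (the printed stiffness is the literal second derivative) and harmonic
  angles E = (k/2)(theta - theta_eq)^2.
* All non-bonded, non-excluded pairs interact through a Morse potential
  M(r) = D0 [e^{-2 a (r-r0)} - 2 e^{-a (r-r0)}], a = 15 nm^-1, with a shift
  and linear tail so V(Rc) = V'(Rc) = 0 at Rc = 1 nm.  Well depths/positions
  are species- and layer-resolved: the default head-head value is
  D0 = 0.010 eV, r0 = 0.41 nm; NP tail beads bind to their own rigid layer
  (D0 = 5 eV, r0 = 0.41 nm) and to the neighbouring molecules' matching tail
  bead (D0 = 5 eV, r0 = a = 0.82 nm).  Cross-layer Morse interactions exist
  only between polar-head beads (CA, R1-R3, AN); all rigid-rigid and
  cross-layer tail/rigid combinations are masked (D0 = 0).
* Coulomb interactions between the +-q head charges are Ewald-split: an
  erfc-damped real-space sum inside r_cut plus a reciprocal-space sum,
  Gaussian self-energy and a slab (Yeh-Berkowitz) dipole correction for the
  xy-periodic geometry, to a force accuracy of 1e-4 eV/nm.  The physical
  total is independent of the split; the splitting parameter is a solver
  knob, not physics.

Pair energies/forces are evaluated from cubic-Hermite tables on an r^2 grid
(the tabulated force is the exact derivative of the tabulated energy;
interpolation error ~1e-9 eV at the defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from . import _kernels
from .geometry import (SystemConfiguration, HEAD_SPECIES, N_BEADS, N_CLASSES,
                       CLASS_SUB_RIGID, CLASS_SUP_RIGID)
from .units import KC, N_M_TO_EV_NM2, DEG


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseParams:
    """Morse well for one species pair: depth D0 (eV), minimum r0 (nm)."""
    D0: float
    r0: float


@dataclass(frozen=True)
class ElectrostaticsParams:
    """Ewald splitting/accuracy knobs for the xy-periodic slab geometry."""
    accuracy: float = 1e-4          # target force error, eV/nm
    r_cut: float | None = None      # real-space cutoff; None = auto from box
    alpha: float | None = None      # splitting parameter; None = auto
    vacuum_factor: float = 3.0      # Lz = vacuum_factor * slab extent
    k_cut_sigmas: float = 3.0       # k-space cutoff = 2*alpha*k_cut_sigmas


@dataclass(frozen=True)
class ExclusionPolicy:
    """Scaling factors for 1-2, 1-3, 1-4 intramolecular non-bonded pairs.

    The default excludes all three from Morse and Coulomb; the 1-5 pair
    (CA..AN in the standard chain) interacts fully.  Only factor 0 ("fully
    excluded") and 1 ("fully interacting") are supported.
    """
    scale_12: float = 0.0
    scale_13: float = 0.0
    scale_14: float = 0.0

    def excluded_separations(self):
        out = []
        for sep, fac in ((1, self.scale_12), (2, self.scale_13),
                         (3, self.scale_14)):
            if fac == 0.0:
                out.append(sep)
            elif fac != 1.0:
                raise ValueError("only scale factors 0 or 1 are supported")
        return tuple(out)


@dataclass
class ForceFieldParams:
    k_bond_n_m: float = 480.0                  # N/m, all six bonds
    k_angle: float = 3.0                       # eV/rad^2, all five angles
    #: tail-verticality restraint (eV/rad^2): harmonic in the angle between
    #: the NP2->NP1 bond and the layer normal.  The printed angle table is
    #: truncated; without this member the relative lateral offset of the
    #: NP1 and NP2 nets is a zero-energy collective mode and the bilayer
    #: cannot support the stated 0-20 MPa loads (it flattens and the
    #: layers interdigitate).  Sized like the other angular springs.
    k_tilt: float = 3.0
    morse_alpha: float = 15.0                  # nm^-1
    morse_cutoff: float = 1.0                  # nm
    morse_default: MorseParams = field(
        default_factory=lambda: MorseParams(0.010, 0.41))
    morse_anchor: MorseParams = field(          # NP1/NP2 <-> own rigid layer
        default_factory=lambda: MorseParams(5.0, 0.41))
    morse_tail: MorseParams = field(            # NP1-NP1, NP2-NP2 same layer
        default_factory=lambda: MorseParams(5.0, 0.82))
    electrostatics: ElectrostaticsParams = field(
        default_factory=ElectrostaticsParams)
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    #: knots of the r^2-grid pair tables; 1025 keeps the working set inside
    #: L2 cache while the cubic interpolant stays ~1e-6 eV accurate
    table_points: int = 2049

    @property
    def k_bond(self) -> float:
        """Bond stiffness in eV/nm^2."""
        return self.k_bond_n_m * N_M_TO_EV_NM2


# ---------------------------------------------------------------------------
# closed-form single-pair operations (used directly and as table sources)
# ---------------------------------------------------------------------------

def morse_energy_force(r, D0, r0=0.41, alpha=15.0, Rc=1.0):
    """Shifted/tilted Morse: V(r) = M(r) - M(Rc) - (r-Rc) M'(Rc) for r < Rc.

    Both V and the radial force -dV/dr vanish identically at and beyond Rc.
    Returns (energy eV, force eV/nm); array-friendly.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Morse evaluated at non-positive distance")
    em = np.exp(-alpha * (r - r0))
    m = D0 * (em * em - 2.0 * em)
    dm = D0 * (-2.0 * alpha * em * em + 2.0 * alpha * em)
    ec = math.exp(-alpha * (Rc - r0))
    mc = D0 * (ec * ec - 2.0 * ec)
    dmc = D0 * (-2.0 * alpha * ec * ec + 2.0 * alpha * ec)
    v = np.where(r < Rc, m - mc - (r - Rc) * dmc, 0.0)
    f = np.where(r < Rc, -(dm - dmc), 0.0)
    if v.ndim == 0:
        return float(v), float(f)
    return v, f


def transient_coulomb_pair_energy(q1, q2, r):
    """Bare (unscreened, non-periodic) Coulomb pair energy, eV."""
    return KC * q1 * q2 / r


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def _cubic_coef_table(fun_and_deriv, s_lo, s_hi, n):
    """Per-interval cubic coefficients of the Hermite interpolant of V(s).

    Sampling V and dV/ds at n knots of a uniform s = r^2 grid, each interval
    stores (c3, c2, c1, c0) with V(u) = ((c3 u + c2) u + c1) u + c0 for the
    local coordinate u in [0, 1); the polynomial derivative is exactly the
    force the kernels apply, so energy and force are mutually consistent to
    machine precision.
    """
    s = np.linspace(s_lo, s_hi, n)
    V, G = fun_and_deriv(s)
    h = (s_hi - s_lo) / (n - 1)
    v0, v1 = V[:-1], V[1:]
    g0, g1 = G[:-1] * h, G[1:] * h
    coef = np.empty((n - 1, 4))
    coef[:, 0] = 2 * v0 + g0 - 2 * v1 + g1          # c3
    coef[:, 1] = -3 * v0 - 2 * g0 + 3 * v1 - g1     # c2
    coef[:, 2] = g0                                 # c1
    coef[:, 3] = v0                                 # c0
    return s_lo, (n - 1) / (s_hi - s_lo), coef


class ForceField:
    """Bound force field: parameters + topology of one SystemConfiguration.

    The heavy lifting lives in :mod:`zwitterslide._kernels`; this class owns
    parameter matrices, interpolation tables, the exclusion map and the Ewald
    setup, and exposes per-term and total energy/force evaluation.
    """

    R_TABLE_MIN = 0.02  # nm; pair tables are clamped below this distance

    def __init__(self, config: SystemConfiguration,
                 params: ForceFieldParams | None = None,
                 neighbor_skin: float = 0.2):
        self.config = config
        self.params = params or ForceFieldParams()
        self.skin = neighbor_skin
        p = self.params
        box = config.box

        # --- bonded parameter arrays ------------------------------------
        tmpl = config.template
        self.bond_i = np.ascontiguousarray(config.bonds[:, 0])
        self.bond_j = np.ascontiguousarray(config.bonds[:, 1])
        self.bond_kk = np.full(len(config.bonds), p.k_bond)
        self.bond_r0 = np.array([tmpl.bond_r_eq[s] for s in config.bond_slot])
        self.ang_i = np.ascontiguousarray(config.angles[:, 0])
        self.ang_j = np.ascontiguousarray(config.angles[:, 1])
        self.ang_k = np.ascontiguousarray(config.angles[:, 2])
        self.ang_kk = np.full(len(config.angles), p.k_angle)
        self.ang_t0 = np.array([tmpl.angle_theta_eq_deg[s] * DEG
                                for s in config.angle_slot])
        # tail-verticality restraint operands: the NP1/NP2 pair of every
        # molecule and its outward normal sign (+z for SUB, -z for SUP)
        np1 = np.flatnonzero(config.species == 5)
        np2 = np.flatnonzero(config.species == 6)
        order1 = np.argsort(config.molecule_id[np1])
        order2 = np.argsort(config.molecule_id[np2])
        self.np1_idx = np.ascontiguousarray(np1[order1])
        self.np2_idx = np.ascontiguousarray(np2[order2])
        self.tilt_sgn = np.where(config.layer[self.np1_idx] == 0, 1.0, -1.0)

        # --- Morse class matrix ------------------------------------------
        self.morse_matrix = self._build_morse_matrix()
        self._build_pair_tables()

        # --- exclusions ----------------------------------------------------
        self.excl_ptr, self.excl_idx, self.excl_pairs = \
            self._build_exclusions()

        # --- per-particle arrays ------------------------------------------
        self.cid = config.class_id
        self.charges = np.ascontiguousarray(config.charges, dtype=float)
        self.group = np.where(config.species >= 0, 2,
                              np.where(config.layer == 0, 0, 1)).astype(
                                  np.int64)
        self.q_idx = np.flatnonzero(self.charges != 0.0).astype(np.int64)
        self.do_coulomb = bool(len(self.q_idx))

        # --- electrostatics ------------------------------------------------
        self._setup_ewald()

        # --- neighbour storage (two-level Verlet lists) --------------------
        n = config.n_particles
        self.reservoir = 0.8   # nm; long-list margin beyond cutoff + skin
        cap = max(400 * n, 40000)
        self.lng_i = np.empty(cap, dtype=np.int32)
        self.lng_j = np.empty(cap, dtype=np.int32)
        self.lng_t = np.empty(cap, dtype=np.int32)
        self.lng_qq = np.empty(cap, dtype=float)
        self.lng_n = np.array([-1], dtype=np.int64)
        cap2 = max(120 * n, 20000)
        self.mp_i = np.empty(cap2, dtype=np.int32)
        self.mp_j = np.empty(cap2, dtype=np.int32)
        self.mp_t = np.empty(cap2, dtype=np.int32)
        capc = max(120 * max(len(self.q_idx), 1), 10000)
        self.cp_i = np.empty(capc, dtype=np.int32)
        self.cp_j = np.empty(capc, dtype=np.int32)
        self.cp_qq = np.empty(capc, dtype=float)
        self.counts = np.array([-1, -1], dtype=np.int64)
        self.mol_id = np.ascontiguousarray(config.molecule_id,
                                           dtype=np.int64)

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------

    def _build_morse_matrix(self):
        """(D0, r0) for every (class, class) pair; D0 = 0 masks the pair.

        Classes: species + 7*layer for molecule beads; 14/15 = SUB/SUP rigid.
        """
        p = self.params
        D0 = np.full((N_CLASSES, N_CLASSES), p.morse_default.D0)
        r0 = np.full((N_CLASSES, N_CLASSES), p.morse_default.r0)

        def cls(layer, species):
            return species + N_BEADS * layer

        rigid = {0: CLASS_SUB_RIGID, 1: CLASS_SUP_RIGID}

        def layer_of(c):
            if c == CLASS_SUB_RIGID:
                return 0
            if c == CLASS_SUP_RIGID:
                return 1
            return c // N_BEADS

        def is_head(c):
            return c < N_BEADS * 2 and (c % N_BEADS) in HEAD_SPECIES

        # cross-layer interactions are restricted to the polar heads
        for a in range(N_CLASSES):
            for b in range(N_CLASSES):
                if layer_of(a) != layer_of(b) and not (is_head(a) and
                                                       is_head(b)):
                    D0[a, b] = 0.0
        # rigid-rigid pairs never interact (SUB-SUP masked; same-layer rigid
        # pairs are internal to a frozen/rigid body)
        for a in rigid.values():
            for b in rigid.values():
                D0[a, b] = 0.0
        # NP tail beads bind to their own rigid layer...
        for lay in (0, 1):
            for sp in (5, 6):  # NP1, NP2
                D0[rigid[lay], cls(lay, sp)] = p.morse_anchor.D0
                D0[cls(lay, sp), rigid[lay]] = p.morse_anchor.D0
                r0[rigid[lay], cls(lay, sp)] = p.morse_anchor.r0
                r0[cls(lay, sp), rigid[lay]] = p.morse_anchor.r0
            # ...and to the matching tail bead of neighbouring molecules
            for sp in (5, 6):
                c = cls(lay, sp)
                D0[c, c] = p.morse_tail.D0
                r0[c, c] = p.morse_tail.r0
        return D0, r0

    def _build_pair_tables(self):
        p = self.params
        D0m, r0m = self.morse_matrix
        combos = []
        tid = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
        for a in range(N_CLASSES):
            for b in range(N_CLASSES):
                d, r = D0m[a, b], r0m[a, b]
                if d == 0.0:
                    continue
                key = (d, r)
                if key not in combos:
                    combos.append(key)
                tid[a, b] = combos.index(key) + 1
        self.tidmat = tid
        self.morse_combos = combos
        n = p.table_points
        s_lo = self.R_TABLE_MIN ** 2
        s_hi = p.morse_cutoff ** 2
        self.mcoef = np.zeros((max(len(combos), 1), n - 1, 4))
        for t, (d, r0) in enumerate(combos):
            def vg(s, d=d, r0=r0):
                r = np.sqrt(s)
                v, f = morse_energy_force(r, d, r0, p.morse_alpha,
                                          p.morse_cutoff)
                return v, -f / (2.0 * r)   # dV/ds = (dV/dr)/(2r)
            self.s0m, self.inv_dsm, self.mcoef[t] = _cubic_coef_table(
                vg, s_lo, s_hi, n)
        if not combos:
            self.s0m, self.inv_dsm = s_lo, (n - 1) / (s_hi - s_lo)
        self.nintm = n - 1
        self.s_cut_m = s_hi

    def _build_exclusions(self):
        """Per-particle sorted exclusion lists (CSR layout) + pair list."""
        seps = self.params.exclusions.excluded_separations()
        cfg = self.config
        n = cfg.n_particles
        neigh = [[] for _ in range(n)]
        for i, j in cfg.bonds:
            neigh[i].append(j)
            neigh[j].append(i)
        excl = [set() for _ in range(n)]
        for i in range(n):
            frontier = {i}
            seen = {i}
            for dist in range(1, 4):
                frontier = {k for f in frontier for k in neigh[f]} - seen
                seen |= frontier
                if dist in seps:
                    excl[i] |= frontier
        ptr = np.zeros(n + 1, dtype=np.int64)
        idx = []
        pairs = []
        for i in range(n):
            mine = sorted(excl[i])
            ptr[i + 1] = ptr[i] + len(mine)
            idx.extend(mine)
            pairs.extend((i, j) for j in mine if j > i)
        return ptr, np.array(idx, dtype=np.int64), np.array(
            pairs, dtype=np.int64).reshape(-1, 2)

    def _setup_ewald(self):
        """Choose splitting/cutoffs for the target accuracy; build k-vectors.

        The box is padded in z to ``vacuum_factor`` times the occupied slab
        extent (Yeh-Berkowitz); k-space cutoff at ``k_cut_sigmas`` Gaussian
        widths makes the truncated tail comparable to the target accuracy,
        which the splitting-invariance test verifies end to end.
        """
        es = self.params.electrostatics
        box = self.config.box
        half_min = 0.5 * min(box.l_x, box.l_y)
        self.r_cut_coul = es.r_cut if es.r_cut is not None else min(
            half_min - 1e-9, 2.0)
        if self.r_cut_coul > half_min + 1e-12:
            raise ValueError("Coulomb real-space cutoff exceeds the minimum-"
                             "image radius of the box")
        if es.alpha is not None:
            self.ewald_alpha = es.alpha
        else:
            # erfc(alpha r_cut) small enough that the real-space truncation
            # stays below the accuracy target for |q| <= 0.25 e
            q2 = 0.0625
            target = es.accuracy
            s = 2.0
            while s < 6.0:
                a = s / self.r_cut_coul
                tail = KC * q2 * (erfc(s) / self.r_cut_coul ** 2 +
                                  2 * a / math.sqrt(math.pi) *
                                  math.exp(-s * s) / self.r_cut_coul)
                if tail < 0.5 * target:
                    break
                s += 0.05
            self.ewald_alpha = s / self.r_cut_coul
        z = self.config.positions[:, 2]
        slab = (z.max() - z.min()) + 2.0 if len(z) else 1.0
        self.lz = max(es.vacuum_factor * slab, 3.0 * slab, 8.0)
        self._build_kvectors()
        self._build_coul_table()

    def _build_kvectors(self):
        es = self.params.electrostatics
        box = self.config.box
        alpha = self.ewald_alpha
        k_cut = 2.0 * alpha * es.k_cut_sigmas
        tp = 2.0 * math.pi
        nx = int(k_cut * box.l_x / tp)
        ny = int(k_cut * box.l_y / tp)
        nz = int(k_cut * self.lz / tp)
        kint = []
        kc_e = []
        vol = box.l_x * box.l_y * self.lz
        pref = 4.0 * math.pi * KC / vol   # half-space convention
        for ax in range(0, nx + 1):
            for ay in range(-ny, ny + 1):
                for az in range(-nz, nz + 1):
                    if ax == 0 and (ay < 0 or (ay == 0 and az <= 0)):
                        continue
                    kx = tp * ax / box.l_x
                    ky = tp * ay / box.l_y
                    kz = tp * az / self.lz
                    k2 = kx * kx + ky * ky + kz * kz
                    if k2 > k_cut * k_cut:
                        continue
                    kint.append((ax, ay, az))
                    kc_e.append(pref * math.exp(-k2 / (4 * alpha * alpha))
                                / k2)
        self.kint = np.array(kint, dtype=np.int64).reshape(-1, 3)
        self.kc_e = np.array(kc_e)
        self.kc_slab = 4.0 * math.pi * KC / vol

    def _build_coul_table(self):
        alpha = self.ewald_alpha
        n = self.params.table_points
        s_lo = self.R_TABLE_MIN ** 2
        s_hi = self.r_cut_coul ** 2

        def vg(s):
            r = np.sqrt(s)
            v = KC * erfc(alpha * r) / r
            dvdr = -KC * (erfc(alpha * r) / r ** 2 +
                          2 * alpha / math.sqrt(math.pi) *
                          np.exp(-(alpha * r) ** 2) / r)
            return v, dvdr / (2.0 * r)

        self.s0c, self.inv_dsc, self.ccoef = _cubic_coef_table(
            vg, s_lo, s_hi, n)
        self.nintc = n - 1
        self.s_cut_c = s_hi

    # ------------------------------------------------------------------
    # evaluation
    # ------------------------------------------------------------------

    def neighbor_cutoffs2(self):
        """(long_m, long_c, short_m, short_c) squared list cutoffs."""
        rm = self.params.morse_cutoff + self.skin
        rc = self.r_cut_coul + self.skin
        res = self.reservoir
        return ((rm + res) ** 2, (rc + res) ** 2, rm * rm, rc * rc)

    def _ensure_neighbors(self, positions):
        box = self.config.box
        lm2, lc2, rm2, rc2 = self.neighbor_cutoffs2()
        cnt = _kernels.build_long(
            positions, box.l_x, box.l_y, self.group, self.cid, self.charges,
            self.mol_id, self.tidmat, lm2, lc2, self.excl_ptr, self.excl_idx,
            self.lng_i, self.lng_j, self.lng_t, self.lng_qq)
        if cnt < 0:
            raise RuntimeError("long neighbour-list capacity exceeded")
        self.lng_n[0] = cnt
        _kernels.build_short(
            positions, box.l_x, box.l_y, int(self.lng_n[0]), self.lng_i,
            self.lng_j, self.lng_t, self.lng_qq, rm2, rc2,
            self.mp_i, self.mp_j, self.mp_t, self.cp_i, self.cp_j,
            self.cp_qq, self.counts)
        if self.counts[0] < 0:
            raise RuntimeError("short neighbour-list capacity exceeded")
        return int(self.counts[0]), int(self.counts[1])

    def bond_energy_forces(self, positions=None):
        pos = self._pos(positions)
        box = self.config.box
        frc = np.zeros_like(pos)
        e = _kernels.bond_energy_forces(pos, box.l_x, box.l_y, self.bond_i,
                                        self.bond_j, self.bond_kk,
                                        self.bond_r0, frc)
        if np.isnan(e):
            raise FloatingPointError("degenerate bond (zero length)")
        return float(e), frc

    def angle_energy_forces(self, positions=None):
        pos = self._pos(positions)
        box = self.config.box
        frc = np.zeros_like(pos)
        e = _kernels.angle_energy_forces(pos, box.l_x, box.l_y, self.ang_i,
                                         self.ang_j, self.ang_k, self.ang_kk,
                                         self.ang_t0, frc)
        if np.isnan(e):
            raise FloatingPointError("degenerate angle (coincident beads)")
        return float(e), frc

    def tilt_energy_forces(self, positions=None):
        """Tail-verticality restraint (see ForceFieldParams.k_tilt)."""
        pos = self._pos(positions)
        frc = np.zeros_like(pos)
        if self.params.k_tilt <= 0.0 or len(self.np1_idx) == 0:
            return 0.0, frc
        e = _kernels.tilt_energy_forces(pos, self.np1_idx, self.np2_idx,
                                        self.tilt_sgn, self.params.k_tilt,
                                        frc)
        if np.isnan(e):
            raise FloatingPointError("degenerate NP1-NP2 bond")
        return float(e), frc

    def morse_energy_forces(self, positions=None):
        """Total Morse energy/forces (tabulated pair sum, neighbour list)."""
        pos = self._pos(positions)
        box = self.config.box
        nm, _ = self._ensure_neighbors(pos)
        frc = np.zeros_like(pos)
        e_m = _kernels.morse_pair_forces(
            pos, box.l_x, box.l_y, nm, self.mp_i, self.mp_j, self.mp_t,
            self.mcoef, self.s0m, self.inv_dsm, self.nintm, self.s_cut_m,
            frc)
        return float(e_m), frc

    def coulomb_real_space(self, positions=None):
        """erfc-damped pair sum within r_cut (+ excluded-pair erf correction)."""
        pos = self._pos(positions)
        if not self.do_coulomb:
            return 0.0, np.zeros_like(pos)
        box = self.config.box
        _, nc = self._ensure_neighbors(pos)
        frc = np.zeros_like(pos)
        e_c = _kernels.coul_pair_forces(
            pos, box.l_x, box.l_y, nc, self.cp_i, self.cp_j, self.cp_qq,
            self.ccoef, self.s0c, self.inv_dsc, self.nintc, self.s_cut_c,
            frc)
        e_x, f_x = self._exclusion_correction(pos)
        return float(e_c + e_x), frc + f_x

    def _exclusion_correction(self, pos):
        """Remove the reciprocal-space contribution of excluded charged pairs."""
        e = 0.0
        frc = np.zeros_like(pos)
        if len(self.excl_pairs) == 0:
            return e, frc
        box = self.config.box
        a = self.ewald_alpha
        for i, j in self.excl_pairs:
            qq = self.charges[i] * self.charges[j]
            if qq == 0.0:
                continue
            d = pos[i] - pos[j]
            d[0] -= box.l_x * round(d[0] / box.l_x)
            d[1] -= box.l_y * round(d[1] / box.l_y)
            r = math.sqrt(d @ d)
            if r < 1e-4:
                raise FloatingPointError("overlapping charged beads")
            erf_r = 1.0 - erfc(a * r)
            e -= KC * qq * erf_r / r
            # d/dr [erf(ar)/r]
            dd = (2 * a / math.sqrt(math.pi) * math.exp(-(a * r) ** 2) / r
                  - erf_r / r ** 2)
            fpair = KC * qq * dd / r * d   # force on i of the -erf/r term
            frc[i] += fpair
            frc[j] -= fpair
        return e, frc

    def coulomb_reciprocal(self, positions=None):
        """k-space sum + self-energy + slab dipole correction."""
        pos = self._pos(positions)
        frc = np.zeros_like(pos)
        if not self.do_coulomb:
            return 0.0, frc
        box = self.config.box
        e = _kernels.ewald_recip(pos, self.q_idx, self.charges, box.l_x,
                                 box.l_y, self.lz, self.ewald_alpha,
                                 self.kint, self.kc_e, frc)
        e_self = -KC * self.ewald_alpha / math.sqrt(math.pi) * float(
            np.sum(self.charges ** 2))
        mz = float(np.sum(self.charges[self.q_idx] * pos[self.q_idx, 2]))
        e_slab = 0.5 * self.kc_slab * mz * mz
        frc[self.q_idx, 2] -= self.kc_slab * self.charges[self.q_idx] * mz
        return float(e + e_self + e_slab), frc

    def coulomb_energy_forces(self, positions=None):
        er, fr = self.coulomb_real_space(positions)
        ek, fk = self.coulomb_reciprocal(positions)
        return er + ek, fr + fk

    def total_energy_forces(self, positions=None):
        """U and per-particle forces; returns (U, F, components dict)."""
        pos = self._pos(positions)
        box = self.config.box
        nm, nc = self._ensure_neighbors(pos)
        frc = np.zeros_like(pos)
        e_m = _kernels.morse_pair_forces(
            pos, box.l_x, box.l_y, nm, self.mp_i, self.mp_j, self.mp_t,
            self.mcoef, self.s0m, self.inv_dsm, self.nintm, self.s_cut_m,
            frc)
        e_c = _kernels.coul_pair_forces(
            pos, box.l_x, box.l_y, nc, self.cp_i, self.cp_j, self.cp_qq,
            self.ccoef, self.s0c, self.inv_dsc, self.nintc, self.s_cut_c,
            frc)
        e_b, f_b = self.bond_energy_forces(pos)
        e_a, f_a = self.angle_energy_forces(pos)
        e_t, f_t = self.tilt_energy_forces(pos)
        frc += f_b + f_a + f_t
        comps = {"morse": float(e_m), "coulomb_real": float(e_c),
                 "bonds": e_b, "angles": e_a + e_t, "coulomb_recip": 0.0}
        if self.do_coulomb:
            e_k, f_k = self.coulomb_reciprocal(pos)
            e_x, f_x = self._exclusion_correction(pos)
            comps["coulomb_recip"] = e_k + e_x
            frc += f_k + f_x
        u = sum(comps.values())
        return float(u), frc, comps

    def _pos(self, positions):
        pos = self.config.positions if positions is None else positions
        return np.ascontiguousarray(pos, dtype=float)
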