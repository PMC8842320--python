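"""Geometry construction for the two-monolayer sliding system.

Two triangular lattices (node spacing a/2 = 0.41 nm) are rotated by -phi/2
(SUB, bottom) and +phi/2 (SUP, top) and embedded in a common rectangular
supercell, periodic in x and y.  Every fourth node (the a-spaced triangular
sublattice) anchors one 7-bead coarse-grained molecule: CA-R1-R2-R3-AN-NP1-NP2,
with the NP1/NP2 tail pair planted at the node.  SUB molecules point up (+z),
SUP molecules point down, and the two head planes face each other across the
sliding interface.

The commensuration search is a coincidence-lattice construction: a rectangle
(l_x, 0), (0, l_y) tiles a triangular lattice of spacing ``a`` rotated by
``-chi`` exactly when (l_x, 0) equals the rotated image of an integer lattice
vector v = p a1 + q a2 and (0, l_y) that of an orthogonal integer vector
w = r a1 + s a2.  Mirror symmetry of the triangular lattice about the x axis
guarantees the same rectangle tiles the +chi lattice, so the relative angle
between layers is phi = 2 chi.  All returned solutions are exact (zero strain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .units import DEG

#: molecular bead species, in chain order from the exposed head inward
SPECIES = ("CA", "R1", "R2", "R3", "AN", "NP1", "NP2")
N_BEADS = len(SPECIES)

#: species indices of the polar head (the only beads with cross-layer Morse)
HEAD_SPECIES = (0, 1, 2, 3, 4)  # CA, R1, R2, R3, AN

#: class ids used by the force field: species + 7*layer for molecule beads,
#: then the two rigid-layer classes
CLASS_SUB_RIGID = 14
CLASS_SUP_RIGID = 15
N_CLASSES = 16

SUB, SUP = 0, 1


class CommensurationError(ValueError):
    """No commensurate supercell satisfying the constraints."""


class GeometryError(ValueError):
    """Invalid or inconsistent geometric construction."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    """Triangular-lattice parameters of one rigid layer.

    node_spacing is the rigid-layer periodicity a/2; molecule_spacing the
    anchor sublattice spacing a = 2 * node_spacing; rotation_phi the relative
    angle between the two layers (each layer is rotated by +-phi/2).
    """

    node_spacing: float = 0.41
    molecule_spacing: float = 0.82
    rotation_phi: float = 19.652859631664562

    def __post_init__(self):
        if not math.isclose(self.molecule_spacing, 2.0 * self.node_spacing,
                            rel_tol=1e-9):
            raise GeometryError("molecule_spacing must equal 2 x node_spacing")
        if not (0.0 <= self.rotation_phi < 60.0):
            raise GeometryError("rotation_phi must lie in [0, 60) degrees")


@dataclass(frozen=True)
class Supercell:
    """Rectangular simulation cell, periodic in x and y only."""

    l_x: float
    l_y: float
    periodic_x: bool = True
    periodic_y: bool = True
    z_extent: float = 0.0  # open direction; padded later if Ewald is used

    def __post_init__(self):
        if self.l_x <= 0 or self.l_y <= 0:
            raise GeometryError("cell dimensions must be positive")

    @property
    def area(self) -> float:
        return self.l_x * self.l_y


@dataclass(frozen=True)
class CommensurateCell:
    """One exact coincidence solution of the two-lattice commensuration."""

    phi_deg: float
    l_x: float
    l_y: float
    pq: tuple            # integer coordinates of the x cell vector (a-basis)
    rs: tuple            # integer coordinates of the minimal orthogonal vector
    repetitions: tuple   # multiples (t1, t2) of the minimal vectors used
    n_molecules: int     # anchor count per layer
    mismatch: float      # relative strain (0 for exact solutions)
    molecule_spacing: float

    @property
    def cell(self) -> Supercell:
        return Supercell(self.l_x, self.l_y)


@dataclass(frozen=True)
class MoleculeTemplate:
    """Per-bead masses/charges and intramolecular topology of one molecule.

    Beads in chain order CA, R1, R2, R3, AN, NP1, NP2.  CA carries +q, AN -q
    (q = 0.25 e for the zwitterionic model, 0 for the charge-free control).
    Six successive bonds; five successive angle triplets, all with
    theta_eq = 180 deg except NP2-NP1-AN at 111 deg.
    """

    q: float = 0.25
    masses_amu: tuple = (60.0, 15.0, 15.0, 15.0, 80.0, 50.0, 50.0)
    bond_pairs: tuple = ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6))
    bond_r_eq: tuple = (0.16, 0.16, 0.16, 0.16, 0.16, 0.67)
    angle_triplets: tuple = ((0, 1, 2), (1, 2, 3), (2, 3, 4),
                             (3, 4, 5), (4, 5, 6))
    angle_theta_eq_deg: tuple = (180.0, 180.0, 180.0, 180.0, 111.0)

    def __post_init__(self):
        if len(self.masses_amu) != N_BEADS:
            raise GeometryError("template must have exactly 7 beads")
        if self.q < 0:
            raise GeometryError("q must be non-negative")

    @property
    def charges(self) -> np.ndarray:
        c = np.zeros(N_BEADS)
        c[0] = self.q    # CA
        c[4] = -self.q   # AN
        return c


@dataclass
class BuiltLayer:
    """Rigid bead positions and molecule anchor nodes of one layer."""

    which: int                   # SUB or SUP
    rigid_xy: np.ndarray         # (n_rigid, 2)
    anchor_xy: np.ndarray        # (n_anchor, 2)
    z_plane: float
    spec: LatticeSpec = field(default_factory=LatticeSpec)
    residual: float = 0.0

    @property
    def n_rigid(self) -> int:
        return len(self.rigid_xy)

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_xy)


@dataclass
class SystemConfiguration:
    """Complete particle system: coordinates, topology and group membership."""

    positions: np.ndarray        # (N, 3) nm
    species: np.ndarray          # (N,) int; molecule beads 0..6, rigid -1
    layer: np.ndarray            # (N,) 0 = SUB, 1 = SUP
    molecule_id: np.ndarray      # (N,) int; -1 for rigid beads
    charges: np.ndarray          # (N,) e
    masses_amu: np.ndarray       # (N,) a.m.u.
    bonds: np.ndarray            # (nb, 2) particle indices
    bond_slot: np.ndarray        # (nb,) template bond index 0..5
    angles: np.ndarray           # (na, 3) particle indices
    angle_slot: np.ndarray       # (na,) template angle index 0..4
    box: Supercell
    template: MoleculeTemplate
    cell_solution: CommensurateCell | None = None

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def is_rigid(self) -> np.ndarray:
        return self.species < 0

    @property
    def frozen(self) -> np.ndarray:
        """SUB rigid beads: kept fully immobile."""
        return (self.species < 0) & (self.layer == SUB)

    @property
    def rigid_translating(self) -> np.ndarray:
        """SUP rigid beads: one rigid body translating in 3D."""
        return (self.species < 0) & (self.layer == SUP)

    @property
    def class_id(self) -> np.ndarray:
        """Force-field class: species + 7*layer for beads, 14/15 for rigid."""
        cid = np.where(self.species >= 0,
                       self.species + N_BEADS * self.layer,
                       np.where(self.layer == SUB, CLASS_SUB_RIGID,
                                CLASS_SUP_RIGID))
        return cid.astype(np.int64)

    @property
    def n_molecules_per_layer(self) -> int:
        sel = (self.species == 0)
        return int(np.sum(sel & (self.layer == SUB)))

    def molecule_areal_density(self) -> float:
        return self.n_molecules_per_layer / self.box.area

    def validate(self):
        if abs(float(self.charges.sum())) > 1e-9:
            raise GeometryError("system is not charge neutral")
        n_sub = np.sum((self.species == 0) & (self.layer == SUB))
        n_sup = np.sum((self.species == 0) & (self.layer == SUP))
        if n_sub != n_sup:
            raise GeometryError("layers have different molecule counts")
        for lay in (SUB, SUP):
            nr = int(np.sum((self.species < 0) & (self.layer == lay)))
            nm = int(np.sum((self.species == 0) & (self.layer == lay)))
            if nr != 4 * nm:
                raise GeometryError(
                    f"layer {lay}: rigid bead count {nr} != 4 x molecules {nm}")
        return self


# ---------------------------------------------------------------------------
# commensuration search
# ---------------------------------------------------------------------------

def _lattice_vec_xy(p: int, q: int, a: float):
    """Cartesian components of p*a1 + q*a2 for a1=a(1,0), a2=a(1/2,sqrt3/2)."""
    return a * (p + 0.5 * q), a * (0.5 * math.sqrt(3.0) * q)


def enumerate_commensurate_cells(molecule_spacing: float,
                                 angle_window=(15.0, 25.0),
                                 max_dims: float = 15.0,
                                 mismatch_tol: float = 1e-3,
                                 include_multiples: bool = True):
    """Enumerate exact coincidence rectangles for two lattices rotated +-phi/2.

    Returns a list of :class:`CommensurateCell`, unsorted.  phi = 0 (aligned
    lattices) is produced when the window includes 0.
    """
    a = molecule_spacing
    if mismatch_tol <= 0:
        raise CommensurationError("mismatch_tol must be positive")
    lo, hi = angle_window
    if not (0.0 <= lo < hi <= 60.0):
        raise CommensurationError("angle_window must lie inside [0, 60] deg")
    out = []
    p_max = int(max_dims / a) + 1
    for p in range(1, p_max + 1):
        for q in range(0, p + 1):
            if math.gcd(p, q) != 1:
                continue
            vx, vy = _lattice_vec_xy(p, q, a)
            chi = math.degrees(math.atan2(vy, vx))
            phi = 2.0 * chi
            if not (lo - 1e-12 <= phi <= hi + 1e-12):
                continue
            l_x0 = math.hypot(vx, vy)
            if l_x0 > max_dims * (1 + 1e-12):
                continue
            # minimal integer lattice vector orthogonal to (p, q):
            # 2pr + ps + qr + 2qs = 0  =>  (r, s) ~ (-(p+2q), 2p+q)
            g = math.gcd(p + 2 * q, 2 * p + q)
            r, s = -(p + 2 * q) // g, (2 * p + q) // g
            wx, wy = _lattice_vec_xy(r, s, a)
            l_y0 = math.hypot(wx, wy)
            n0 = abs(p * s - q * r)
            t1_max = int(max_dims / l_x0) if include_multiples else 1
            t2_max = int(max_dims / l_y0) if include_multiples else 1
            for t1 in range(1, max(t1_max, 1) + 1):
                if t1 * l_x0 > max_dims * (1 + 1e-12):
                    break
                for t2 in range(1, max(t2_max, 1) + 1):
                    if t2 * l_y0 > max_dims * (1 + 1e-12):
                        break
                    out.append(CommensurateCell(
                        phi_deg=phi, l_x=t1 * l_x0, l_y=t2 * l_y0,
                        pq=(p, q), rs=(r, s), repetitions=(t1, t2),
                        n_molecules=n0 * t1 * t2, mismatch=0.0,
                        molecule_spacing=a))
    return out


def find_commensurate_supercell(molecule_spacing: float,
                                angle_window=(15.0, 25.0),
                                max_dims: float = 15.0,
                                mismatch_tol: float = 1e-3,
                                target_cell=None,
                                min_molecules: int = 0) -> CommensurateCell:
    """Find a rectangular supercell commensurate with both rotated lattices.

    Default selection: the smallest-area qualifying cell, ties broken by
    |phi - window centre| and then by l_x.  ``target_cell=(l_x, l_y)``
    instead selects the solution matching the given dimensions to 1%
    (used to recover a printed supercell).  ``min_molecules`` filters out
    cells below a molecule count (used to pick desk-scale systems).

    Raises :class:`CommensurationError` when no solution exists.
    """
    sols = enumerate_commensurate_cells(molecule_spacing, angle_window,
                                        max_dims, mismatch_tol)
    sols = [c for c in sols if c.n_molecules >= min_molecules]
    if not sols:
        raise CommensurationError(
            f"no commensurate cell for a={molecule_spacing} nm in "
            f"phi window {angle_window} within {max_dims} nm")
    if target_cell is not None:
        tx, ty = target_cell
        match = [c for c in sols
                 if abs(c.l_x - tx) <= 0.01 * tx and abs(c.l_y - ty) <= 0.01 * ty]
        if not match:
            raise CommensurationError(
                f"no commensurate cell matching target {target_cell} nm")
        return min(match, key=lambda c: abs(c.l_x - tx) + abs(c.l_y - ty))
    centre = 0.5 * (angle_window[0] + angle_window[1])
    return min(sols, key=lambda c: (c.l_x * c.l_y,
                                    abs(c.phi_deg - centre), c.l_x))


def full_cell() -> CommensurateCell:
    """The published supercell: phi = 19.65 deg, 8.32 x 14.41 nm, 206 mol/layer."""
    return find_commensurate_supercell(0.82, (15.0, 25.0), 15.0, 1e-3,
                                       target_cell=(8.32, 14.41))


def desk_cell() -> CommensurateCell:
    """Reduced-size commensurate cell for desk-scale runs (42 mol/layer).

    Same coincidence construction and molecule spacing as the full system at
    phi = 21.79 deg; the smallest cell in the same angle window with at least
    30 molecules per layer and both box lengths large enough for the
    electrostatics real-space cutoff under minimum image.
    """
    return find_commensurate_supercell(0.82, (15.0, 25.0), 8.0, 1e-3,
                                       min_molecules=30)


# ---------------------------------------------------------------------------
# layer construction
# ---------------------------------------------------------------------------

def _layer_rotation_deg(spec: LatticeSpec, which: int) -> float:
    return (-0.5 if which == SUB else +0.5) * spec.rotation_phi


def build_layer(spec: LatticeSpec, cell: Supercell, which: int,
                z_plane: float = 0.0, x_offset: float = 0.0,
                tol: float = 1e-6) -> BuiltLayer:
    """Fill the cell with the rigid triangular lattice of one layer.

    Rigid beads occupy every node of the (a/2)-spaced lattice rotated by
    -phi/2 (SUB) or +phi/2 (SUP); anchors are the nodes with even integer
    coordinates, forming the a-spaced molecule sublattice (1 node in 4).
    ``x_offset`` rigidly shifts the layer (used to break the t=0 registry of
    the two anchor lattices).

    Raises :class:`GeometryError` if the cell is not commensurate with the
    rotated lattice (reporting the residual mismatch).
    """
    a2 = spec.node_spacing
    theta = _layer_rotation_deg(spec, which) * DEG
    c, s = math.cos(theta), math.sin(theta)
    # primitive vectors of the rotated a/2 lattice
    e1 = np.array([a2 * c, a2 * s])
    e2 = np.array([a2 * (0.5 * c - 0.5 * math.sqrt(3) * s),
                   a2 * (0.5 * s + 0.5 * math.sqrt(3) * c)])
    basis = np.column_stack([e1, e2])
    cellmat = np.diag([cell.l_x, cell.l_y])
    # commensuration check: cell vectors must be integer in the lattice basis
    coeff = np.linalg.solve(basis, cellmat)
    residual = float(np.max(np.abs(coeff - np.round(coeff))))
    if residual > tol:
        raise GeometryError(
            f"cell {cell.l_x:.4f} x {cell.l_y:.4f} nm is not commensurate "
            f"with the layer lattice (residual mismatch {residual:.3e})")
    # enumerate nodes in a bounding index range and wrap into the cell
    corners = np.array([[0, 0], [cell.l_x, 0], [0, cell.l_y],
                        [cell.l_x, cell.l_y]]).T
    ij = np.linalg.solve(basis, corners)
    i_lo, i_hi = int(np.floor(ij[0].min())) - 2, int(np.ceil(ij[0].max())) + 2
    j_lo, j_hi = int(np.floor(ij[1].min())) - 2, int(np.ceil(ij[1].max())) + 2
    ii, jj = np.meshgrid(np.arange(i_lo, i_hi + 1),
                         np.arange(j_lo, j_hi + 1), indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    xy = basis @ np.vstack([ii, jj]) + np.array([[x_offset], [0.0]])
    frac = np.linalg.solve(cellmat, xy)
    frac -= np.floor(frac + 1e-9)
    xy = (cellmat @ frac).T
    # deduplicate wrapped nodes; parity of (i, j) is invariant under cell
    # translations (their lattice coordinates are even), so anchors are
    # identified from any representative
    seen = {}
    even = []
    for k in range(len(xy)):
        key = (round(xy[k, 0] / tol), round(xy[k, 1] / tol))
        if key in seen:
            continue
        seen[key] = k
        even.append(ii[k] % 2 == 0 and jj[k] % 2 == 0)
    idx = np.fromiter(seen.values(), dtype=int)
    even = np.array(even, dtype=bool)
    rigid_xy = xy[idx]
    anchor_xy = rigid_xy[even]
    order = np.lexsort((rigid_xy[:, 0], rigid_xy[:, 1]))
    rigid_xy = rigid_xy[order]
    anchor_order = np.lexsort((anchor_xy[:, 0], anchor_xy[:, 1]))
    anchor_xy = anchor_xy[anchor_order]
    if len(rigid_xy) != 4 * len(anchor_xy):
        raise GeometryError(
            f"node bookkeeping failed: {len(rigid_xy)} rigid beads vs "
            f"{len(anchor_xy)} anchors")
    return BuiltLayer(which=which, rigid_xy=rigid_xy, anchor_xy=anchor_xy,
                      z_plane=z_plane, spec=spec, residual=residual)


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

#: default initial head tilt from the layer normal, degrees.  The 111 deg
#: NP2-NP1-AN equilibrium corresponds to a 69 deg tilt, which would overlap
#: neighbouring heads at a = 0.82 nm spacing; the pose starts near-vertical
#: and relaxes toward equilibrium during running-in.
DEFAULT_TILT_DEG = 15.0

#: initial distance of NP2 above its anchor node plane (the Morse r0 to the
#: nearest rigid bead).
NP2_HEIGHT = 0.41

MIN_SEPARATION = 0.05


def _chain_offsets(template: MoleculeTemplate, tilt_deg: float,
                   azimuth: float, up: bool) -> np.ndarray:
    """Bead offsets (7, 3) relative to the anchor node, chain order CA..NP2."""
    sgn = 1.0 if up else -1.0
    t = tilt_deg * DEG
    u = np.array([math.sin(t) * math.cos(azimuth),
                  math.sin(t) * math.sin(azimuth),
                  sgn * math.cos(t)])
    r = np.array(template.bond_r_eq)
    np2 = np.array([0.0, 0.0, sgn * NP2_HEIGHT])
    np1 = np2 + np.array([0.0, 0.0, sgn * r[5]])        # NP1-NP2 bond, 0.67
    off = np.zeros((N_BEADS, 3))
    off[6] = np2
    off[5] = np1
    # head beads AN, R3, R2, R1, CA walk outward from NP1 along u
    d = 0.0
    for bead in (4, 3, 2, 1, 0):
        d += r[bead]                                     # 0.16 nm bonds
        off[bead] = np1 + d * u
    return off


def chain_extent(template: MoleculeTemplate,
                 tilt_deg: float = DEFAULT_TILT_DEG) -> float:
    """Vertical distance from the rigid plane to the CA bead in the pose."""
    r = template.bond_r_eq
    return NP2_HEIGHT + r[5] + sum(r[0:5]) * math.cos(tilt_deg * DEG)


def assemble_system(template: MoleculeTemplate,
                    sub_layer: BuiltLayer, sup_layer: BuiltLayer,
                    cell: Supercell,
                    initial_gap: float = 0.5,
                    charge_on: bool = True,
                    seed: int = 0,
                    tilt_deg: float = DEFAULT_TILT_DEG,
                    azimuth_mode: str = "ordered",
                    cell_solution: CommensurateCell | None = None
                    ) -> SystemConfiguration:
    """Place molecules on both layers' anchors and build the full topology.

    SUB rigid beads sit at z = 0 and its molecules point up; the SUP layer is
    the z mirror, positioned so the two CA planes start ``initial_gap`` nm
    apart.  Kink azimuths are drawn per molecule from a seeded RNG (identical
    sequences in the two layers, so the construction is an exact z mirror
    modulo the relative lattice rotation).  Raises if any two beads come
    closer than 0.05 nm.
    """
    if sub_layer.which != SUB or sup_layer.which != SUP:
        raise GeometryError("assemble_system expects (SUB, SUP) layers")
    if sub_layer.n_anchors != sup_layer.n_anchors:
        raise GeometryError("layers must hold identical molecule counts")
    rng = np.random.default_rng(seed)
    n_mol = sub_layer.n_anchors
    if azimuth_mode == "ordered":
        # uniformly tilted carpet (the low-temperature ordered phase the
        # intra-layer interactions favour) with a small seeded jitter so
        # no symmetry is mathematically exact
        azimuths = 0.15 * rng.standard_normal(n_mol)
    elif azimuth_mode == "random":
        azimuths = rng.uniform(0.0, 2.0 * math.pi, size=n_mol)
    else:
        raise GeometryError(f"unknown azimuth_mode {azimuth_mode!r}")

    h = chain_extent(template, tilt_deg)
    z_sup_plane = 2.0 * h + initial_gap

    pos, spec_l, layer_l, mol_l = [], [], [], []
    q_mol = template.charges if charge_on else np.zeros(N_BEADS)
    m_mol = np.asarray(template.masses_amu)
    charges, masses = [], []
    bonds, bond_slot, angles, angle_slot = [], [], [], []

    mol_counter = 0
    for lay, built, zp, up in ((SUB, sub_layer, 0.0, True),
                               (SUP, sup_layer, z_sup_plane, False)):
        # rigid beads
        nr = built.n_rigid
        rp = np.column_stack([built.rigid_xy,
                              np.full(nr, zp)])
        pos.append(rp)
        spec_l.append(np.full(nr, -1, dtype=np.int64))
        layer_l.append(np.full(nr, lay, dtype=np.int64))
        mol_l.append(np.full(nr, -1, dtype=np.int64))
        charges.append(np.zeros(nr))
        masses.append(np.full(nr, 50.0))   # rigid bead mass, config-exposed
        # molecules
        for k in range(n_mol):
            off = _chain_offsets(template, tilt_deg, azimuths[k], up)
            base = np.array([built.anchor_xy[k, 0], built.anchor_xy[k, 1], zp])
            start = int(np.sum([len(p) for p in pos]))
            pos.append(base + off)
            spec_l.append(np.arange(N_BEADS, dtype=np.int64))
            layer_l.append(np.full(N_BEADS, lay, dtype=np.int64))
            mol_l.append(np.full(N_BEADS, mol_counter, dtype=np.int64))
            charges.append(q_mol.copy())
            masses.append(m_mol.copy())
            for bslot, (i, j) in enumerate(template.bond_pairs):
                bonds.append((start + i, start + j))
                bond_slot.append(bslot)
            for aslot, (i, j, k3) in enumerate(template.angle_triplets):
                angles.append((start + i, start + j, start + k3))
                angle_slot.append(aslot)
            mol_counter += 1

    config = SystemConfiguration(
        positions=np.vstack(pos),
        species=np.concatenate(spec_l),
        layer=np.concatenate(layer_l),
        molecule_id=np.concatenate(mol_l),
        charges=np.concatenate(charges),
        masses_amu=np.concatenate(masses),
        bonds=np.array(bonds, dtype=np.int64),
        bond_slot=np.array(bond_slot, dtype=np.int64),
        angles=np.array(angles, dtype=np.int64),
        angle_slot=np.array(angle_slot, dtype=np.int64),
        box=replace(cell, z_extent=z_sup_plane),
        template=template,
        cell_solution=cell_solution,
    )
    config.validate()
    dmin = _min_separation(config.positions, cell.l_x, cell.l_y)
    if dmin < MIN_SEPARATION:
        raise GeometryError(
            f"overlapping beads in the assembled system (min distance "
            f"{dmin:.4f} nm < {MIN_SEPARATION} nm)")
    return config


def _min_separation(positions: np.ndarray, l_x: float, l_y: float) -> float:
    """Global minimum pair distance under xy periodicity (KD-tree on the
    3x3 in-plane image tiling)."""
    from scipy.spatial import cKDTree
    tiles = []
    for sx in (-l_x, 0.0, l_x):
        for sy in (-l_y, 0.0, l_y):
            t = positions.copy()
            t[:, 0] += sx
            t[:, 1] += sy
            tiles.append(t)
    tree = cKDTree(np.vstack(tiles))
    d, _ = tree.query(positions, k=2)
    return float(d[:, 1].min())


def build_system(cell_solution: CommensurateCell | None = None,
                 charge_on: bool = True,
                 q: float = 0.25,
                 initial_gap: float = 0.5,
                 seed: int = 0,
                 tilt_deg: float = DEFAULT_TILT_DEG,
                 azimuth_mode: str = "ordered") -> SystemConfiguration:
    """One-call constructor: commensurate cell -> layers -> full system.

    With no arguments this builds the published system (8.32 x 14.41 nm,
    206 molecules and 824 rigid beads per layer, 4532 particles).
    """
    sol = cell_solution if cell_solution is not None else full_cell()
    spec = LatticeSpec(molecule_spacing=sol.molecule_spacing,
                       node_spacing=0.5 * sol.molecule_spacing,
                       rotation_phi=sol.phi_deg)
    cell = sol.cell
    template = MoleculeTemplate(q=q)
    sub = build_layer(spec, cell, SUB, 0.0)
    # half-a-node x offset avoids exact anchor registry at t = 0
    sup = build_layer(spec, cell, SUP, 0.0, x_offset=0.5 * spec.node_spacing)
    return assemble_system(template, sub, sup, cell, initial_gap=initial_gap,
                           charge_on=charge_on, seed=seed, tilt_deg=tilt_deg,
                           azimuth_mode=azimuth_mode, cell_solution=sol)
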