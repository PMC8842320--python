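"""Langevin dynamics of the sliding bilayer contact.

Equations of motion: molecule beads follow velocity-Verlet dynamics with a
Langevin thermostat acting only on the transverse coordinates u = y, z
(friction -m gamma v_u plus Gaussian random forces of variance
2 m gamma k_B T / dt), so no spurious thermostat damping acts along the
sliding direction x.  SUB rigid beads are fully frozen.  SUP rigid beads
form one rigid body translating in the three directions under the sum of
its members' forces, the normal load -L A along z and, in production mode,
a pulling spring k (x_stage - x_SUP) with the stage advancing at constant
velocity, x_stage = v_stage t.  During running-in the SUP x velocity is
constrained to v_stage instead (no spring attached yet).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forcefield import ForceField
from .units import AMU, KB, EV_NM3_TO_MPA, M_S_TO_NM_PS


class SimulationBlowUp(RuntimeError):
    """Non-finite coordinates or forces encountered during integration."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ThermostatParams:
    """Anisotropic Langevin thermostat: gamma on y,z of molecule beads only."""
    temperature: float = 300.0     # K
    gamma: float = 1.0             # ps^-1 (gamma_x = 0 by construction)

    def __post_init__(self):
        if self.gamma < 0 or self.temperature < 0:
            raise ValueError("gamma and temperature must be non-negative")


@dataclass(frozen=True)
class DriveParams:
    """Pulling stage: spring k (eV/nm^2) towed at v_stage along +x."""
    v_stage_m_s: float = 5.0
    k_spring: float = 1.0

    def __post_init__(self):
        if self.k_spring <= 0:
            raise ValueError("k_spring must be positive")

    @property
    def v_stage(self) -> float:
        """Stage velocity in nm/ps."""
        return self.v_stage_m_s * M_S_TO_NM_PS


@dataclass(frozen=True)
class LoadParams:
    """Normal load L (MPa) applied to the SUP body along -z over the cell."""
    L_mpa: float = 10.0

    def force_on(self, area_nm2: float) -> float:
        """Downward force L*A in eV/nm."""
        return self.L_mpa * area_nm2 / EV_NM3_TO_MPA


@dataclass
class SimState:
    """Snapshot of the dynamic state (for restarts and inspection).

    Beyond positions/velocities this captures every piece of persistent
    integrator state (cached forces, reciprocal-space forces, SUP body
    force, neighbour list, RNG state) so that a restarted run continues
    bit-for-bit identically to an uninterrupted one (given the same
    chunking of steps).
    """
    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    rec_forces: np.ndarray
    f_sup: np.ndarray
    sup_velocity: np.ndarray
    sup_com: np.ndarray
    stage_x: float
    time_ps: float
    step: int
    rng_state: dict
    mode: int
    neighbor: tuple | None = None


MODE_FREE, MODE_RUN_IN, MODE_PRODUCTION = 0, 1, 2


class LangevinIntegrator:
    """Chunked velocity-Verlet/Langevin propagator for one configuration.

    Parameters
    ----------
    config, forcefield : the particle system and its bound force field.
    thermostat, drive, load : physical run conditions.
    dt : timestep, ps (default 1 fs; desk-scale protocol runs use 2 fs).
    seed : seeds the Gaussian noise stream (bit-for-bit reproducible).
    recip_every : refresh interval (steps) of the reciprocal-space Coulomb
        forces; they vary slowly and are held between refreshes.
    rebuild_every : fixed short-list refilter interval (steps); the long
        candidate list is rebuilt every ``long_every`` steps.  The skin and
        reservoir margins are sized so these deterministic schedules are
        always conservative.
    """

    def __init__(self, config, forcefield: ForceField,
                 thermostat: ThermostatParams | None = None,
                 drive: DriveParams | None = None,
                 load: LoadParams | None = None,
                 dt: float = 1e-3, seed: int = 0,
                 recip_every: int = 5, rebuild_every: int = 20,
                 long_every: int = 200):
        self.config = config
        self.ff = forcefield
        self.thermostat = thermostat or ThermostatParams()
        self.drive = drive or DriveParams()
        self.load = load or LoadParams(0.0)
        self.dt = float(dt)
        self.recip_every = int(recip_every)
        self.rebuild_every = int(rebuild_every)
        self.long_every = int(long_every)
        self.rng = np.random.default_rng(seed)

        box = config.box
        self.area = box.area
        self.pos = np.array(config.positions, dtype=float)
        n = config.n_particles
        self.vel = np.zeros((n, 3))
        self.frc = np.zeros((n, 3))
        self.rec_frc = np.zeros((n, 3))
        self.masses = config.masses_amu * AMU
        self.inv_m = np.where(self.masses > 0, 1.0 / self.masses, 0.0)
        self.mol_idx = np.flatnonzero(config.species >= 0).astype(np.int64)
        self.sup_idx = np.flatnonzero(config.rigid_translating).astype(
            np.int64)
        self.sub_idx = np.flatnonzero(config.frozen).astype(np.int64)
        self.sup_mass = float(self.masses[self.sup_idx].sum())
        self.sup_vel = np.zeros(3)
        com = self.pos[self.sup_idx].mean(axis=0)
        # state: [stage_x, sup_com_x, sup_com_y, sup_com_z]
        self.state = np.array([0.0, com[0], com[1], com[2]])
        self.f_sup = np.zeros(3)
        self.mode = MODE_FREE
        self.step = 0
        self._sig = self._noise_sigma()
        self._load_fz = self.load.force_on(self.area)
        self._forces_fresh = False

    # ------------------------------------------------------------------

    def _noise_sigma(self):
        th = self.thermostat
        m = self.masses[self.mol_idx]
        return np.sqrt(2.0 * m * th.gamma * KB * th.temperature / self.dt)

    @property
    def time_ps(self) -> float:
        return self.step * self.dt

    @property
    def x_sup(self) -> float:
        return float(self.state[1])

    @property
    def stage_x(self) -> float:
        return float(self.state[0])

    @property
    def shear_stress_mpa(self) -> float:
        """Instantaneous shear stress k (x_stage - x_SUP)/A, in MPa."""
        if self.mode != MODE_PRODUCTION:
            return 0.0
        f = self.drive.k_spring * (self.state[0] - self.state[1])
        return f / self.area * EV_NM3_TO_MPA

    def spring_force(self) -> float:
        return self.drive.k_spring * (self.state[0] - self.state[1])

    def interlayer_distance(self) -> float:
        return float(self.pos[self.sup_idx, 2].mean()
                     - self.pos[self.sub_idx, 2].mean())

    def instantaneous_temperature(self) -> float:
        """Kinetic temperature of the damped (y, z molecule) DOFs, K."""
        m = self.masses[self.mol_idx]
        v2 = (self.vel[self.mol_idx, 1:] ** 2).sum(axis=1)
        ndof = 2 * len(self.mol_idx)
        return float((m * v2).sum() / (ndof * KB))

    def kinetic_energy(self) -> float:
        ke = 0.5 * float((self.masses[self.mol_idx] *
                          (self.vel[self.mol_idx] ** 2).sum(axis=1)).sum())
        ke += 0.5 * self.sup_mass * float(self.sup_vel @ self.sup_vel)
        return ke

    def potential_energy(self) -> float:
        u, _, _ = self.ff.total_energy_forces(self.pos)
        return u

    # ------------------------------------------------------------------

    def set_mode(self, mode: int):
        """Switch drive mode; attaching the spring zeroes its elongation."""
        self.mode = mode
        if mode == MODE_RUN_IN:
            self.sup_vel[0] = self.drive.v_stage
        if mode == MODE_PRODUCTION:
            self.state[0] = self.state[1]   # x_stage starts at x_SUP
        self._forces_fresh = False

    def seed_velocities(self, temperature: float, seed: int | None = None):
        """Maxwell-Boltzmann start for molecule beads (all three components)."""
        rng = self.rng if seed is None else np.random.default_rng(seed)
        m = self.masses[self.mol_idx, None]
        self.vel[self.mol_idx] = rng.normal(
            0.0, np.sqrt(KB * temperature / m), size=(len(self.mol_idx), 3))
        self._forces_fresh = False

    def _refresh_forces(self):
        """Full force evaluation at the current positions (chunk entry)."""
        u, frc, comps = self.ff.total_energy_forces(self.pos)
        self.frc[:] = frc
        if self.ff.do_coulomb:
            ek, fk = self.ff.coulomb_reciprocal(self.pos)
            ex, fx = self.ff._exclusion_correction(self.pos)
            self.rec_frc[:] = fk + fx
        # Langevin terms enter inside the kernel; here only conservative
        self.f_sup[:] = self.frc[self.sup_idx].sum(axis=0)
        if self.mode == MODE_PRODUCTION:
            self.f_sup[0] += self.spring_force()
        self.f_sup[2] -= self._load_fz
        self._last_components = comps
        self._forces_fresh = True

    def _chunk(self, nn, noise, lm2, lc2, rm2, rc2):
        ff = self.ff
        box = self.config.box
        return _kernels.integrate_chunk(
            self.pos, self.vel, self.frc, self.inv_m, ff.group,
            self.mol_idx, self.sup_idx,
            box.l_x, box.l_y, self.dt, nn, self.step,
            ff.lng_i, ff.lng_j, ff.lng_t, ff.lng_qq, ff.lng_n,
            self.long_every,
            ff.mp_i, ff.mp_j, ff.mp_t, ff.cp_i, ff.cp_j, ff.cp_qq,
            ff.counts, self.rebuild_every,
            ff.cid, ff.charges, ff.mol_id, ff.tidmat, lm2, lc2, rm2, rc2,
            ff.excl_ptr, ff.excl_idx,
            ff.mcoef, ff.s0m, ff.inv_dsm, ff.nintm, ff.s_cut_m,
            ff.ccoef, ff.s0c, ff.inv_dsc, ff.nintc, ff.s_cut_c,
            ff.bond_i, ff.bond_j, ff.bond_kk, ff.bond_r0,
            ff.ang_i, ff.ang_j, ff.ang_k, ff.ang_kk, ff.ang_t0,
            ff.np1_idx, ff.np2_idx, ff.tilt_sgn, ff.params.k_tilt,
            ff.do_coulomb, self.recip_every, ff.q_idx, ff.kint, ff.kc_e,
            ff.lz, ff.ewald_alpha, ff.kc_slab, self.rec_frc,
            self.thermostat.gamma, self._sig, noise,
            self.mode, self.drive.v_stage, self.drive.k_spring,
            self._load_fz, self.sup_mass,
            self.state, self.sup_vel, self.f_sup)

    def advance(self, n_steps: int):
        """Integrate n_steps; returns the last potential-energy components."""
        if n_steps <= 0:
            return self._last_components if self._forces_fresh else None
        if not self._forces_fresh:
            self._refresh_forces()
        ff = self.ff
        box = self.config.box
        th = self.thermostat
        lm2, lc2, rm2, rc2 = ff.neighbor_cutoffs2()
        # cap sub-chunk size so per-chunk noise buffers stay small; the
        # noise stream is drawn sequentially, so splitting does not change it
        remaining = n_steps
        while remaining > 0:
            nn = min(remaining, 4000)
            noise = self.rng.standard_normal((nn, len(self.mol_idx), 2))
            try:
                out = self._chunk(nn, noise, lm2, lc2, rm2, rc2)
            except (ZeroDivisionError, OverflowError, FloatingPointError,
                    ValueError) as exc:
                raise SimulationBlowUp(
                    f"numeric failure in step chunk at step {self.step}: "
                    f"{exc}",
                    diagnostics={"step": self.step,
                                 "stage_x": self.stage_x}) from exc
            self.step += nn
            remaining -= nn
        e_m, e_c, e_b, e_a, e_r = out
        if not (np.isfinite(self.pos).all() and np.isfinite(out).all()
                and np.isfinite(self.vel[self.mol_idx]).all()):
            raise SimulationBlowUp(
                f"non-finite state at step {self.step}",
                diagnostics={"step": self.step, "stage_x": self.stage_x,
                             "x_sup": self.x_sup})
        self._last_components = {"morse": e_m, "coulomb_real": e_c,
                                 "bonds": e_b, "angles": e_a,
                                 "coulomb_recip": e_r}
        return self._last_components

    def last_potential_energy(self) -> float:
        """Potential energy of the most recent in-chunk force evaluation.

        The reciprocal component is refreshed on the recip_every schedule;
        sample at chunk boundaries aligned with it for a consistent total.
        """
        c = self._last_components
        return float(sum(c.values()))

    # ------------------------------------------------------------------
    # restart support
    # ------------------------------------------------------------------

    def get_state(self) -> SimState:
        ff = self.ff
        nm, nc = int(ff.counts[0]), int(ff.counts[1])
        ln = int(ff.lng_n[0])
        nbr = None
        if nm >= 0 and ln >= 0:
            nbr = (nm, ff.mp_i[:nm].copy(), ff.mp_j[:nm].copy(),
                   ff.mp_t[:nm].copy(),
                   nc, ff.cp_i[:nc].copy(), ff.cp_j[:nc].copy(),
                   ff.cp_qq[:nc].copy(),
                   ln, ff.lng_i[:ln].copy(), ff.lng_j[:ln].copy(),
                   ff.lng_t[:ln].copy(), ff.lng_qq[:ln].copy())
        return SimState(
            positions=self.pos.copy(), velocities=self.vel.copy(),
            forces=self.frc.copy(), rec_forces=self.rec_frc.copy(),
            f_sup=self.f_sup.copy(), sup_velocity=self.sup_vel.copy(),
            sup_com=self.state[1:].copy(), stage_x=float(self.state[0]),
            time_ps=self.time_ps, step=self.step,
            rng_state=self.rng.bit_generator.state, mode=self.mode,
            neighbor=nbr)

    def set_state(self, st: SimState):
        self.pos[:] = st.positions
        self.vel[:] = st.velocities
        self.frc[:] = st.forces
        self.rec_frc[:] = st.rec_forces
        self.f_sup[:] = st.f_sup
        self.sup_vel[:] = st.sup_velocity
        self.state[0] = st.stage_x
        self.state[1:] = st.sup_com
        self.step = st.step
        self.mode = st.mode
        self.rng.bit_generator.state = st.rng_state
        if st.neighbor is not None:
            (nm, mi, mj, mt, nc, ci, cj, cqq,
             ln, li, lj, lt, lqq) = st.neighbor
            self.ff.mp_i[:nm] = mi
            self.ff.mp_j[:nm] = mj
            self.ff.mp_t[:nm] = mt
            self.ff.cp_i[:nc] = ci
            self.ff.cp_j[:nc] = cj
            self.ff.cp_qq[:nc] = cqq
            self.ff.counts[0] = nm
            self.ff.counts[1] = nc
            self.ff.lng_i[:ln] = li
            self.ff.lng_j[:ln] = lj
            self.ff.lng_t[:ln] = lt
            self.ff.lng_qq[:ln] = lqq
            self.ff.lng_n[0] = ln
        else:
            self.ff.counts[0] = -1
            self.ff.counts[1] = -1
            self.ff.lng_n[0] = -1
        self._forces_fresh = True

    def save_state(self, path):
        """Binary snapshot (runtime artifact) for exact continuation."""
        import pickle
        with open(path, "wb") as fh:
            pickle.dump(self.get_state(), fh)

    def load_state(self, path):
        import pickle
        with open(path, "rb") as fh:
            st = pickle.load(fh)
        self.set_state(st)


def rigid_layer_displacement_closed_form(force, mass, t):
    """Constant-force kinematics F t^2 / (2 M) used as an integrator oracle."""
    return force * t * t / (2.0 * mass)
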