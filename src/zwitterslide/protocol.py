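"""Experiment orchestration: running-in, production sliding, averaging.

A friction experiment drags the SUP layer at constant stage velocity under
a chosen load and temperature: first a running-in stretch with the SUP x
velocity clamped to v_stage until the contact reaches a steady sliding
state, then the measuring spring is attached and the stage towed for the
production travel while the spring elongation (shear stress), hooking
fraction, interlayer distance, potential energy and kinetic temperature
are sampled on a uniform stage-travel grid.  Averages discard an initial
transient (a fixed travel and at least the first slip event).

``FrictionTrace`` is a pandas DataFrame with columns
time_ps, x_stage, x_sup, shear_mpa, hooking_pct, U_ev, d_nm, T_inst_K
and experiment metadata in ``.attrs``.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis
from .dynamics import (LangevinIntegrator, ThermostatParams, DriveParams,
                       LoadParams, SimulationBlowUp,
                       MODE_RUN_IN, MODE_PRODUCTION)
from .forcefield import ForceField, ForceFieldParams

TRACE_COLUMNS = ("time_ps", "x_stage", "x_sup", "shear_mpa", "hooking_pct",
                 "U_ev", "d_nm", "T_inst_K")


@dataclass(frozen=True)
class RunPlan:
    """Travel budget and sampling of one friction experiment (lengths in nm
    of stage travel).

    The defaults are the full-scale protocol (100 nm production, 20 nm
    discard); :func:`desk_plan` returns the reduced desk-scale settings.
    """
    run_in_nm: float = 10.0
    production_nm: float = 100.0
    discard_nm: float = 20.0
    sample_dx_nm: float = 0.01
    dt_ps: float = 1e-3
    recip_every: int = 5
    rebuild_every: int = 20
    seed: int = 1
    #: settling time (load off, no drive) before the loaded running-in, so
    #: the carpets order at the target temperature instead of being slammed
    #: together in the artificial initial pose
    settle_ps: float = 0.0

    def __post_init__(self):
        if self.discard_nm >= self.production_nm:
            raise ValueError("discard must be shorter than production")


def desk_plan(**overrides) -> RunPlan:
    """Reduced-scale plan for desk runs (~10 nm travel, dt = 2 fs).

    The discard keeps the same ~25% fraction of the production travel as the
    full-scale protocol; the reciprocal-space refresh stride is relaxed to
    20 steps (40 fs), far below the ~ps timescale on which those smooth
    long-range forces vary.
    """
    base = RunPlan(run_in_nm=1.0, production_nm=8.0, discard_nm=2.0,
                   sample_dx_nm=0.01, dt_ps=2e-3, recip_every=20,
                   settle_ps=150.0)
    return replace(base, **overrides)


def _steps_per_sample(plan: RunPlan, v_stage_nm_ps: float) -> int:
    n = int(round(plan.sample_dx_nm / (v_stage_nm_ps * plan.dt_ps)))
    # align chunks with the reciprocal refresh and list rebuild schedules
    q = int(np.lcm(plan.recip_every, plan.rebuild_every))
    return max(q, (n // q) * q)


def make_integrator(config, temperature, v_stage_m_s, load_mpa, plan,
                    ff_params: ForceFieldParams | None = None,
                    gamma: float = 1.0) -> LangevinIntegrator:
    ff = ForceField(config, ff_params)
    return LangevinIntegrator(
        config, ff,
        thermostat=ThermostatParams(temperature=temperature, gamma=gamma),
        drive=DriveParams(v_stage_m_s=v_stage_m_s),
        load=LoadParams(load_mpa),
        dt=plan.dt_ps, seed=plan.seed,
        recip_every=plan.recip_every, rebuild_every=plan.rebuild_every)


def _sample_row(itg: LangevinIntegrator) -> tuple:
    cfg = itg.config
    h = analysis.hooking_fraction(cfg, itg.pos)
    return (itg.time_ps, itg.stage_x, itg.x_sup, itg.shear_stress_mpa, h,
            itg.last_potential_energy(), itg.interlayer_distance(),
            itg.instantaneous_temperature())


def _trace(rows, itg, extra=None) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(TRACE_COLUMNS))
    df.attrs["area_nm2"] = itg.area
    df.attrs["k_spring"] = itg.drive.k_spring
    df.attrs["v_stage_m_s"] = itg.drive.v_stage_m_s
    df.attrs["load_mpa"] = itg.load.L_mpa
    df.attrs["temperature_K"] = itg.thermostat.temperature
    df.attrs.update(extra or {})
    return df


def run_in(itg: LangevinIntegrator, plan: RunPlan, log=None):
    """Prepare the contact: optional unloaded settling, then a
    constant-velocity running-in over plan.run_in_nm of SUP travel under
    the target load."""
    from .dynamics import MODE_FREE
    itg.seed_velocities(itg.thermostat.temperature)
    if plan.settle_ps > 0:
        load_fz = itg._load_fz
        itg._load_fz = 0.0
        itg.set_mode(MODE_FREE)
        q = int(np.lcm(plan.recip_every, plan.rebuild_every))
        n = max(int(round(plan.settle_ps / plan.dt_ps)) // q, 1) * q
        itg.advance(n)
        itg._load_fz = load_fz
        if log:
            print(f"[settle] {plan.settle_ps} ps done", file=log)
    itg.set_mode(MODE_RUN_IN)
    v = itg.drive.v_stage
    per = _steps_per_sample(plan, v)
    n_chunks = int(round(plan.run_in_nm / (v * plan.dt_ps * per)))
    for c in range(max(n_chunks, 1)):
        itg.advance(per)
    if log:
        print(f"[run-in] {plan.run_in_nm} nm done, t={itg.time_ps:.1f} ps",
              file=log)


def production(itg: LangevinIntegrator, plan: RunPlan, travel_nm=None,
               log=None) -> pd.DataFrame:
    """Spring-driven production sliding with uniform-travel sampling.

    On numeric blow-up the partial trace collected so far is attached to the
    raised :class:`SimulationBlowUp` as ``diagnostics['partial_trace']``.
    """
    travel = plan.production_nm if travel_nm is None else travel_nm
    itg.set_mode(MODE_PRODUCTION)
    v = itg.drive.v_stage
    per = _steps_per_sample(plan, v)
    n_chunks = int(round(travel / (v * plan.dt_ps * per)))
    rows = []
    try:
        itg.advance(per)  # prime in-kernel energy components
        rows.append(_sample_row(itg))
        for c in range(n_chunks - 1):
            itg.advance(per)
            rows.append(_sample_row(itg))
    except SimulationBlowUp as exc:
        exc.diagnostics["partial_trace"] = _trace(rows, itg)
        raise
    if log:
        print(f"[production] {travel} nm done, t={itg.time_ps:.1f} ps",
              file=log)
    return _trace(rows, itg)


def run_experiment(config, plan: RunPlan | None = None, *,
                   temperature: float = 300.0, v_stage_m_s: float = 5.0,
                   load_mpa: float = 10.0, gamma: float = 1.0,
                   ff_params=None, integrator=None, log=None) -> pd.DataFrame:
    """Full experiment: running-in, spring attachment, production trace."""
    plan = plan or RunPlan()
    itg = integrator or make_integrator(config, temperature, v_stage_m_s,
                                        load_mpa, plan, ff_params,
                                        gamma=gamma)
    run_in(itg, plan, log=log)
    trace = production(itg, plan, log=log)
    trace.attrs["plan"] = plan
    return trace


def steady_average(trace: pd.DataFrame, discard_nm: float | None = None,
                   regime_kw: dict | None = None) -> "analysis.TraceSummary":
    """Steady-state mean/RMS shear stress and companion observables.

    The retained window starts after ``discard_nm`` of stage travel *and*
    after the first slip event (if the trace shows stick-slip); the regime
    label, slip events and rho_Uh come from :mod:`zwitterslide.analysis`.
    """
    if discard_nm is None:
        plan = trace.attrs.get("plan")
        discard_nm = plan.discard_nm if plan is not None else 0.0
    return analysis.summarize_trace(trace, discard_nm,
                                    **(regime_kw or {}))


def load_cycle(config, loads_mpa=None, plan: RunPlan | None = None, *,
               temperature: float = 300.0, v_stage_m_s: float = 5.0,
               settle_nm: float = 1.0, leg_nm: float | None = None,
               pre_stretch_nm: float = 0.0,
               gamma: float = 1.0, ff_params=None, log=None):
    """Friction load cycle 0 -> max -> 0 MPa on one continued trajectory.

    ``pre_stretch_nm`` of spring-driven sliding before the first measured
    leg lets the spring load up and the contact reach steady sliding, so
    every leg is measured under comparable conditions (the first leg would
    otherwise contain the zero-elongation start-up ramp).

    Returns (legs, merged): ``legs`` is a list of (load, direction, trace,
    summary); ``merged`` a DataFrame per distinct load with loading and
    unloading means, their average, and the hysteresis |loading-unloading|.
    """
    plan = plan or RunPlan()
    if loads_mpa is None:
        loads_mpa = [0.0, 10.0, 20.0, 10.0, 0.0]
    itg = make_integrator(config, temperature, v_stage_m_s, loads_mpa[0],
                          plan, ff_params, gamma=gamma)
    run_in(itg, plan, log=log)
    if pre_stretch_nm > 0:
        production(itg, plan, travel_nm=pre_stretch_nm, log=None)
    legs = []
    peak = max(loads_mpa)
    seen_peak = False
    for li, load in enumerate(loads_mpa):
        itg.load = LoadParams(load)
        itg._load_fz = itg.load.force_on(itg.area)
        itg._forces_fresh = False
        if li > 0 and settle_nm > 0:
            production(itg, plan, travel_nm=settle_nm, log=None)
        trace = production(itg, plan, travel_nm=leg_nm, log=log)
        trace.attrs["plan"] = plan
        trace.attrs["load_mpa"] = load
        summ = steady_average(trace)
        if load == peak:
            seen_peak = True
        direction = "unloading" if (seen_peak and load != peak) else "loading"
        legs.append((load, direction, trace, summ))
    rows = []
    for load in sorted({l for l, *_ in legs}):
        means = {"loading": [], "unloading": []}
        rmss = []
        for l, direction, _, s in legs:
            if l == load:
                means[direction].append(s.mean_shear_mpa)
                rmss.append(s.rms_shear_mpa)
        m_load = float(np.mean(means["loading"])) if means["loading"] else np.nan
        m_unload = (float(np.mean(means["unloading"]))
                    if means["unloading"] else np.nan)
        both = means["loading"] + means["unloading"]
        rows.append({"load_mpa": load, "mean_loading": m_load,
                     "mean_unloading": m_unload,
                     "mean_shear_mpa": float(np.mean(both)),
                     "rms_shear_mpa": float(np.mean(rmss)),
                     "hysteresis_mpa": (abs(m_load - m_unload)
                                        if np.isfinite(m_unload) else np.nan)})
    return legs, pd.DataFrame(rows)


def velocity_sweep(config, velocities_m_s, plan=None, **kw):
    """Independent experiments over a stage-velocity grid; returns summaries."""
    out = {}
    for v in velocities_m_s:
        trace = run_experiment(config, plan, v_stage_m_s=v, **kw)
        out[v] = steady_average(trace)
    return out


def temperature_sweep(config, temperatures_k, plan=None, **kw):
    out = {}
    for t in temperatures_k:
        trace = run_experiment(config, plan, temperature=t, **kw)
        out[t] = steady_average(trace)
    return out
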