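"""YAML experiment configuration.

A single mapping fully captures an experiment; every key has a default so a
minimal file like::

    system:
      scale: desk          # or "full", or explicit target_cell: [8.32, 14.41]
      charge_on: true
    conditions:
      temperature_K: 300
      v_stage_m_s: 5.0
      load_mpa: 10.0
    plan:
      production_nm: 8.0

runs out of the box.  See DEFAULTS for the full schema.
"""

from __future__ import annotations

import copy

import yaml

from . import geometry
from .protocol import RunPlan, desk_plan

DEFAULTS = {
    "system": {
        "scale": "desk",            # "desk" | "full"
        "target_cell": None,        # explicit [l_x, l_y] overrides scale
        "molecule_spacing": 0.82,
        "phi_window": [15.0, 25.0],
        "charge_on": True,
        "q": 0.25,
        "initial_gap": 0.5,
        "tilt_deg": geometry.DEFAULT_TILT_DEG,
        "seed": 0,
    },
    "conditions": {
        "temperature_K": 300.0,
        "v_stage_m_s": 5.0,
        "load_mpa": 10.0,
        "gamma_ps": 1.0,
    },
    "plan": {
        "scale": None,              # None = follow system.scale
        "run_in_nm": None,
        "production_nm": None,
        "discard_nm": None,
        "sample_dx_nm": None,
        "dt_ps": None,
        "seed": 1,
    },
}


def _deep_update(base, extra):
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None, overrides=None) -> dict:
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            _deep_update(cfg, yaml.safe_load(fh) or {})
    _deep_update(cfg, overrides or {})
    return cfg


def build_system_from(cfg: dict):
    sy = cfg["system"]
    if sy.get("target_cell"):
        sol = geometry.find_commensurate_supercell(
            sy["molecule_spacing"], tuple(sy["phi_window"]), 20.0, 1e-3,
            target_cell=tuple(sy["target_cell"]))
    elif sy["scale"] == "full":
        sol = geometry.full_cell()
    else:
        sol = geometry.desk_cell()
    return geometry.build_system(
        sol, charge_on=sy["charge_on"], q=sy["q"],
        initial_gap=sy["initial_gap"], seed=sy["seed"],
        tilt_deg=sy["tilt_deg"])


def plan_from(cfg: dict) -> RunPlan:
    pl = dict(cfg["plan"])
    scale = pl.pop("scale") or cfg["system"]["scale"]
    base = desk_plan() if scale == "desk" else RunPlan()
    kw = {k: v for k, v in pl.items() if v is not None}
    from dataclasses import replace
    return replace(base, **kw)
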