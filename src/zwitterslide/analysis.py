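"""Derived friction observables.

- hooking fraction h: percentage of molecules (counted over both layers)
  whose CA head bead crosses the opposing layer's mean CA plane by at least
  a margin delta_z - the degree of head-group interpenetration;
- interlayer distance: mean z separation of the two rigid layers;
- regime classification: stick-slip (>= 2 detected slip events: a drop of
  more than f_drop of the running stress peak within a short stage travel)
  vs smooth sliding;
- critical velocity v_c: midpoint between the fastest stick-slip and the
  slowest smooth velocity of a sweep;
- Pearson correlation rho_Uh between total potential energy U and h over
  the steady window (transient interlocking lowers U, so stick-slip runs
  show systematic anticorrelation; in smooth sliding h = 0 and rho_Uh is
  undefined);
- closed-form estimates: the transient-bond energy of a cation bridging two
  opposing-layer anions versus its flat-layer position, and k_B T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import KB, KC


@dataclass(frozen=True)
class HookingDefinition:
    """Reference-plane rule for the hooking fraction.

    ``plane_species`` selects which bead species defines the opposing
    reference plane (CA by default; AN selectable); ``delta_z`` is the
    crossing margin in nm.
    """
    plane_species: str = "CA"
    delta_z: float = 0.0


@dataclass
class TraceSummary:
    """Steady-state digest of one friction trace."""
    mean_shear_mpa: float
    rms_shear_mpa: float
    regime: str                      # "smooth" | "stick-slip" | "unconverged"
    rho_uh: float                    # NaN when undefined (smooth sliding)
    mean_distance_nm: float
    mean_hooking_pct: float
    n_slips: int
    slip_positions_nm: tuple
    discard_nm: float
    retained_nm: float

    def as_dict(self):
        d = dict(self.__dict__)
        d["slip_positions_nm"] = list(self.slip_positions_nm)
        return d


_SPECIES_CODE = {"CA": 0, "R1": 1, "R2": 2, "R3": 3, "AN": 4,
                 "NP1": 5, "NP2": 6}


def hooking_fraction(config, positions=None,
                     definition: HookingDefinition | None = None) -> float:
    """Percent of molecules whose head crosses the opposing head plane.

    For each layer the reference plane is the opposing layer's mean CA
    (or AN) z level; a SUB molecule is hooked when its CA bead lies at
    least delta_z above the SUP plane, and vice versa.  Both layers are
    counted; the denominator is the total molecule number.
    """
    definition = definition or HookingDefinition()
    sp = _SPECIES_CODE[definition.plane_species]
    pos = config.positions if positions is None else positions
    species = config.species
    layer = config.layer
    if species is None or layer is None:
        raise ValueError("configuration lacks species/layer tags")
    dz = definition.delta_z
    z = pos[:, 2]
    sel_sub = (species == sp) & (layer == 0)
    sel_sup = (species == sp) & (layer == 1)
    ca_sub = (species == 0) & (layer == 0)
    ca_sup = (species == 0) & (layer == 1)
    plane_sup = z[sel_sup].mean()
    plane_sub = z[sel_sub].mean()
    hooked = (int(np.sum(z[ca_sub] >= plane_sup + dz)) +
              int(np.sum(z[ca_sup] <= plane_sub - dz)))
    n_total = int(np.sum(ca_sub) + np.sum(ca_sup))
    return 100.0 * hooked / n_total


def interlayer_distance(config, positions=None) -> float:
    """Mean z of SUP rigid beads minus mean z of SUB rigid beads (nm)."""
    pos = config.positions if positions is None else positions
    z = pos[:, 2]
    return float(z[config.rigid_translating].mean() - z[config.frozen].mean())


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_rho(u_series, h_series, method: str = "streaming"):
    """Pearson correlation coefficient between U and h series.

    Returns NaN ("undefined") when either variance vanishes - in smooth
    sliding h is identically 0 so rho_Uh only exists for stick-slip runs.
    ``method='twopass'`` uses the textbook two-pass formula (cross-check).
    """
    u = np.asarray(u_series, dtype=float)
    h = np.asarray(h_series, dtype=float)
    if u.shape != h.shape:
        raise ValueError("series length mismatch")
    n = len(u)
    if n < 2:
        return float("nan")
    if method == "twopass":
        du = u - u.mean()
        dh = h - h.mean()
        vu = float(du @ du)
        vh = float(dh @ dh)
        if vu == 0.0 or vh == 0.0:
            return float("nan")
        return float(du @ dh) / math.sqrt(vu * vh)
    # single-pass (Welford-style) running co-moments
    mu = mh = 0.0
    cuu = chh = cuh = 0.0
    for k in range(n):
        k1 = k + 1.0
        du = u[k] - mu
        dh = h[k] - mh
        mu += du / k1
        mh += dh / k1
        cuu += du * (u[k] - mu)
        chh += dh * (h[k] - mh)
        cuh += du * (h[k] - mh)
    if cuu <= 0.0 or chh <= 0.0:
        return float("nan")
    return cuh / math.sqrt(cuu * chh)


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlipDetection:
    """Slip-event thresholds.

    A slip is a drop of the smoothed shear stress by at least ``f_drop`` of
    the running local peak, completed within ``dx_slip`` nm of stage travel,
    with an absolute drop of at least ``min_drop_frac`` of the trace's
    (5th-95th percentile) span - the latter rejects thermal ripple on
    near-zero smooth-sliding traces.
    """
    f_drop: float = 0.5
    dx_slip: float = 1.0
    smooth_window_nm: float = 0.25
    min_drop_frac: float = 0.25
    rearm_frac: float = 0.1       # rise off the trough before re-arming
    min_events: int = 2
    min_window_nm: float = 2.0


def detect_slips(x_stage, shear, det: SlipDetection | None = None):
    """Slip-event positions (nm of stage travel) in a shear trace."""
    det = det or SlipDetection()
    x = np.asarray(x_stage, dtype=float)
    s = np.asarray(shear, dtype=float)
    if len(x) < 4:
        return []
    dx = np.median(np.diff(x))
    w = max(int(round(det.smooth_window_nm / max(dx, 1e-12))), 1)
    if w > 1:
        kernel = np.ones(w) / w
        s = np.convolve(s, kernel, mode="same")
    lo, hi = np.percentile(s, [5.0, 95.0])
    span = hi - lo
    events = []
    peak_v, peak_x = s[0], x[0]
    armed = True
    trough = s[0]
    for k in range(1, len(s)):
        if not armed:
            # wait for the stress to climb off the post-slip trough before
            # tracking a new peak, so one slip is not counted twice
            trough = min(trough, s[k])
            if s[k] > trough + det.rearm_frac * span:
                armed = True
                peak_v, peak_x = s[k], x[k]
            continue
        if s[k] >= peak_v:
            peak_v, peak_x = s[k], x[k]
            continue
        drop = peak_v - s[k]
        if (s[k] <= peak_v * (1.0 - det.f_drop)
                and (x[k] - peak_x) <= det.dx_slip
                and drop >= det.min_drop_frac * span and span > 0):
            events.append(float(x[k]))
            armed = False
            trough = s[k]
    return events


def classify_regime(trace: pd.DataFrame,
                    det: SlipDetection | None = None) -> tuple:
    """('stick-slip'|'smooth'|'unconverged', slip positions)."""
    det = det or SlipDetection()
    x = trace["x_stage"].to_numpy()
    if len(x) < 4 or (x[-1] - x[0]) < det.min_window_nm:
        return "unconverged", []
    events = detect_slips(x, trace["shear_mpa"].to_numpy(), det)
    regime = "stick-slip" if len(events) >= det.min_events else "smooth"
    return regime, events


def critical_velocity(regimes_by_velocity: dict) -> tuple:
    """Midpoint of the (fastest stick-slip, slowest smooth) bracket.

    ``regimes_by_velocity`` maps stage velocity (m/s) to a regime label or a
    TraceSummary.  Raises ValueError("not bracketed") when the grid does not
    span both regimes in the expected order.
    """
    ss, sm = [], []
    for v, r in regimes_by_velocity.items():
        label = getattr(r, "regime", r)
        if label == "stick-slip":
            ss.append(v)
        elif label == "smooth":
            sm.append(v)
    if not ss or not sm or max(ss) >= min(sm):
        raise ValueError("not bracketed")
    return 0.5 * (max(ss) + min(sm)), (max(ss), min(sm))


# ---------------------------------------------------------------------------
# steady-state summary
# ---------------------------------------------------------------------------

def summarize_trace(trace: pd.DataFrame, discard_nm: float = 0.0,
                    det: SlipDetection | None = None) -> TraceSummary:
    """Classify, apply the discard rule, and average the retained window.

    The retained window starts after ``discard_nm`` of stage travel and, in
    stick-slip, not before the first slip event.  A stick-slip trace whose
    first slip leaves no averaging room is flagged unconverged.
    """
    det = det or SlipDetection()
    x = trace["x_stage"].to_numpy()
    x0 = x[0]
    regime, events = classify_regime(trace, det)
    start = x0 + discard_nm
    if regime == "stick-slip" and events:
        start = max(start, events[0])
    keep = trace[x >= start]
    retained = float(x[-1] - start)
    if len(keep) < 4 or retained < 0.25 * det.min_window_nm:
        regime = "unconverged"
        keep = trace
        retained = float(x[-1] - x0)
    shear = keep["shear_mpa"].to_numpy()
    mean = float(shear.mean())
    rms = float(shear.std())
    rho = float("nan")
    if regime == "stick-slip":
        rho = pearson_rho(keep["U_ev"].to_numpy(),
                          keep["hooking_pct"].to_numpy())
    return TraceSummary(
        mean_shear_mpa=mean, rms_shear_mpa=rms, regime=regime, rho_uh=rho,
        mean_distance_nm=float(keep["d_nm"].mean()),
        mean_hooking_pct=float(keep["hooking_pct"].mean()),
        n_slips=len(events), slip_positions_nm=tuple(events),
        discard_nm=float(start - x0), retained_nm=retained)


# ---------------------------------------------------------------------------
# closed-form estimates
# ---------------------------------------------------------------------------

def transient_bond_energy(q: float = 0.25, r_hook: float = 0.41,
                          r_flat: float = 0.51) -> float:
    """Coulomb gain of a cation bridging two opposing anions, in meV.

    The cation sits midway between two adjacent anions of the opposing
    layer (distance r_hook each) versus its flat-layer configuration
    (distance r_flat each): Delta E = 2 k_C q^2 (1/r_hook - 1/r_flat),
    about 85 meV at the model charges - comparable to k_B T near the
    friction-peak temperature.
    """
    if q < 0 or r_hook <= 0 or r_flat <= 0:
        raise ValueError("q must be >= 0 and distances positive")
    return 2.0 * KC * q * q * (1.0 / r_hook - 1.0 / r_flat) * 1e3


def thermal_energy(temperature_k: float) -> float:
    """k_B T in meV (~86 meV at 1000 K)."""
    if temperature_k < 0:
        raise ValueError("temperature must be non-negative")
    return KB * temperature_k * 1e3
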