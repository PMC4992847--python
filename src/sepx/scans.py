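"""Parameter-plane sweeps: maximum-voltage maps and threshold boundaries.

A clamp scan holds the membrane at ``v_c`` for ``tau_c`` (gating relaxes in
closed form), releases, and records the maximum voltage of the free
evolution for every grid cell.  The fire/no-fire border of the resulting
map samples the projection of the separatrix into the (tau_c, v_c) plane:
depolarized rows flip fire -> no-fire as the clamp outlasts the threshold
time (adaptation carries the state across the separatrix), hyperpolarized
rows flip no-fire -> fire (post-inhibitory facilitation).  In the high
voltage region a second border appears where the released trajectory has
no depolarizing phase at all (the dv/dt = 0 border).

A pulse scan plays rectangular or ramp currents of given amplitude and
duration from rest; the threshold (amplitude, duration) pairs form the
projection of the separatrix into the stimulus-parameter plane.

For the 2D piecewise-linear model both clamp borders are analytic, which
makes the scans exactly checkable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .dynamics import DEFAULT_DT, DEFAULT_T_END, classify_states, evolve_batch, rest_state
from .exceptions import SepxError
from .models import NeuronModel, PWL2DModel, QIFModel, piecewise_f
from .separatrix import pwl2d_separatrix
from .threshold import clamp_relax

__all__ = [
    "VmaxMap",
    "clamp_scan",
    "pulse_scan",
    "extract_boundary",
    "refine_boundary",
    "analytic_clamp_boundary",
    "analytic_zero_rate_boundary",
]

log = logging.getLogger("sepx")

#: default scan grids (all overridable)
PWL2D_VC_GRID = np.round(np.arange(-30.0, 40.0 + 1e-9, 0.5), 6)
PWL2D_TAU_GRID = np.round(np.arange(0.1, 20.0 + 1e-9, 0.1), 6)
HH_VC_GRID = np.round(np.arange(-90.0, -30.0 + 1e-9, 2.0), 6)
HH_TAU_GRID = np.round(np.arange(0.5, 25.0 + 1e-9, 0.5), 6)


@dataclass
class VmaxMap:
    """Grid of maximum post-stimulus voltages.

    ``axis1`` is the clamp voltage (or pulse amplitude), ``axis2`` the
    clamp duration (or pulse duration); ``vmax[i, j]`` corresponds to
    ``(axis1[i], axis2[j])`` and ``fired = vmax >= AP criterion`` (QIF:
    reset occurred).
    """

    axis1: np.ndarray
    axis2: np.ndarray
    vmax: np.ndarray
    fired: np.ndarray
    model: str
    protocol_kind: str  # "clamp" | "step" | "ramp"
    axis_names: tuple[str, str] = ("v_c", "tau_c")

    def to_dataframe(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {
                self.axis_names[0]: a1.ravel(),
                self.axis_names[1]: a2.ravel(),
                "vmax": self.vmax.ravel(),
                "fired": self.fired.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# clamp scan
# ---------------------------------------------------------------------------


def clamp_scan(
    model: NeuronModel,
    v_c_grid=None,
    tau_c_grid=None,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> VmaxMap:
    """Maximum free-evolution voltage after every (v_c, tau_c) clamp.

    The settled resting state is computed once (200 time-unit settle) and
    the clamped gating relaxation is evaluated in closed form, so each grid
    cell costs one free-evolution trajectory; all cells are integrated as
    one batch.  Cells whose integration fails are NaN-flagged and reported,
    the scan continues.
    """
    if v_c_grid is None or tau_c_grid is None:
        defaults = {
            "pwl2d": (PWL2D_VC_GRID, PWL2D_TAU_GRID),
            "hh": (HH_VC_GRID, HH_TAU_GRID),
        }
        d1, d2 = defaults.get(model.name, (None, None))
        v_c_grid = v_c_grid if v_c_grid is not None else d1
        tau_c_grid = tau_c_grid if tau_c_grid is not None else d2
        if v_c_grid is None or tau_c_grid is None:
            raise SepxError(f"no default clamp grids for {model.name}; pass them")
    v_c_grid = np.asarray(v_c_grid, dtype=float)
    tau_c_grid = np.asarray(tau_c_grid, dtype=float)
    if v_c_grid.size == 0 or tau_c_grid.size == 0:
        raise SepxError("clamp_scan grids must be non-empty")

    rest = rest_state(model)
    gating0 = rest[1:]
    n1, n2 = v_c_grid.size, tau_c_grid.size
    states = np.empty((n1 * n2, model.dim))
    for i, v_c in enumerate(v_c_grid):
        g = clamp_relax(model, gating0, float(v_c), tau_c_grid)  # (n2, g)
        states[i * n2 : (i + 1) * n2, 0] = v_c
        states[i * n2 : (i + 1) * n2, 1:] = g
    fired, vmax, _ = classify_states(
        model, states, i_e=0.0, t_end=t_end, dt=dt, on_nonfinite="nan"
    )
    n_bad = int(np.sum(~np.isfinite(vmax)))
    if n_bad:
        log.warning("clamp_scan: %d/%d cells failed (NaN)", n_bad, n1 * n2)
    return VmaxMap(
        axis1=v_c_grid,
        axis2=tau_c_grid,
        vmax=vmax.reshape(n1, n2),
        fired=fired.reshape(n1, n2),
        model=model.name,
        protocol_kind="clamp",
    )


# ---------------------------------------------------------------------------
# pulse scan
# ---------------------------------------------------------------------------


def pulse_scan(
    model: NeuronModel,
    kind: str,
    amp_grid,
    dur_grid,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> VmaxMap:
    """Maximum voltage after step or ramp pulses (amplitude x duration).

    Each pulse starts from the settled resting state; a ramp rises linearly
    from 0 to the given amplitude over the pulse duration.  v_max is
    tracked from pulse onset through the subsequent free evolution.
    """
    if kind not in ("step", "ramp"):
        raise SepxError("pulse kind must be 'step' or 'ramp'")
    amp_grid = np.asarray(amp_grid, dtype=float)
    dur_grid = np.asarray(dur_grid, dtype=float)
    if amp_grid.size == 0 or dur_grid.size == 0:
        raise SepxError("pulse_scan grids must be non-empty")
    rest = rest_state(model)
    n1, n2 = amp_grid.size, dur_grid.size
    vmax = np.empty((n1, n2))
    fired = np.zeros((n1, n2), dtype=bool)
    for j, dur in enumerate(dur_grid):
        states0 = np.tile(rest, (n1, 1))
        if kind == "step":
            drive = lambda t: amp_grid
        else:
            drive = lambda t: amp_grid * min(t / dur, 1.0)
        on = evolve_batch(model, states0, t_end=float(dur), dt=dt, i_e_fn=drive)
        rem = max(t_end - float(dur), 0.0)
        off = evolve_batch(model, on["final"], t_end=rem, dt=dt, i_e=0.0)
        vmax[:, j] = np.maximum(on["v_max"], off["v_max"])
        if isinstance(model, QIFModel):
            fired[:, j] = on["fired"] | off["fired"]
        else:
            fired[:, j] = vmax[:, j] >= model.v_ap
    return VmaxMap(
        axis1=amp_grid,
        axis2=dur_grid,
        vmax=vmax,
        fired=fired,
        model=model.name,
        protocol_kind=kind,
        axis_names=("amp", "dur"),
    )


# ---------------------------------------------------------------------------
# boundary extraction
# ---------------------------------------------------------------------------


def _line_flips(flags: np.ndarray) -> np.ndarray:
    return np.nonzero(np.diff(flags.astype(int)))[0]


def extract_boundary(
    vmax_map: VmaxMap,
    model: NeuronModel | None = None,
    axis: str = "tau_c",
    tol: float = 1e-3,
    border: str = "separatrix",
    rise_eps: float = 1e-6,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Extract the fire/no-fire border of a V_max map.

    For each scan line the flip of the firing indicator is located; if a
    ``model`` is given the flip is refined by bisection in the scanned
    parameter (to ``tol``), otherwise the bracketing-cell midpoint is
    returned.  ``border="separatrix"`` uses the AP indicator (the
    low-voltage border, the separatrix projection); ``border="zero-rate"``
    uses the "any further depolarization after release" indicator
    ``v_max > v_c + rise_eps`` (the high-voltage dv/dt = 0 border of clamp
    maps).  Lines with no flip are omitted (logged); lines with several
    flips contribute all of them, flagged via the ``n_flips`` column.
    """
    if vmax_map.protocol_kind != "clamp" and border == "zero-rate":
        raise SepxError("zero-rate border only applies to clamp maps")
    if axis not in vmax_map.axis_names:
        raise SepxError(f"axis must be one of {vmax_map.axis_names}")
    along_axis2 = axis == vmax_map.axis_names[1]

    if border == "separatrix":
        flags = vmax_map.fired
    else:
        flags = vmax_map.vmax > (vmax_map.axis1[:, None] + rise_eps)

    rows = []
    fixed_grid = vmax_map.axis1 if along_axis2 else vmax_map.axis2
    scan_grid = vmax_map.axis2 if along_axis2 else vmax_map.axis1
    fixed_name = "v_c" if along_axis2 else vmax_map.axis_names[1]
    for i, fixed in enumerate(fixed_grid):
        line = flags[i, :] if along_axis2 else flags[:, i]
        flips = _line_flips(line)
        if flips.size == 0:
            log.info("extract_boundary: no flip on line %s=%g", axis, fixed)
            continue
        for k in flips:
            rows.append(
                {
                    fixed_name: float(fixed),
                    axis: 0.5 * (scan_grid[k] + scan_grid[k + 1]),
                    "_lo": float(scan_grid[k]),
                    "_hi": float(scan_grid[k + 1]),
                    "_fired_lo": bool(line[k]),
                    "direction": "fire_to_quiet" if line[k] else "quiet_to_fire",
                    "n_flips": int(flips.size),
                    "refined": False,
                }
            )
    df = pd.DataFrame(rows)
    refine = (
        model is not None
        and border == "separatrix"
        and vmax_map.protocol_kind == "clamp"
        and len(df) > 0
    )
    if refine:
        df[axis] = _refine_flips_batch(
            model,
            along_axis2,
            df[fixed_name].to_numpy(),
            df["_lo"].to_numpy(),
            df["_hi"].to_numpy(),
            df["_fired_lo"].to_numpy(),
            tol,
            t_end,
            dt,
        )
        df["refined"] = True
    if len(df):
        df = df.drop(columns=["_lo", "_hi", "_fired_lo"])
    return df


def _clamp_relax_rows(model, gating0, v_rows, tau_rows):
    """Closed-form clamp relaxation with per-row clamp voltage and time."""
    xinf = np.atleast_2d(model.gating_inf(v_rows))
    taux = np.atleast_2d(model.gating_tau(v_rows))
    return xinf + (gating0 - xinf) * np.exp(-tau_rows[:, None] / taux)


def _refine_flips_batch(
    model, along_axis2, fixed, lo, hi, fired_lo, tol, t_end, dt
):
    """Bisect all clamp-map flips at once (one batch classify per iteration)."""
    rest = rest_state(model)
    gating0 = rest[1:]
    lo = lo.astype(float).copy()
    hi = hi.astype(float).copy()
    span = float(np.max(hi - lo))
    n_iter = max(1, int(math.ceil(math.log2(max(span / tol, 1.0)))))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        v_c = fixed if along_axis2 else mid
        tau_c = mid if along_axis2 else fixed
        states = np.concatenate(
            [v_c[:, None], _clamp_relax_rows(model, gating0, v_c, tau_c)], axis=1
        )
        f, _, _ = classify_states(model, states, i_e=0.0, t_end=t_end, dt=dt)
        same = f == fired_lo
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)
    return 0.5 * (lo + hi)


def refine_boundary(
    model: NeuronModel,
    tau_c: float,
    v_lo: float,
    v_hi: float,
    tol: float = 1e-3,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> float:
    """Bisect the clamp-boundary voltage at a fixed clamping duration.

    The classifier must flip between ``v_lo`` and ``v_hi``; returns the
    flip voltage to ``tol``.  This is the form used for the threshold
    self-consistency identity ``v_c = theta(X(v_c, tau_c); 0)``.
    """
    rest = rest_state(model)
    gating0 = rest[1:]

    def fires_at(v_c: float) -> bool:
        g = clamp_relax(model, gating0, float(v_c), float(tau_c))
        st = np.concatenate([[v_c], np.atleast_1d(g)])
        f, _, _ = classify_states(model, st[None, :], i_e=0.0, t_end=t_end, dt=dt)
        return bool(f[0])

    f_lo = fires_at(v_lo)
    if fires_at(v_hi) == f_lo:
        raise SepxError(
            f"no clamp-boundary flip in [{v_lo}, {v_hi}] at tau_c={tau_c}"
        )
    n_iter = max(1, int(math.ceil(math.log2(max((v_hi - v_lo) / tol, 1.0)))))
    for _ in range(n_iter):
        mid = 0.5 * (v_lo + v_hi)
        if fires_at(mid) == f_lo:
            v_lo = mid
        else:
            v_hi = mid
    return 0.5 * (v_lo + v_hi)


# ---------------------------------------------------------------------------
# analytic clamp boundaries of the 2D piecewise-linear model
# ---------------------------------------------------------------------------


def analytic_clamp_boundary(model: PWL2DModel, v_c, i_e: float = 0.0):
    """Threshold clamping time at v_c: the separatrix-projection border.

    From rest (w = 0) the clamped recovery variable follows
    ``w(tau) = k_w v_c (1 - exp(-tau/tau_w))``; release fires while w is
    below the separatrix line, so the border is

        tau_c* = -tau_w * ln(1 - (k_theta v_c + b_theta) / (k_w v_c)).

    NaN where no crossing exists (the clamp never carries the state across
    the line, e.g. hyperpolarized v_c whose firing boundary is the winding
    separatrix branch instead).
    """
    line = pwl2d_separatrix(model, i_e)
    v_c = np.asarray(v_c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = line.w_of(v_c) / (model.k_w * v_c)
        out = np.where(
            (ratio > 0.0) & (ratio < 1.0), -model.tau_w * np.log(1.0 - ratio), np.nan
        )
    return out if out.ndim else float(out)


def analytic_zero_rate_boundary(model: PWL2DModel, v_c, i_e: float = 0.0):
    """Clamping time beyond which release starts with dv/dt <= 0.

    The released trajectory lacks a depolarizing phase once the clamped
    recovery current reaches the v-nullcline: w(tau) = f(v_c) + i_e, i.e.

        tau_c* = -tau_w * ln(1 - (f(v_c) + i_e) / (k_w v_c)).
    """
    v_c = np.asarray(v_c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (piecewise_f(model.f, v_c) + i_e) / (model.k_w * v_c)
        out = np.where(
            (ratio > 0.0) & (ratio < 1.0), -model.tau_w * np.log(1.0 - ratio), np.nan
        )
    return out if out.ndim else float(out)
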