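"""Instantaneous thresholds, voltage-clamp relaxation and threshold traces.

The *instantaneous threshold voltage* theta(X; i_e) is the voltage value
such that instantaneously shifting the membrane potential across it — with
the gating/recovery state X frozen at the instant of the shift — flips the
spike/no-spike outcome of the subsequent free evolution.  It is the voltage
coordinate of the separatrix at X and is found here by bisection over the
voltage axis (hyperpolarized thresholds, below rest, are allowed).

During an ideal voltage clamp at ``v_c`` every adaptation-form variable
relaxes exponentially, ``x(t) = x_inf(v_c) + (x0 - x_inf(v_c))
exp(-t / tau_x(v_c))``, so the post-clamp gating state — and with it the
threshold trace theta(t) — is available in closed form.  The threshold
evolution equation

    d(theta)/dt = d(theta)/d(i_e) * di_e/dt
                  + sum_x  d(theta)/dx * (x_inf(v) - x) / tau_x(v)

is integrated along such protocols, with the partial derivatives taken
analytically where the separatrix is analytic (QIF, piecewise-linear) and
by central finite differences of the bisection threshold otherwise (HH).
When a single gating variable with constant tau dominates and theta is
linear in it, the trace collapses to the classic first-order relaxation
theta(t) = theta_inf + (theta_0 - theta_inf) exp(-t / tau_theta); the
:func:`eq1_reduction_fit` helper measures how well that reduction holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np

from .dynamics import (
    DEFAULT_DT,
    DEFAULT_T_END,
    StimulusProtocol,
    classify_states,
    rest_state,
)
from .exceptions import BracketError, SepxError
from .models import NeuronModel, PWL2DModel, PWL3DModel, QIFModel
from .separatrix import (
    bisect_boundary_batch,
    pwl2d_separatrix,
    pwl3d_separatrix,
    qif_threshold,
)

__all__ = [
    "InstantaneousThreshold",
    "ThresholdTrace",
    "Eq1Fit",
    "instantaneous_threshold",
    "instantaneous_threshold_batch",
    "clamp_relax",
    "post_clamp_fires",
    "threshold_ode",
    "eq1_reduction_fit",
]

#: default voltage bisection brackets per model family
_DEFAULT_BRACKETS = {
    "qif": (-20.0, 39.0),
    "fhn": (-2.5, 2.0),
    "boltzmann-fhn": (-2.5, 2.0),
    "fhn3d": (-2.5, 2.0),
    "pwl2d": (-40.0, 24.9),
    "pwl3d": (-40.0, 49.9),
    "hh": (-90.0, -10.0),
}


def _default_bracket(model: NeuronModel) -> tuple[float, float]:
    try:
        return _DEFAULT_BRACKETS[model.name]
    except KeyError:  # pragma: no cover
        raise SepxError(f"no default threshold bracket for {model.name}; pass one")


@dataclass
class InstantaneousThreshold:
    theta: float
    gating_state: np.ndarray
    i_e_after: float
    bracket: tuple[float, float]
    tol: float
    n_flips: int = 1


@dataclass
class ThresholdTrace:
    """Threshold versus time along a protocol, by two independent routes."""

    times: np.ndarray
    theta: np.ndarray  # from the threshold-evolution ODE
    theta_direct: np.ndarray  # from direct bisection at each node
    protocol: StimulusProtocol
    method: str  # "analytic" | "finite_difference"


# ---------------------------------------------------------------------------
# instantaneous threshold by voltage bisection
# ---------------------------------------------------------------------------


def instantaneous_threshold_batch(
    model: NeuronModel,
    gating_states: np.ndarray,
    i_e_after: float = 0.0,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-6,
    pre_scan: int = 20,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Thresholds for many frozen gating states at once.

    For each row of ``gating_states`` the voltage axis is pre-scanned on
    ``pre_scan`` points to bracket classifier flips (if several flips are
    present — graded, quasi-threshold responses — the one nearest the
    resting potential is kept and a warning is issued), then refined by
    batched bisection to ``tol``.
    """
    gating_states = np.atleast_2d(np.asarray(gating_states, dtype=float))
    N = gating_states.shape[0]
    if gating_states.shape[1] != model.n_gating:
        raise SepxError(
            f"gating state has {gating_states.shape[1]} coordinates, "
            f"expected {model.n_gating}"
        )
    lo, hi = bracket if bracket is not None else _default_bracket(model)
    ie = np.broadcast_to(np.asarray(i_e_after, dtype=float), (N,))

    def classify(states, ie_rows):
        fired, _, _ = classify_states(model, states, i_e=ie_rows, t_end=t_end, dt=dt)
        return fired

    grid = np.linspace(lo, hi, pre_scan)
    # pre-scan all rows in one batch
    states = np.empty((N * pre_scan, model.dim))
    states[:, 0] = np.tile(grid, N)
    states[:, 1:] = np.repeat(gating_states, pre_scan, axis=0)
    fired = classify(states, np.repeat(ie, pre_scan)).reshape(N, pre_scan)
    v_rest = float(rest_state(model, i_e=0.0)[0])

    blo = np.empty(N)
    bhi = np.empty(N)
    for r in range(N):
        flips = np.nonzero(np.diff(fired[r]))[0]
        if flips.size == 0:
            raise BracketError(
                f"no spike/no-spike flip in bracket ({lo}, {hi}) for gating "
                f"state {gating_states[r]!r} (i_e_after={i_e_after})"
            )
        if flips.size > 1:
            warnings.warn(
                f"{flips.size} threshold flips in bracket for gating state "
                f"{gating_states[r]!r}; keeping the one nearest rest "
                "(quasi-threshold ambiguity)",
                stacklevel=2,
            )
            mids = 0.5 * (grid[flips] + grid[flips + 1])
            k = int(np.argmin(np.abs(mids - v_rest)))
        else:
            k = 0
        blo[r] = grid[flips[k]]
        bhi[r] = grid[flips[k] + 1]

    direction = np.zeros(model.dim)
    direction[0] = 1.0
    anchors = np.concatenate([np.zeros((N, 1)), gating_states], axis=1)
    s = bisect_boundary_batch(
        lambda st: classify(st, ie),
        anchors,
        direction,
        blo,
        bhi,
        tol=tol,
        check_bracket=False,
    )
    return s


def instantaneous_threshold(
    model: NeuronModel,
    gating_state=(),
    i_e_after: float = 0.0,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-6,
    pre_scan: int = 20,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> InstantaneousThreshold:
    """Instantaneous threshold voltage for one frozen gating state.

    The voltage coordinate alone is bisected; the remaining coordinates are
    frozen at ``gating_state`` for the instant of the shift and free
    thereafter.  Brackets below rest are legitimate (inhibition can create
    hyperpolarized thresholds).
    """
    g = np.atleast_1d(np.asarray(gating_state, dtype=float)).reshape(1, -1)
    if model.n_gating == 0:
        g = g.reshape(1, 0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        theta = instantaneous_threshold_batch(
            model, g, i_e_after, bracket, tol, pre_scan, t_end, dt
        )[0]
    n_flips = 1 + sum("flips" in str(w.message) for w in caught)
    for w in caught:  # re-emit outside the recording context
        warnings.warn(w.message, stacklevel=2)
    lo, hi = bracket if bracket is not None else _default_bracket(model)
    return InstantaneousThreshold(
        theta=float(theta),
        gating_state=g[0],
        i_e_after=i_e_after,
        bracket=(lo, hi),
        tol=tol,
        n_flips=n_flips,
    )


# ---------------------------------------------------------------------------
# voltage-clamp relaxation (closed form)
# ---------------------------------------------------------------------------


def clamp_relax(model: NeuronModel, x0, v_c: float, tau_c):
    """Gating state after clamping the voltage at ``v_c`` for ``tau_c``.

    Exact per-coordinate exponential relaxation toward ``x_inf(v_c)`` with
    time constant ``tau_x(v_c)``.  ``tau_c`` may be an array, in which case
    an extra leading axis is returned.
    """
    x0 = np.asarray(x0, dtype=float)
    xinf = np.asarray(model.gating_inf(v_c), dtype=float)
    tau = np.asarray(model.gating_tau(v_c), dtype=float)
    tau_c = np.asarray(tau_c, dtype=float)
    decay = np.exp(-tau_c[..., None] / tau)
    return xinf + (x0 - xinf) * decay


def post_clamp_fires(
    model: NeuronModel,
    rest,
    v_c: float,
    tau_c: float,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> bool:
    """Does the neuron fire after a voltage clamp (v_c, tau_c) from rest?

    Gating relaxes per :func:`clamp_relax`; the post-clamp evolution is
    autonomous (i_e = 0).  Equivalently: fires iff v_c lies on the firing
    side of theta(X(v_c, tau_c); 0).
    """
    rest = np.asarray(rest, dtype=float)
    gating = clamp_relax(model, rest[1:], v_c, float(tau_c))
    state = np.concatenate([[v_c], np.atleast_1d(gating)])
    fired, _, _ = classify_states(model, state[None, :], i_e=0.0, t_end=t_end, dt=dt)
    return bool(fired[0])


# ---------------------------------------------------------------------------
# analytic threshold gradients
# ---------------------------------------------------------------------------


def _theta_partials_analytic(model: NeuronModel, i_e: float):
    """(dtheta/dx vector, dtheta/di_e) for models with analytic separatrix."""
    if isinstance(model, PWL2DModel):
        line = pwl2d_separatrix(model, i_e)
        # theta(w; i_e) = (w - b_theta(i_e)) / k_theta, b_theta linear in i_e
        db_die = (model.k_w - line.k_theta) / (model.k_w - model.f.k_m)
        return np.array([1.0 / line.k_theta]), -db_die / line.k_theta
    if isinstance(model, PWL3DModel):
        pl = pwl3d_separatrix(model, i_e)
        n = pl.normal
        d_dx = np.array([-n[1] / n[0], -n[2] / n[0]])
        # the anchor point moves linearly with i_e; the normal does not
        denom = model.k_u + model.k_w - model.f.k_m
        dv_die = 1.0 / denom
        dp_die = np.array([dv_die, model.k_u * dv_die, model.k_w * dv_die])
        d_die = (n @ dp_die) / n[0]
        return d_dx, d_die
    raise SepxError(f"{model.name}: no analytic threshold gradients")


def _qif_dtheta_die(model: QIFModel, i_e: float) -> float:
    s = model.v_t + model.v_r
    disc = s * s - 4.0 * (model.v_r * model.v_t + i_e)
    if disc <= 0:
        raise SepxError(f"QIF beyond rheobase at i_e={i_e}")
    return -1.0 / math.sqrt(disc)


# ---------------------------------------------------------------------------
# threshold evolution along a protocol
# ---------------------------------------------------------------------------


def _protocol_clamp_segment(protocol: StimulusProtocol):
    clamps = [s for s in protocol.segments if s.kind == "clamp"]
    if len(clamps) > 1:
        raise SepxError("threshold_ode supports at most one clamp segment")
    return clamps[0] if clamps else None


def threshold_ode(
    model: NeuronModel,
    protocol: StimulusProtocol,
    t_grid,
    fd_step: float = 1e-3,
    bisect_tol: float = 1e-4,
    fd_bisect_tol: float | None = None,
    bracket: tuple[float, float] | None = None,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> ThresholdTrace:
    """Integrate the threshold-evolution equation along a protocol.

    Two protocol shapes are supported, matching the situations where the
    gating trajectory entering the equation is known in closed form:

    * a voltage-clamp phase (``theta(t) = theta(X(v_c, t); 0)``): the
      gating drive ``(x_inf(v_c) - x)/tau_x(v_c)`` is exact, and
      ``di_e/dt = 0`` after the clamp;
    * a pure current protocol for QIF (no gating variables): only the
      ``dtheta/di_e * di_e/dt`` term survives.

    The partial derivatives are analytic for QIF and the piecewise-linear
    models and central finite differences of the bisection threshold for
    HH (``fd_step`` per gating unit; the perturbed thresholds use the
    tighter ``fd_bisect_tol`` — default ``bisect_tol / 1000`` — so that
    bisection noise divided by the small step does not pollute the
    gradients).  The same grid is also evaluated by direct bisection,
    returned alongside for cross-validation.

    Accuracy note: the quadrature resolves only what the grid resolves.
    Fast gating transients (e.g. the sub-millisecond m-gate equilibration
    at clamp onset in HH) need nodes clustered near the start — a
    quadratically spaced grid such as ``span * linspace(0, 1, n)**2``
    works well.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 3:
        raise SepxError("t_grid must be 1-D with at least 3 nodes")
    protocol.validate()

    if isinstance(model, QIFModel):
        # theta depends on i_e only; integrate dtheta/di_e * di_e/dt
        theta0 = qif_threshold(model, protocol.i_e(t_grid[0])).theta
        fine, node_idx = _refine_grid(t_grid, 10)
        h = 1e-6
        die_fine = np.array(
            [(protocol.i_e(t + h) - protocol.i_e(max(t - h, 0.0))) / (2 * h) if t > h
             else (protocol.i_e(t + h) - protocol.i_e(t)) / h
             for t in fine]
        )
        integrand_fine = np.array(
            [_qif_dtheta_die(model, protocol.i_e(t)) for t in fine]
        ) * die_fine
        theta = theta0 + _cumulative_simpson(integrand_fine, fine)[node_idx]
        theta_direct = instantaneous_threshold_batch(
            model,
            np.zeros((t_grid.size, 0)),
            i_e_after=np.array([protocol.i_e(t) for t in t_grid]),
            bracket=bracket,
            tol=bisect_tol,
            t_end=t_end,
            dt=dt,
        )
        return ThresholdTrace(t_grid, theta, theta_direct, protocol, "analytic")

    clamp = _protocol_clamp_segment(protocol)
    if clamp is None:
        raise SepxError(
            "threshold_ode requires a clamp segment for models with gating "
            "variables (the gating trajectory must be in closed form)"
        )
    if t_grid[0] < clamp.t0 or t_grid[-1] > clamp.t1:
        raise SepxError("t_grid must lie inside the clamp segment")
    v_c = clamp.v_c
    x0 = rest_state(model)[1:]
    tau_rel = t_grid - clamp.t0
    gating = clamp_relax(model, x0, v_c, tau_rel)  # (n, g)
    xinf = np.asarray(model.gating_inf(v_c), dtype=float)
    taux = np.asarray(model.gating_tau(v_c), dtype=float)
    xdot = (xinf - gating) / taux  # (n, g)

    if isinstance(model, (PWL2DModel, PWL3DModel)):
        # analytic gradients: the integrand is closed form, so quadrature
        # can run on an internally refined grid at negligible cost
        d_dx, _ = _theta_partials_analytic(model, 0.0)
        fine, node_idx = _refine_grid(t_grid, 10)
        gating_fine = clamp_relax(model, x0, v_c, fine - clamp.t0)
        xdot_fine = (xinf - gating_fine) / taux
        integrand_fine = xdot_fine @ d_dx
        method = "analytic"
        theta_direct = instantaneous_threshold_batch(
            model, gating, i_e_after=0.0, bracket=bracket, tol=bisect_tol,
            t_end=t_end, dt=dt,
        )
        if isinstance(model, PWL2DModel):
            line = pwl2d_separatrix(model, 0.0)
            theta0 = float(line.theta_of(gating[0, 0]))
        else:
            pl = pwl3d_separatrix(model, 0.0)
            theta0 = float(pl.theta_of(gating[0, 0], gating[0, 1]))
        theta = theta0 + _cumulative_simpson(integrand_fine, fine)[node_idx]
        return ThresholdTrace(t_grid, theta, theta_direct, protocol, method)
    else:
        # finite-difference gradients: batch all (node, coordinate, sign)
        g = model.n_gating
        n = t_grid.size
        fd_tol = fd_bisect_tol if fd_bisect_tol is not None else bisect_tol / 1000.0
        pert = np.repeat(gating, 2 * g, axis=0)
        for j in range(g):
            pert[2 * j::2 * g, j] += fd_step
            pert[2 * j + 1::2 * g, j] -= fd_step
        theta_pert = instantaneous_threshold_batch(
            model, pert, i_e_after=0.0, bracket=bracket, tol=fd_tol,
            t_end=t_end, dt=dt,
        ).reshape(n, g, 2)
        grad = (theta_pert[:, :, 0] - theta_pert[:, :, 1]) / (2.0 * fd_step)
        integrand = np.sum(grad * xdot, axis=1)
        method = "finite_difference"
        theta_direct = instantaneous_threshold_batch(
            model, gating, i_e_after=0.0, bracket=bracket, tol=bisect_tol,
            t_end=t_end, dt=dt,
        )
        theta0 = float(theta_direct[0])

    theta = theta0 + _cumulative_simpson(integrand, t_grid)
    return ThresholdTrace(t_grid, theta, theta_direct, protocol, method)


def _refine_grid(t_grid: np.ndarray, factor: int):
    """Insert ``factor - 1`` nodes per interval; return (fine, node_index)."""
    parts = [
        np.linspace(a, b, factor + 1)[:-1] for a, b in zip(t_grid, t_grid[1:])
    ]
    fine = np.concatenate(parts + [t_grid[-1:]])
    node_idx = np.arange(t_grid.size) * factor
    return fine, node_idx


def _cumulative_simpson(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    from scipy.integrate import cumulative_simpson

    return np.concatenate([[0.0], cumulative_simpson(y, x=x)])


# ---------------------------------------------------------------------------
# first-order (single-exponential) reduction
# ---------------------------------------------------------------------------


@dataclass
class Eq1Fit:
    theta_inf: float
    tau_theta: float
    rms_residual: float
    flagged: bool = False
    note: str = ""


def eq1_reduction_fit(times, theta) -> Eq1Fit:
    """Least-squares fit of theta(t) = theta_inf + (theta0 - theta_inf) e^(-t/tau).

    Initialisation is deterministic (log-linearised residual regression).
    A constant trace leaves tau unidentifiable (flagged, theta_inf = the
    constant); a non-monotone trace is fitted anyway but flagged.
    """
    from scipy.optimize import least_squares

    t = np.asarray(times, dtype=float)
    y = np.asarray(theta, dtype=float)
    if t.size < 10:
        raise SepxError("eq1_reduction_fit needs at least 10 nodes")
    t = t - t[0]
    scale = max(np.ptp(y), abs(y).max(), 1e-300)
    if np.ptp(y) < 1e-12 * max(abs(y).max(), 1.0):
        return Eq1Fit(float(y.mean()), math.nan, 0.0, True, "constant trace")

    diffs = np.diff(y)
    monotone = np.all(diffs >= -1e-12 * scale) or np.all(diffs <= 1e-12 * scale)

    # deterministic init: log-linear regression of |y - y_end|
    y_inf0 = y[-1]
    resid = np.abs(y - y_inf0)
    ok = resid > 1e-6 * np.ptp(y)
    if ok.sum() >= 2:
        slope, _ = np.polyfit(t[ok], np.log(resid[ok]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 2.0
    else:  # pragma: no cover - near-degenerate
        tau0 = (t[-1] - t[0]) / 2.0
    tau0 = min(max(tau0, 1e-6), 1e6)

    def model_fn(p):
        th_inf, dlt, tau = p
        return th_inf + dlt * np.exp(-t / tau) - y

    res = least_squares(
        model_fn,
        x0=[y_inf0, y[0] - y_inf0, tau0],
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return Eq1Fit(
        theta_inf=float(res.x[0]),
        tau_theta=float(res.x[2]),
        rms_residual=rms,
        flagged=not monotone,
        note="" if monotone else "non-monotone trace",
    )
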