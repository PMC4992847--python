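"""Deterministic time integration under arbitrary stimulus protocols.

The integrator is the classic fixed-step 4th-order Runge–Kutta scheme.  It
supports

* DC / step / ramp current segments (summed into ``i_e(t)``),
* impulse stimuli, realised as exact instantaneous voltage jumps
  ``dv = q / C`` (a narrow rectangular pulse is available as an optional
  approximation),
* ideal voltage clamp: the voltage coordinate is pinned to the clamp value
  while the remaining coordinates evolve,
* the QIF hard reset (spike peak recorded, then ``v <- v_reset``).

A batched variant evolves many initial conditions simultaneously — the
workhorse behind boundary bisections and clamp/pulse parameter scans, where
thousands of trajectories differ only in their initial state or drive.

There is no randomness anywhere: identical inputs give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import ConfigError, IntegrationError, SepxError
from .models import NeuronModel, QIFModel

__all__ = [
    "Segment",
    "StimulusProtocol",
    "Trajectory",
    "integrate",
    "evolve_batch",
    "classify_ap",
    "classify_states",
    "rest_state",
    "linear_region_solution",
    "abort_by_hyperpolarization_demo",
    "DEFAULT_DT",
    "DEFAULT_T_END",
]

#: default fixed step (time units for dimensionless models, ms for HH)
DEFAULT_DT = 0.01
#: default free-evolution horizon
DEFAULT_T_END = 100.0

SEGMENT_KINDS = ("dc", "step", "ramp", "impulse", "clamp")


@dataclass(frozen=True)
class Segment:
    """One stimulus segment.

    kind:
        ``dc``/``step`` — constant current ``amp`` on [t0, t1);
        ``ramp`` — current rising linearly from ``i0`` to ``i1`` on [t0, t1);
        ``impulse`` — charge ``q`` delivered at ``t0`` (instantaneous voltage
        jump ``q / C``; set ``width`` for the rectangular approximation);
        ``clamp`` — voltage held at ``v_c`` on [t0, t1).
    """

    kind: str
    t0: float
    t1: float = 0.0
    amp: float = 0.0
    i0: float = 0.0
    i1: float = 0.0
    q: float = 0.0
    v_c: float = 0.0
    width: float = 0.0

    def __post_init__(self):
        if self.kind not in SEGMENT_KINDS:
            raise ConfigError(f"unknown segment kind {self.kind!r}")
        if self.kind != "impulse" and self.t1 < self.t0:
            raise ConfigError(f"segment {self.kind}: t1 < t0")


@dataclass
class StimulusProtocol:
    """Ordered, non-overlapping stimulus segments; i_e(t) = 0 outside them.

    Clamp segments must precede all free-evolution (current) segments —
    the post-clamp system is autonomous unless the protocol says otherwise.
    """

    segments: list[Segment] = field(default_factory=list)

    # -- constructors ---------------------------------------------------
    @classmethod
    def none(cls) -> "StimulusProtocol":
        return cls([])

    @classmethod
    def dc(cls, amp: float, t0: float = 0.0, t1: float = math.inf) -> "StimulusProtocol":
        return cls([Segment("dc", t0, t1, amp=amp)])

    @classmethod
    def step(cls, amp: float, t0: float, t1: float) -> "StimulusProtocol":
        return cls([Segment("step", t0, t1, amp=amp)])

    @classmethod
    def ramp(cls, i0: float, i1: float, t0: float, t1: float) -> "StimulusProtocol":
        return cls([Segment("ramp", t0, t1, i0=i0, i1=i1)])

    @classmethod
    def impulse(cls, q: float, t0: float = 0.0, width: float = 0.0) -> "StimulusProtocol":
        return cls([Segment("impulse", t0, q=q, width=width)])

    @classmethod
    def clamp(cls, v_c: float, tau_c: float, t0: float = 0.0) -> "StimulusProtocol":
        return cls([Segment("clamp", t0, t0 + tau_c, v_c=v_c)])

    def then(self, other: "StimulusProtocol | Segment") -> "StimulusProtocol":
        segs = other.segments if isinstance(other, StimulusProtocol) else [other]
        return StimulusProtocol(self.segments + list(segs))

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        timed = [s for s in self.segments if s.kind != "impulse"]
        timed.sort(key=lambda s: s.t0)
        for a, b in zip(timed, timed[1:]):
            if b.t0 < a.t1:
                raise ConfigError(
                    f"overlapping segments: {a.kind}[{a.t0},{a.t1}) and "
                    f"{b.kind}[{b.t0},{b.t1})"
                )
        clamp_end = max((s.t1 for s in timed if s.kind == "clamp"), default=-math.inf)
        free_start = min(
            (s.t0 for s in self.segments if s.kind not in ("clamp",)), default=math.inf
        )
        if clamp_end > free_start:
            raise ConfigError("clamp segments must precede free-evolution segments")

    # -- evaluation -----------------------------------------------------
    def i_e(self, t: float) -> float:
        """External current drive at time t (impulse jumps excluded)."""
        tot = 0.0
        for s in self.segments:
            if s.kind in ("dc", "step") and s.t0 <= t < s.t1:
                tot += s.amp
            elif s.kind == "ramp" and s.t0 <= t < s.t1:
                frac = (t - s.t0) / (s.t1 - s.t0) if s.t1 > s.t0 else 1.0
                tot += s.i0 + frac * (s.i1 - s.i0)
            elif s.kind == "impulse" and s.width > 0 and s.t0 <= t < s.t0 + s.width:
                tot += s.q / s.width
        return tot

    def clamp_voltage(self, t: float) -> float | None:
        for s in self.segments:
            if s.kind == "clamp" and s.t0 <= t < s.t1:
                return s.v_c
        return None

    def impulses_in(self, t0: float, t1: float) -> list[Segment]:
        return [
            s
            for s in self.segments
            if s.kind == "impulse" and s.width == 0 and t0 <= s.t0 < t1
        ]

    @property
    def end_time(self) -> float:
        """Time after which the system is autonomous (0 if no segments)."""
        t = 0.0
        for s in self.segments:
            if s.kind == "impulse":
                t = max(t, s.t0 + s.width)
            elif math.isfinite(s.t1):
                t = max(t, s.t1)
        return t


@dataclass
class Trajectory:
    """Sampled time series of state and applied stimulus."""

    times: np.ndarray  # (n,)
    states: np.ndarray  # (n, dim)
    stimulus: np.ndarray  # (n,)
    events: list[tuple[float, str]]
    model_name: str = ""
    state_names: tuple[str, ...] = ()
    free_from: float = 0.0  # start of the post-stimulus free-evolution window

    @property
    def v(self) -> np.ndarray:
        return self.states[:, 0]

    def to_dataframe(self):
        import pandas as pd

        names = self.state_names or tuple(f"x{i}" for i in range(self.states.shape[1]))
        data = {"t": self.times}
        for i, nm in enumerate(names):
            data[nm] = self.states[:, i]
        data["i_e"] = self.stimulus
        flags = np.array([""] * len(self.times), dtype=object)
        for t_ev, kind in self.events:
            idx = int(np.argmin(np.abs(self.times - t_ev)))
            flags[idx] = (flags[idx] + "+" + kind).lstrip("+")
        data["event"] = flags
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# core steppers
# ---------------------------------------------------------------------------


def _rk4_step(f: Callable, y: np.ndarray, t: float, dt: float) -> np.ndarray:
    k1 = f(t, y)
    k2 = f(t + dt / 2.0, y + dt / 2.0 * k1)
    k3 = f(t + dt / 2.0, y + dt / 2.0 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(
    model: NeuronModel,
    state0,
    protocol: StimulusProtocol | None = None,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
    peak_cap: float = math.inf,
) -> Trajectory:
    """Integrate one trajectory with full state recording.

    Fixed-step classic RK4.  During clamp segments the voltage coordinate
    is pinned to the clamp voltage while the other coordinates evolve;
    impulses are applied as instantaneous jumps between steps; the QIF
    reset fires at the first step where ``v >= v_peak`` (the overshooting
    step is accepted, the recorded peak is ``min(v, peak_cap)``).
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    protocol = protocol or StimulusProtocol.none()
    protocol.validate()
    y = np.asarray(state0, dtype=float).copy()
    if y.shape != (model.dim,):
        raise ConfigError(
            f"state0 shape {y.shape} does not match model dimension {model.dim}"
        )
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite initial state")

    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    states = np.empty((n + 1, model.dim))
    stim = np.empty(n + 1)
    events: list[tuple[float, str]] = []
    is_qif = isinstance(model, QIFModel)

    clamp_ends = sorted({s.t1 for s in protocol.segments if s.kind == "clamp"})
    released = set()

    def f(t, yy):
        return model._rhs(yy, protocol.i_e(t))

    def f_clamped(t, yy):
        d = model._rhs(yy, protocol.i_e(t))
        d[..., 0] = 0.0
        return d

    for i in range(n + 1):
        t = times[i]
        for imp in protocol.impulses_in(t, t + dt):
            y[0] += imp.q / model.C
        vc = protocol.clamp_voltage(t)
        if vc is not None:
            y[0] = vc
        states[i] = y
        stim[i] = protocol.i_e(t)
        if i == n:
            break
        y = _rk4_step(f_clamped if vc is not None else f, y, t, dt)
        if vc is not None:
            y[0] = vc  # released voltage continues from the clamp value
            for te in clamp_ends:
                if t < te <= t + dt and te not in released:
                    released.add(te)
                    events.append((te, "clamp_release"))
        if is_qif and y[0] >= model.v_peak:
            y[0] = min(y[0], peak_cap)
            events.append((t + dt, "spike_peak"))
            y[0] = model.v_reset
            events.append((t + dt, "reset"))
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"{model.name}: non-finite state at t={t + dt:.6g}"
            )

    return Trajectory(
        times=times,
        states=states,
        stimulus=stim,
        events=sorted(events),
        model_name=model.name,
        state_names=model.state_names,
        # post-stimulus window; for drives that outlast the trajectory
        # (ongoing DC) the whole trace is the evaluation window
        free_from=protocol.end_time if protocol.end_time < t_end else 0.0,
    )


def evolve_batch(
    model: NeuronModel,
    states0: np.ndarray,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
    i_e=0.0,
    i_e_fn: Callable[[float], object] | None = None,
    track_from: float = 0.0,
    check_every: int = 50,
    on_nonfinite: str = "raise",
):
    """Evolve many initial conditions at once (no state recording).

    Parameters
    ----------
    states0 : (N, dim) array of initial states.
    i_e : scalar or (N,) per-trajectory constant drive.
    i_e_fn : optional callable t -> scalar or (N,) drive, overriding i_e.
    track_from : running maximum of v is tracked only for t >= track_from.

    Returns
    -------
    dict with ``final`` (N, dim), ``v_max`` (N,), ``t_of_max`` (N,) and
    ``fired`` (N,) — for QIF, whether a reset occurred in the tracking
    window; otherwise ``v_max >= model.v_ap``.
    """
    y = np.array(states0, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    N = y.shape[0]
    n = int(round(t_end / dt))
    drive = (lambda t: i_e) if i_e_fn is None else i_e_fn
    is_qif = isinstance(model, QIFModel)

    v_max = np.full(N, -np.inf)
    t_of_max = np.zeros(N)
    fired = np.zeros(N, dtype=bool)

    def f(t, yy):
        return model._rhs(yy, drive(t))

    t = 0.0
    if track_from <= 0.0:
        v_max[:] = y[:, 0]
    for i in range(n):
        y = _rk4_step(f, y, t, dt)
        t = (i + 1) * dt
        if is_qif:
            over = y[:, 0] >= model.v_peak
            if np.any(over):
                if t >= track_from:
                    fired |= over
                    upd = over & (y[:, 0] > v_max)
                    v_max[upd] = y[upd, 0]
                    t_of_max[upd] = t
                y[over, 0] = model.v_reset
        if t >= track_from:
            upd = y[:, 0] > v_max
            v_max[upd] = y[upd, 0]
            t_of_max[upd] = t
        if i % check_every == 0 and not np.all(np.isfinite(y[:, 0])):
            bad = ~np.isfinite(y[:, 0])
            if on_nonfinite == "nan":
                # flag and park the failed rows; the batch continues
                v_max[bad] = np.nan
                y[bad] = 0.0
            else:
                raise IntegrationError(
                    f"{model.name}: non-finite state at t={t:.6g} in rows "
                    f"{np.where(bad)[0][:5]}"
                )
    if not is_qif:
        with np.errstate(invalid="ignore"):
            fired = v_max >= model.v_ap
    return {"final": y, "v_max": v_max, "t_of_max": t_of_max, "fired": fired}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_ap(traj: Trajectory, model: NeuronModel):
    """(is_ap, v_max, t_of_max) over the post-stimulus free-evolution window.

    The AP criterion is model specific: HH fires if V_max >= 0 mV, the
    piecewise-linear models if v_max reaches the right breakpoint of f(v),
    the FHN family if v_max >= 1, and QIF iff a reset event occurred.
    """
    mask = traj.times >= traj.free_from
    if not np.any(mask):
        raise SepxError("trajectory has no free-evolution window")
    v = traj.states[mask, 0]
    i = int(np.argmax(v))
    v_max = float(v[i])
    t_of_max = float(traj.times[mask][i])
    if isinstance(model, QIFModel):
        is_ap = any(k == "reset" and t >= traj.free_from for t, k in traj.events)
    else:
        is_ap = v_max >= model.v_ap
    return is_ap, v_max, t_of_max


def classify_states(
    model: NeuronModel,
    states,
    i_e=0.0,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
    on_nonfinite: str = "raise",
):
    """Batched free-evolution AP classification of initial states.

    Returns (fired, v_max, t_of_max) arrays of length N.
    """
    out = evolve_batch(
        model,
        np.atleast_2d(np.asarray(states, float)),
        t_end,
        dt,
        i_e=i_e,
        on_nonfinite=on_nonfinite,
    )
    return out["fired"], out["v_max"], out["t_of_max"]


# ---------------------------------------------------------------------------
# resting state
# ---------------------------------------------------------------------------

_REST_CACHE: dict[tuple, np.ndarray] = {}


def rest_state(
    model: NeuronModel,
    i_e: float = 0.0,
    t_settle: float = 200.0,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Settled resting state: integrate from the model's deterministic
    starting guess for ``t_settle`` time units with constant drive."""
    key = (model.name, tuple(sorted(model.params().items())), i_e, t_settle, dt)
    if key not in _REST_CACHE:
        out = evolve_batch(model, model.rest_guess()[None, :], t_settle, dt, i_e=i_e)
        _REST_CACHE[key] = out["final"][0]
    return _REST_CACHE[key].copy()


# ---------------------------------------------------------------------------
# closed-form linear-region solution (accuracy oracle for RK4)
# ---------------------------------------------------------------------------


def linear_region_solution(model, state0, region: str, t: float, i_e: float = 0.0):
    """Exact solution of one linear region's affine ODE after time t.

    Valid while the trajectory stays inside ``region``.  Uses the matrix
    exponential of the augmented affine system, which also covers defective
    (repeated-eigenvalue) Jacobians without special-casing.
    """
    from scipy.linalg import expm

    A, c = model.region_affine(region, i_e)
    n = A.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = c
    aug = np.concatenate([np.asarray(state0, dtype=float), [1.0]])
    return (expm(M * t) @ aug)[:n]


# ---------------------------------------------------------------------------
# demonstration: aborting an already-initiated QIF spike
# ---------------------------------------------------------------------------


def abort_by_hyperpolarization_demo(
    model: QIFModel,
    t_cross: float,
    I_hyp: float,
    dur: float,
    v0: float | None = None,
    t_end: float = 40.0,
    dt: float = 1e-3,
) -> bool:
    """Does the spike still happen when hyperpolarized after crossing?

    The baseline trajectory starts just above threshold (``v0``, default
    v_t + 1) and fires.  A hyperpolarizing step of amplitude ``-|I_hyp|``
    and duration ``dur`` is injected starting at ``t_cross``; the return
    value says whether a spike (reset) still occurs.  Because the step
    only ever pushes dv/dt down, the outcome is monotone: non-increasing
    in both |I_hyp| and dur.
    """
    if v0 is None:
        v0 = model.v_t + 1.0
    protocol = StimulusProtocol.step(-abs(I_hyp), t_cross, t_cross + dur)
    traj = integrate(model, [v0], protocol, t_end=t_end, dt=dt)
    return any(kind == "reset" for _, kind in traj.events)
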