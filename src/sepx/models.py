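"""Model zoo: excitable-neuron models with explicit dynamical structure.

Every model exposes a deterministic right-hand side ``d(state)/dt =
rhs(state, i_e)``, an analytic Jacobian, and — for models whose recovery /
gating variables follow the adaptation form ``dx/dt = (x_inf(v) - x) /
tau_x(v)`` — the asymptote ``gating_inf`` and time constant ``gating_tau``
used by voltage-clamp analysis.

The zoo covers:

* ``qif`` — quadratic integrate-and-fire, ``dv/dt = (v - v_r)(v - v_t) + i_e``
  with a hard reset at ``v_peak``; its firing threshold is a single point.
* ``fhn`` / ``boltzmann-fhn`` / ``fhn3d`` — FitzHugh–Nagumo cubic models
  (classic type II, a Boltzmann-nullcline type I variant, and a
  three-dimensional extension with a second slow recovery current).
* ``pwl2d`` / ``pwl3d`` — piecewise-linear caricatures whose separatrix is
  exactly computable (a line, resp. a plane, in the middle linear region).
* ``hh`` — the classic Hodgkin–Huxley squid-axon model (modern voltage
  convention, rest near -65 mV).

All dimensionless models use membrane capacitance C = 1.  Parameter sets are
the built-in fixtures returned by :func:`get_model` and can be overridden
field-by-field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np

from .exceptions import (
    DimensionMismatchError,
    FixtureValidationError,
    NoEquilibriumError,
    NonFiniteStateError,
    RegionAmbiguityError,
)

__all__ = [
    "NeuronModel",
    "PiecewiseLinearV",
    "Equilibrium",
    "QIFModel",
    "FHNModel",
    "BoltzmannFHNModel",
    "FHN3DModel",
    "PWL2DModel",
    "PWL3DModel",
    "HHModel",
    "piecewise_f",
    "piecewise_region",
    "hh_rates",
    "eval_rhs",
    "jacobian",
    "jacobian_fd",
    "find_equilibria",
    "classify_eigenvalues",
    "get_model",
    "MODEL_NAMES",
]


# ---------------------------------------------------------------------------
# piecewise-linear voltage nullcline
# ---------------------------------------------------------------------------

#: region labels in voltage order
REGIONS = ("left", "middle", "right")


@dataclass(frozen=True)
class PiecewiseLinearV:
    """Three-segment piecewise-linear function f(v) = k_s * v + b_s.

    Segment selection uses half-open intervals: left for ``v < v_l``,
    middle for ``v_l <= v < v_r``, right for ``v >= v_r``.  Continuity at
    the breakpoints is *not* required: the discontinuous v-nullcline is a
    deliberate feature of the model family.
    """

    k_l: float = -0.5
    k_m: float = 0.5
    k_r: float = -0.25
    b_l: float = 0.0
    b_m: float = -1.5
    b_r: float = 17.25
    v_l: float = 1.5
    v_r: float = 25.0

    def segment_of(self, v):
        """Return integer segment index (0=left, 1=middle, 2=right)."""
        v = np.asarray(v)
        return np.where(v < self.v_l, 0, np.where(v < self.v_r, 1, 2))

    def slope_intercept(self, region: str) -> tuple[float, float]:
        i = REGIONS.index(region)
        return ((self.k_l, self.k_m, self.k_r)[i], (self.b_l, self.b_m, self.b_r)[i])

    def region_interval(self, region: str) -> tuple[float, float]:
        return {
            "left": (-np.inf, self.v_l),
            "middle": (self.v_l, self.v_r),
            "right": (self.v_r, np.inf),
        }[region]

    def __call__(self, v):
        return piecewise_f(self, v)


def piecewise_f(plv: PiecewiseLinearV, v):
    """Evaluate the piecewise-linear nullcline function at voltage(s) v."""
    v = np.asarray(v, dtype=float)
    left = plv.k_l * v + plv.b_l
    mid = plv.k_m * v + plv.b_m
    right = plv.k_r * v + plv.b_r
    out = np.where(v < plv.v_l, left, np.where(v < plv.v_r, mid, right))
    return out if out.ndim else float(out)


def piecewise_region(plv: PiecewiseLinearV, v: float) -> str:
    """Name of the region containing voltage v (half-open convention)."""
    return REGIONS[int(plv.segment_of(v))]


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------


@dataclass
class Equilibrium:
    """A fixed point of one model (or of one linear segment of it).

    ``reality`` is ``"virtual"`` when the fixed point of a linear segment
    lies outside the voltage region on which that segment defines the flow;
    virtual saddles still organise the flow inside their neighbouring
    region, which is exactly how the piecewise-linear separatrix arises.
    """

    state: np.ndarray
    region: str | None
    reality: str  # "real" | "virtual"
    stability: str  # e.g. "stable spiral", "saddle", "unstable node"
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns

    @property
    def v(self) -> float:
        return float(self.state[0])

    @property
    def is_saddle(self) -> bool:
        return "saddle" in self.stability


def classify_eigenvalues(eigvals: np.ndarray) -> str:
    """Human-readable stability class from a Jacobian spectrum."""
    ev = np.asarray(eigvals)
    re = ev.real
    if ev.size == 1:
        return "stable point" if re[0] < 0 else "unstable point"
    complex_pair = np.any(np.abs(ev.imag) > 1e-12)
    if complex_pair:
        shape = "spiral"
        if np.all(re < 0):
            return "stable spiral"
        if np.all(re > 0):
            return "unstable spiral"
        return "saddle focus"
    # all-real spectrum
    if np.all(re < 0):
        return "stable node"
    if np.all(re > 0):
        return "unstable node"
    return "saddle"


# ---------------------------------------------------------------------------
# base class
# ---------------------------------------------------------------------------


class NeuronModel:
    """Base class: a named deterministic dynamical system.

    Subclasses define ``_rhs`` (vectorised over leading axes: state has
    shape ``(..., dim)`` and the return value matches), ``jacobian`` and,
    where the model has adaptation-form recovery/gating variables,
    ``gating_inf`` / ``gating_tau``.
    """

    name: str = "abstract"
    state_names: tuple[str, ...] = ()
    C: float = 1.0
    #: AP criterion: v_max >= this value counts as an action potential
    #: (None for QIF, which fires iff a reset occurred).
    v_ap: float | None = None
    has_reset: bool = False
    default_drive: float = 0.0

    @property
    def dim(self) -> int:
        return len(self.state_names)

    @property
    def n_gating(self) -> int:
        return self.dim - 1

    # -- right-hand side -----------------------------------------------
    def _rhs(self, state: np.ndarray, i_e) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def rhs(self, state, i_e=0.0) -> np.ndarray:
        """Validated time derivative d(state)/dt at (state, i_e)."""
        state = np.asarray(state, dtype=float)
        if state.shape[-1:] != (self.dim,):
            raise DimensionMismatchError(
                f"{self.name}: state has shape {state.shape}, expected "
                f"trailing dimension {self.dim} ({', '.join(self.state_names)})"
            )
        if not np.all(np.isfinite(state)):
            raise NonFiniteStateError(f"{self.name}: non-finite state {state!r}")
        return self._rhs(state, i_e)

    # -- adaptation form -----------------------------------------------
    def gating_inf(self, v):  # pragma: no cover
        raise NotImplementedError(f"{self.name} has no gating variables")

    def gating_tau(self, v):  # pragma: no cover
        raise NotImplementedError(f"{self.name} has no gating variables")

    # -- structure ------------------------------------------------------
    def jacobian(self, state, i_e=0.0, region: str | None = None) -> np.ndarray:
        raise NotImplementedError

    def rest_guess(self) -> np.ndarray:
        """Deterministic starting point for settling to rest."""
        return np.zeros(self.dim)

    def params(self) -> dict[str, float]:
        """Flat mapping of all model parameters (round-trippable)."""
        out = {}
        for f in fields(self):  # type: ignore[arg-type]
            val = getattr(self, f.name)
            if isinstance(val, PiecewiseLinearV):
                out.update({k.name: getattr(val, k.name) for k in fields(val)})
            else:
                out[f.name] = val
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} {self.name} dim={self.dim}>"


def eval_rhs(model: NeuronModel, state, i_e=0.0) -> np.ndarray:
    """Functional form of :meth:`NeuronModel.rhs` (validates input)."""
    return model.rhs(state, i_e)


# ---------------------------------------------------------------------------
# QIF
# ---------------------------------------------------------------------------


@dataclass
class QIFModel(NeuronModel):
    """Quadratic integrate-and-fire: dv/dt = (v - v_r)(v - v_t) + i_e.

    With no drive the stable root v_r is the resting potential and the
    unstable root v_t is the threshold; the two roots merge in a
    saddle-node at the rheobase current (v_t - v_r)^2 / 4.  A spike is a
    runaway past ``v_peak`` followed by a hard reset to ``v_reset``.
    """

    v_r: float = 0.0
    v_t: float = 30.0
    v_peak: float = 40.0
    v_reset: float = -5.0

    name = "qif"
    state_names = ("v",)
    has_reset = True
    v_ap = None

    def __post_init__(self):
        if not (self.v_peak > self.v_t > self.v_r > self.v_reset):
            raise FixtureValidationError(
                "QIF requires v_peak > v_t > v_r > v_reset, got "
                f"{self.v_peak}, {self.v_t}, {self.v_r}, {self.v_reset}"
            )

    def _rhs(self, state, i_e):
        v = state[..., 0]
        dv = (v - self.v_r) * (v - self.v_t) + i_e
        return np.stack([dv], axis=-1)

    def jacobian(self, state, i_e=0.0, region=None):
        v = float(np.asarray(state)[..., 0])
        return np.array([[2.0 * v - self.v_r - self.v_t]])

    def rest_guess(self):
        return np.array([self.v_r])


# ---------------------------------------------------------------------------
# FHN family
# ---------------------------------------------------------------------------


@dataclass
class FHNModel(NeuronModel):
    """Classic FitzHugh–Nagumo (type II excitability, quasi-threshold).

    dv/dt = v - v^3/3 - w + i_e
    dw/dt = (k_w v + b_w - w) / tau_w

    so the w-nullcline is the line w = k_w v + b_w and the recovery
    variable follows the adaptation form with w_inf(v) = k_w v + b_w.
    """

    tau_w: float = 15.0
    k_w: float = 1.25
    b_w: float = 0.875

    name = "fhn"
    state_names = ("v", "w")
    v_ap = 1.0

    def w_inf(self, v):
        return self.k_w * np.asarray(v, dtype=float) + self.b_w

    def _rhs(self, state, i_e):
        v, w = state[..., 0], state[..., 1]
        dv = v - v**3 / 3.0 - w + i_e
        dw = (self.w_inf(v) - w) / self.tau_w
        return np.stack([dv, dw], axis=-1)

    def gating_inf(self, v):
        return np.stack([self.w_inf(v)], axis=-1)

    def gating_tau(self, v):
        v = np.asarray(v, dtype=float)
        return np.broadcast_to(np.array([self.tau_w]), v.shape + (1,)).copy()

    def jacobian(self, state, i_e=0.0, region=None):
        v = float(np.asarray(state)[..., 0])
        return np.array(
            [[1.0 - v * v, -1.0], [self.k_w / self.tau_w, -1.0 / self.tau_w]]
        )

    def _dwinf_dv(self, v):
        return self.k_w

    def rest_guess(self):
        return np.array([-1.2, self.w_inf(-1.2)])


@dataclass
class BoltzmannFHNModel(FHNModel):
    """FHN variant whose w-nullcline is a Boltzmann sigmoid.

    w_inf(v) = a / (1 + exp((b - v) / c)).  The half-activation b sits on
    the middle (unstable) branch of the cubic v-nullcline so that, at the
    default drive i_e = 0.62, the phase portrait has exactly three
    equilibria — stable node < saddle < unstable node — a type I neuron
    whose firing threshold is the saddle's stable manifold.  This portrait
    is asserted at construction time (see ``get_model``).
    """

    tau_w: float = 8.0
    a: float = 2.0
    b: float = 0.3
    c: float = 0.27

    name = "boltzmann-fhn"
    default_drive = 0.62

    def w_inf(self, v):
        v = np.asarray(v, dtype=float)
        return self.a / (1.0 + np.exp(np.clip((self.b - v) / self.c, -500, 500)))

    def _dwinf_dv(self, v):
        sig = self.w_inf(v) / self.a
        return self.a * sig * (1.0 - sig) / self.c

    def jacobian(self, state, i_e=0.0, region=None):
        v = float(np.asarray(state)[..., 0])
        return np.array(
            [
                [1.0 - v * v, -1.0],
                [self._dwinf_dv(v) / self.tau_w, -1.0 / self.tau_w],
            ]
        )


@dataclass
class FHN3DModel(NeuronModel):
    """Three-dimensional FHN: a second slow recovery current u.

    dv/dt = v - v^3/3 - u - w + i_e, with u and w both of adaptation form
    (u is subtracted from the voltage equation like w).
    """

    tau_u: float = 15.0
    k_u: float = 1.25
    b_u: float = 0.0
    tau_w: float = 25.0
    k_w: float = 1.25
    b_w: float = 0.0

    name = "fhn3d"
    state_names = ("v", "u", "w")
    v_ap = 1.0
    default_drive = -2.5

    def gating_inf(self, v):
        v = np.asarray(v, dtype=float)
        return np.stack([self.k_u * v + self.b_u, self.k_w * v + self.b_w], axis=-1)

    def gating_tau(self, v):
        v = np.asarray(v, dtype=float)
        return np.broadcast_to(np.array([self.tau_u, self.tau_w]), v.shape + (2,)).copy()

    def _rhs(self, state, i_e):
        v, u, w = state[..., 0], state[..., 1], state[..., 2]
        dv = v - v**3 / 3.0 - u - w + i_e
        du = (self.k_u * v + self.b_u - u) / self.tau_u
        dw = (self.k_w * v + self.b_w - w) / self.tau_w
        return np.stack([dv, du, dw], axis=-1)

    def jacobian(self, state, i_e=0.0, region=None):
        v = float(np.asarray(state)[..., 0])
        return np.array(
            [
                [1.0 - v * v, -1.0, -1.0],
                [self.k_u / self.tau_u, -1.0 / self.tau_u, 0.0],
                [self.k_w / self.tau_w, 0.0, -1.0 / self.tau_w],
            ]
        )

    def rest_guess(self):
        return np.array([-1.5, self.k_u * -1.5 + self.b_u, self.k_w * -1.5 + self.b_w])


# ---------------------------------------------------------------------------
# piecewise-linear models
# ---------------------------------------------------------------------------


@dataclass
class PWL2DModel(NeuronModel):
    """2D piecewise-linear model with an exactly computable separatrix.

    C dv/dt = f(v) - w + i_e,   dw/dt = (k_w v - w) / tau_w

    where f(v) is the three-segment :class:`PiecewiseLinearV`.  In the
    middle region the (virtual) saddle's stable manifold is a straight
    line w = k_theta v + b_theta — the model's firing threshold.
    """

    f: PiecewiseLinearV = field(default_factory=PiecewiseLinearV)
    tau_w: float = 5.0
    k_w: float = 0.45
    C: float = 1.0

    name = "pwl2d"
    state_names = ("v", "w")

    @property
    def v_ap(self) -> float:  # type: ignore[override]
        # an AP excursion enters the right (recovery) segment
        return self.f.v_r

    def gating_inf(self, v):
        v = np.asarray(v, dtype=float)
        return np.stack([self.k_w * v], axis=-1)

    def gating_tau(self, v):
        v = np.asarray(v, dtype=float)
        return np.broadcast_to(np.array([self.tau_w]), v.shape + (1,)).copy()

    def _rhs(self, state, i_e):
        v, w = state[..., 0], state[..., 1]
        dv = (piecewise_f(self.f, v) - w + i_e) / self.C
        dw = (self.k_w * v - w) / self.tau_w
        return np.stack([dv, dw], axis=-1)

    def jacobian(self, state, i_e=0.0, region=None):
        v = float(np.asarray(state)[..., 0])
        region = _resolve_region(self.f, v, region)
        k_s, _ = self.f.slope_intercept(region)
        return np.array(
            [
                [k_s / self.C, -1.0 / self.C],
                [self.k_w / self.tau_w, -1.0 / self.tau_w],
            ]
        )

    def region_jacobian(self, region: str) -> np.ndarray:
        k_s, _ = self.f.slope_intercept(region)
        return np.array(
            [
                [k_s / self.C, -1.0 / self.C],
                [self.k_w / self.tau_w, -1.0 / self.tau_w],
            ]
        )

    def region_affine(self, region: str, i_e: float = 0.0):
        """(A, c) such that d(state)/dt = A state + c inside the region."""
        k_s, b_s = self.f.slope_intercept(region)
        A = self.region_jacobian(region)
        c = np.array([(b_s + i_e) / self.C, 0.0])
        return A, c


def _pwl3d_default_f() -> PiecewiseLinearV:
    return PiecewiseLinearV(k_m=0.95, b_m=-2.175, b_r=57.825, v_r=50.0)


@dataclass
class PWL3DModel(NeuronModel):
    """3D piecewise-linear model; the middle-region threshold is a plane.

    C dv/dt = f(v) - u - w + i_e,  du/dt = (k_u v - u)/tau_u,
    dw/dt = (k_w v - w)/tau_w.  Both recovery currents are subtracted from
    the voltage equation.  The middle-segment Jacobian has three real
    eigenvalues with exactly one dominant positive one; the plane spanned
    by the other two eigenvectors is the threshold (separatrix) plane.
    """

    f: PiecewiseLinearV = field(default_factory=_pwl3d_default_f)
    tau_u: float = 5.0
    k_u: float = 0.45
    tau_w: float = 10.0
    k_w: float = 0.6
    C: float = 1.0

    name = "pwl3d"
    state_names = ("v", "u", "w")

    @property
    def v_ap(self) -> float:  # type: ignore[override]
        return self.f.v_r

    def gating_inf(self, v):
        v = np.asarray(v, dtype=float)
        return np.stack([self.k_u * v, self.k_w * v], axis=-1)

    def gating_tau(self, v):
        v = np.asarray(v, dtype=float)
        return np.broadcast_to(np.array([self.tau_u, self.tau_w]), v.shape + (2,)).copy()

    def _rhs(self, state, i_e):
        v, u, w = state[..., 0], state[..., 1], state[..., 2]
        dv = (piecewise_f(self.f, v) - u - w + i_e) / self.C
        du = (self.k_u * v - u) / self.tau_u
        dw = (self.k_w * v - w) / self.tau_w
        return np.stack([dv, du, dw], axis=-1)

    def region_jacobian(self, region: str) -> np.ndarray:
        k_s, _ = self.f.slope_intercept(region)
        return np.array(
            [
                [k_s / self.C, -1.0 / self.C, -1.0 / self.C],
                [self.k_u / self.tau_u, -1.0 / self.tau_u, 0.0],
                [self.k_w / self.tau_w, 0.0, -1.0 / self.tau_w],
            ]
        )

    def region_affine(self, region: str, i_e: float = 0.0):
        k_s, b_s = self.f.slope_intercept(region)
        A = self.region_jacobian(region)
        c = np.array([(b_s + i_e) / self.C, 0.0, 0.0])
        return A, c

    def jacobian(self, state, i_e=0.0, region=None):
        v = float(np.asarray(state)[..., 0])
        region = _resolve_region(self.f, v, region)
        return self.region_jacobian(region)


def _resolve_region(plv: PiecewiseLinearV, v: float, region: str | None) -> str:
    if region is not None:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return region
    if v == plv.v_l or v == plv.v_r:
        raise RegionAmbiguityError(
            f"v={v} sits exactly on a breakpoint; pass region= explicitly"
        )
    return piecewise_region(plv, v)


# ---------------------------------------------------------------------------
# Hodgkin–Huxley
# ---------------------------------------------------------------------------


def _linexp(x):
    """x / (1 - exp(-x/10)) with the removable singularity at x = 0 filled.

    This is the shape shared by the alpha_m and alpha_n rate functions; the
    limit at x -> 0 is 10 and a short series is used near the singular
    point to avoid catastrophic cancellation.
    """
    x = np.asarray(x, dtype=float)
    s = x / 10.0
    small = np.abs(s) < 1e-3
    safe = np.where(small, 1.0, s)
    exact = 10.0 * safe / (-np.expm1(-safe))
    series = 10.0 * (1.0 + s / 2.0 + s * s / 12.0)
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)


def _dlinexp(x):
    """Derivative of :func:`_linexp` with respect to x."""
    x = np.asarray(x, dtype=float)
    s = x / 10.0
    small = np.abs(s) < 1e-3
    safe = np.where(small, 1.0, s)
    em = -np.expm1(-safe)  # 1 - e^-s
    exact = (em - safe * np.exp(-safe)) / (em * em)
    series = 0.5 + s / 6.0
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)


def hh_rates(V):
    """Hodgkin–Huxley rate functions at membrane potential V (mV).

    Returns a dict with arrays ``alpha``, ``beta``, ``x_inf``, ``tau_x``,
    each with trailing axis ordered (m, h, n).  The removable singularities
    of alpha_m (V = -40) and alpha_n (V = -55) are filled by their limits,
    so every returned quantity is smooth on the physiological range.
    """
    V = np.asarray(V, dtype=float)
    a_m = 0.1 * _linexp(V + 40.0)
    b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    a_n = 0.01 * _linexp(V + 55.0)
    b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    alpha = np.stack([a_m, a_h, a_n], axis=-1)
    beta = np.stack([b_m, b_h, b_n], axis=-1)
    tot = alpha + beta
    return {
        "alpha": alpha,
        "beta": beta,
        "x_inf": alpha / tot,
        "tau_x": 1.0 / tot,
    }


def _hh_rate_derivs(V):
    """d(alpha)/dV and d(beta)/dV, trailing axis (m, h, n)."""
    V = np.asarray(V, dtype=float)
    da_m = 0.1 * _dlinexp(V + 40.0)
    db_m = -(4.0 * np.exp(-(V + 65.0) / 18.0)) / 18.0
    da_h = -(0.07 * np.exp(-(V + 65.0) / 20.0)) / 20.0
    sig = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    db_h = sig * (1.0 - sig) / 10.0
    da_n = 0.01 * _dlinexp(V + 55.0)
    db_n = -(0.125 * np.exp(-(V + 65.0) / 80.0)) / 80.0
    return (
        np.stack([da_m, da_h, da_n], axis=-1),
        np.stack([db_m, db_h, db_n], axis=-1),
    )


@dataclass
class HHModel(NeuronModel):
    """Classic Hodgkin–Huxley model, modern voltage convention.

    State (V, m, h, n); V in mV, time in ms.  Reversal potentials
    E_Na = 50, E_K = -77, E_L = -54.4 mV; standard 1952 conductances
    gbar_Na = 120, gbar_K = 36, gbar_L = 0.3 mS/cm^2 and C_m = 1 uF/cm^2.
    """

    C: float = 1.0  # uF/cm^2
    gbar_Na: float = 120.0
    gbar_K: float = 36.0
    gbar_L: float = 0.3
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -54.4

    name = "hh"
    state_names = ("V", "m", "h", "n")
    v_ap = 0.0  # mV

    def __post_init__(self):
        if min(self.gbar_Na, self.gbar_K, self.gbar_L) <= 0:
            raise FixtureValidationError("HH conductances must be positive")

    def ionic_current(self, V, m, h, n):
        return (
            self.gbar_Na * m**3 * h * (V - self.E_Na)
            + self.gbar_K * n**4 * (V - self.E_K)
            + self.gbar_L * (V - self.E_L)
        )

    def _rhs(self, state, i_e):
        V = state[..., 0]
        m, h, n = state[..., 1], state[..., 2], state[..., 3]
        r = hh_rates(V)
        x = state[..., 1:]
        dx = (r["x_inf"] - x) / r["tau_x"]
        dV = (i_e - self.ionic_current(V, m, h, n)) / self.C
        return np.concatenate([dV[..., None], dx], axis=-1)

    def gating_inf(self, v):
        return hh_rates(v)["x_inf"]

    def gating_tau(self, v):
        return hh_rates(v)["tau_x"]

    def jacobian(self, state, i_e=0.0, region=None):
        V, m, h, n = (float(s) for s in np.asarray(state, dtype=float))
        r = hh_rates(V)
        da, db = _hh_rate_derivs(V)
        J = np.zeros((4, 4))
        J[0, 0] = -(self.gbar_Na * m**3 * h + self.gbar_K * n**4 + self.gbar_L) / self.C
        J[0, 1] = -3.0 * self.gbar_Na * m**2 * h * (V - self.E_Na) / self.C
        J[0, 2] = -self.gbar_Na * m**3 * (V - self.E_Na) / self.C
        J[0, 3] = -4.0 * self.gbar_K * n**3 * (V - self.E_K) / self.C
        x = np.array([m, h, n])
        # dx/dt = alpha (1 - x) - beta x
        J[1:, 0] = da * (1.0 - x) - db * x
        for i in range(3):
            J[1 + i, 1 + i] = -(r["alpha"][i] + r["beta"][i])
        return J

    def rest_guess(self):
        V0 = -65.0
        return np.concatenate([[V0], hh_rates(V0)["x_inf"]])


# ---------------------------------------------------------------------------
# Jacobians: finite-difference fallback
# ---------------------------------------------------------------------------


def jacobian(model: NeuronModel, state, i_e=0.0, region: str | None = None):
    """Analytic Jacobian of the model RHS at (state, i_e)."""
    return model.jacobian(state, i_e=i_e, region=region)


def jacobian_fd(model: NeuronModel, state, i_e=0.0, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian; cross-check for the analytic forms."""
    state = np.asarray(state, dtype=float)
    n = model.dim
    J = np.zeros((n, n))
    for j in range(n):
        dp = state.copy()
        dm = state.copy()
        dp[j] += h
        dm[j] -= h
        J[:, j] = (model.rhs(dp, i_e) - model.rhs(dm, i_e)) / (2.0 * h)
    return J


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------


def _eig_sorted(A: np.ndarray):
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(vals.real)
    return vals[order], vecs[:, order]


def _make_equilibrium(state, region, reality, A) -> Equilibrium:
    vals, vecs = _eig_sorted(A)
    return Equilibrium(
        state=np.asarray(state, dtype=float),
        region=region,
        reality=reality,
        stability=classify_eigenvalues(vals),
        eigenvalues=vals,
        eigenvectors=vecs,
    )


def _pwl_equilibria(model, i_e: float) -> list[Equilibrium]:
    eqs = []
    for region in REGIONS:
        A, c = model.region_affine(region, i_e)
        # fixed point: A x + c = 0
        try:
            x = np.linalg.solve(A, -c)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate params
            continue
        lo, hi = model.f.region_interval(region)
        reality = "real" if lo <= x[0] < hi else "virtual"
        eqs.append(_make_equilibrium(x, region, reality, A))
    return eqs


def _scan_roots(g: Callable[[float], float], grid: np.ndarray) -> list[float]:
    """Sign-change scan + Brent refinement on a deterministic grid."""
    from scipy.optimize import brentq

    vals = np.array([g(v) for v in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(g, grid[i], grid[i + 1], xtol=1e-12)))
    # dedupe
    out: list[float] = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-8:
            out.append(r)
    return out


def find_equilibria(model: NeuronModel, i_e: float = 0.0) -> list[Equilibrium]:
    """All equilibria of the model at constant drive i_e.

    Piecewise-linear models are solved segment-by-segment exactly (fixed
    points flagged real/virtual by region membership); smooth models are
    located by a deterministic sign-change scan of the voltage equation
    with gating at its asymptote, refined by Brent's method.  Each
    equilibrium carries the eigen-decomposition of its Jacobian.
    """
    if isinstance(model, QIFModel):
        disc = (model.v_t + model.v_r) ** 2 - 4.0 * (model.v_r * model.v_t + i_e)
        if disc < 0:
            raise NoEquilibriumError(
                f"QIF at i_e={i_e}: no equilibrium (beyond rheobase; "
                f"search window is the real line, discriminant {disc:.6g} < 0)"
            )
        s = model.v_t + model.v_r
        eqs = []
        for v in ((s - math.sqrt(disc)) / 2.0, (s + math.sqrt(disc)) / 2.0):
            A = model.jacobian([v], i_e)
            eqs.append(_make_equilibrium([v], None, "real", A))
        return eqs

    if isinstance(model, (PWL2DModel, PWL3DModel)):
        return _pwl_equilibria(model, i_e)

    if isinstance(model, (FHN3DModel,)):
        lo, hi = -6.0, 6.0

        def g(v):
            u = model.k_u * v + model.b_u
            w = model.k_w * v + model.b_w
            return v - v**3 / 3.0 - u - w + i_e

        roots = _scan_roots(g, np.linspace(lo, hi, 1201))
        if not roots:
            raise NoEquilibriumError(f"{model.name}: no equilibrium in [{lo}, {hi}]")
        eqs = []
        for v in roots:
            st = np.array([v, model.k_u * v + model.b_u, model.k_w * v + model.b_w])
            eqs.append(_make_equilibrium(st, None, "real", model.jacobian(st, i_e)))
        return eqs

    if isinstance(model, FHNModel):  # covers BoltzmannFHNModel
        lo, hi = -6.0, 6.0

        def g(v):
            return v - v**3 / 3.0 - model.w_inf(v) + i_e

        roots = _scan_roots(g, np.linspace(lo, hi, 2401))
        if not roots:
            raise NoEquilibriumError(f"{model.name}: no equilibrium in [{lo}, {hi}]")
        eqs = []
        for v in roots:
            st = np.array([v, float(model.w_inf(v))])
            eqs.append(_make_equilibrium(st, None, "real", model.jacobian(st, i_e)))
        return eqs

    if isinstance(model, HHModel):
        lo, hi = -100.0, 60.0

        def g(V):
            xinf = hh_rates(V)["x_inf"]
            return float(i_e - model.ionic_current(V, xinf[0], xinf[1], xinf[2]))

        roots = _scan_roots(g, np.linspace(lo, hi, 1601))
        if not roots:
            raise NoEquilibriumError(f"hh: no equilibrium in [{lo}, {hi}] mV")
        eqs = []
        for V in roots:
            st = np.concatenate([[V], hh_rates(V)["x_inf"]])
            eqs.append(_make_equilibrium(st, None, "real", model.jacobian(st, i_e)))
        return eqs

    raise NotImplementedError(f"find_equilibria: unsupported model {model.name}")


def resting_equilibrium(model: NeuronModel, i_e: float = 0.0) -> Equilibrium:
    """The stable equilibrium with the lowest voltage (the resting state)."""
    stable = [e for e in find_equilibria(model, i_e) if e.stability.startswith("stable") and e.reality == "real"]
    if not stable:
        raise NoEquilibriumError(f"{model.name}: no real stable equilibrium at i_e={i_e}")
    return min(stable, key=lambda e: e.v)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

_FACTORIES: dict[str, Callable[..., NeuronModel]] = {
    "qif": QIFModel,
    "fhn": FHNModel,
    "boltzmann-fhn": BoltzmannFHNModel,
    "fhn3d": FHN3DModel,
    "pwl2d": PWL2DModel,
    "pwl3d": PWL3DModel,
    "hh": HHModel,
}

MODEL_NAMES = tuple(_FACTORIES)

_PLV_FIELDS = {f.name for f in fields(PiecewiseLinearV)}


def get_model(name: str, **overrides) -> NeuronModel:
    """Instantiate a named fixture model, optionally overriding parameters.

    Piecewise-linear breakpoint/slope overrides (``k_m``, ``b_r``, ...) are
    routed into the nested :class:`PiecewiseLinearV`.  Unknown names and
    unknown parameters raise :class:`~sepx.exceptions.ConfigError`-style
    ``ValueError``.  The ``boltzmann-fhn`` fixture is validated on
    construction: it must produce the three-equilibrium type I portrait
    (stable point < saddle < unstable node) at its default drive.
    """
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None
    cls_fields = {f.name for f in fields(factory)}  # type: ignore[arg-type]
    plain = {}
    plv = {}
    for k, v in overrides.items():
        if k in cls_fields:
            plain[k] = v
        elif "f" in cls_fields and k in _PLV_FIELDS:
            plv[k] = v
        else:
            raise ValueError(f"model {name!r} has no parameter {k!r}")
    model = factory(**plain)
    if plv:
        model = replace(model, f=replace(model.f, **plv))  # type: ignore[arg-type]
    if name == "boltzmann-fhn":
        _validate_boltzmann_fhn(model)
    return model


def _validate_boltzmann_fhn(model: BoltzmannFHNModel) -> None:
    eqs = sorted(find_equilibria(model, model.default_drive), key=lambda e: e.v)
    kinds = [e.stability for e in eqs]
    ok = (
        len(eqs) == 3
        and kinds[0].startswith("stable")
        and eqs[1].is_saddle
        and kinds[2] in ("unstable node", "unstable spiral")
    )
    if not ok:
        raise FixtureValidationError(
            "boltzmann-fhn fixture must have stable point < saddle < unstable "
            f"node at i_e={model.default_drive}; found "
            + "; ".join(f"v={e.v:.4f} {e.stability}" for e in eqs)
        )
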