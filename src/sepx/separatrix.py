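"""Separatrices: the state-space boundaries that define firing thresholds.

For the models with exact structure the separatrix is analytic:

* QIF — a *point*: the unstable root of the quadratic, paired with the
  stable root (the dynamic resting potential).  Both vary with the drive
  i_e and merge at the rheobase (saddle-node) current.
* 2D piecewise-linear — a *line* ``w = k_theta v + b_theta`` in the middle
  region: the stable-manifold line of the (possibly virtual) middle-segment
  saddle.  ``k_theta = k_m / C - lambda_s`` with ``lambda_s`` the stable
  eigenvalue, and the intercept follows
  ``b_theta = (i_e + b_m)(k_w - k_theta) / (k_w - k_m)``.
* 3D piecewise-linear — a *plane* through the middle-segment equilibrium,
  spanned by the eigenvectors of the two non-dominant eigenvalues (one
  stable, one weakly unstable); the transverse dominant unstable direction
  is the fast firing direction.

For smooth models (FHN family, HH) the quasi-separatrix is sampled
numerically: either by tracing a saddle's stable manifold backward in time
or by bisecting a spike/no-spike classifier along rays in state space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .dynamics import DEFAULT_DT, DEFAULT_T_END, classify_states
from .exceptions import BracketError, NoThresholdError, SepxError
from .models import (
    Equilibrium,
    NeuronModel,
    PWL2DModel,
    PWL3DModel,
    QIFModel,
    find_equilibria,
)

__all__ = [
    "ThresholdPoint",
    "SeparatrixLine",
    "ThresholdPlane",
    "SampledBoundary",
    "qif_rheobase",
    "qif_threshold",
    "pwl2d_separatrix",
    "pwl3d_separatrix",
    "trace_manifold",
    "bisect_boundary",
    "bisect_boundary_batch",
    "make_classifier",
    "separatrix_for",
]


# ---------------------------------------------------------------------------
# analytic objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdPoint:
    """QIF separatrix: threshold theta and dynamic resting potential."""

    theta: float
    v_rest: float
    i_e: float

    def fires(self, v: float) -> bool:
        return v > self.theta


@dataclass(frozen=True)
class SeparatrixLine:
    """2D PWL separatrix line w = k_theta v + b_theta (middle region).

    The firing side is *below* the line (w smaller than the line value):
    depolarizing current raises the line and hence lowers the threshold
    voltage at fixed w.
    """

    k_theta: float
    b_theta: float
    i_e: float
    validity: tuple[float, float]  # middle-region voltage interval

    def w_of(self, v):
        return self.k_theta * np.asarray(v, dtype=float) + self.b_theta

    def theta_of(self, w):
        """Threshold voltage at recovery level w (inverts the line)."""
        return (np.asarray(w, dtype=float) - self.b_theta) / self.k_theta

    def fires(self, state) -> bool | np.ndarray:
        state = np.asarray(state, dtype=float)
        v, w = state[..., 0], state[..., 1]
        out = w < self.w_of(v)
        return bool(out) if np.ndim(out) == 0 else out

    def signed_distance(self, state):
        """Positive on the firing side (below the line)."""
        state = np.asarray(state, dtype=float)
        v, w = state[..., 0], state[..., 1]
        return (self.w_of(v) - w) / math.hypot(self.k_theta, 1.0)


@dataclass(frozen=True)
class ThresholdPlane:
    """3D PWL separatrix: a plane through the middle-segment equilibrium.

    Spanned by the eigenvectors belonging to ``spanning_eigenvalues``
    (``r_i``, ``r_j`` — the two non-dominant eigenvalues); ``firing_side``
    is the sign of ``normal . (state - point)`` that fires, fixed so that
    the dominant unstable eigenvector's positive-voltage direction fires.
    """

    normal: np.ndarray
    point: np.ndarray
    spanning_eigenvalues: tuple[float, float]
    spanning_eigenvectors: np.ndarray  # columns
    dominant_eigenvalue: float
    dominant_eigenvector: np.ndarray
    firing_side: int
    i_e: float
    validity: tuple[float, float]

    def signed_distance(self, state):
        state = np.asarray(state, dtype=float)
        return (state - self.point) @ self.normal

    def fires(self, state):
        out = self.firing_side * self.signed_distance(state) > 0
        return bool(out) if np.ndim(out) == 0 else out

    def theta_of(self, u, w):
        """Threshold voltage as a function of the recovery pair (u, w)."""
        n = self.normal
        if abs(n[0]) < 1e-14:
            raise SepxError("threshold plane is parallel to the voltage axis")
        u = np.asarray(u, dtype=float)
        w = np.asarray(w, dtype=float)
        d = n @ self.point
        return (d - n[1] * u - n[2] * w) / n[0]


@dataclass
class SampledBoundary:
    """Numerically sampled (quasi-)separatrix."""

    points: np.ndarray  # (n, dim)
    parameterization: str = "time"
    tolerance: float | None = None
    truncated: bool = False


# ---------------------------------------------------------------------------
# QIF
# ---------------------------------------------------------------------------


def qif_rheobase(model: QIFModel) -> float:
    """Saddle-node (rheobase) current: (v_t - v_r)^2 / 4."""
    return (model.v_t - model.v_r) ** 2 / 4.0


def qif_threshold(model: QIFModel, i_e: float = 0.0) -> ThresholdPoint:
    """Dynamic threshold point and resting potential of the driven QIF.

    The two real roots of ``(v - v_r)(v - v_t) + i_e = 0``; the larger is
    the threshold, the smaller the resting potential.  theta decreases and
    v_rest increases with depolarizing i_e until they merge at rheobase.
    """
    s = model.v_t + model.v_r
    disc = s * s - 4.0 * (model.v_r * model.v_t + i_e)
    if disc <= 0.0:
        raise NoThresholdError(
            f"QIF at i_e={i_e}: at or beyond rheobase "
            f"({qif_rheobase(model):.6g}); no threshold point exists"
        )
    r = math.sqrt(disc)
    return ThresholdPoint(theta=(s + r) / 2.0, v_rest=(s - r) / 2.0, i_e=i_e)


# ---------------------------------------------------------------------------
# 2D PWL line
# ---------------------------------------------------------------------------


def _middle_saddle(model, i_e: float) -> Equilibrium:
    for eq in find_equilibria(model, i_e):
        if eq.region == "middle":
            return eq
    raise SepxError("no middle-segment equilibrium found")


def pwl2d_separatrix(model: PWL2DModel, i_e: float = 0.0) -> SeparatrixLine:
    """Stable-manifold line of the middle-segment saddle.

    Raises if the middle fixed point is not a saddle (det >= 0).
    """
    A = model.region_jacobian("middle")
    if np.linalg.det(A) >= 0:
        raise SepxError(
            "middle-segment equilibrium is not a saddle "
            f"(det={np.linalg.det(A):.6g} >= 0); no separatrix line"
        )
    lam = np.linalg.eigvals(A).real
    lam_s = lam.min()  # the stable (negative) eigenvalue
    k_m = model.f.k_m
    k_theta = k_m / model.C - lam_s
    b_theta = (i_e + model.f.b_m) * (model.k_w - k_theta) / (model.k_w - k_m)
    return SeparatrixLine(
        k_theta=float(k_theta),
        b_theta=float(b_theta),
        i_e=i_e,
        validity=(model.f.v_l, model.f.v_r),
    )


# ---------------------------------------------------------------------------
# 3D PWL plane
# ---------------------------------------------------------------------------


def pwl3d_separatrix(model: PWL3DModel, i_e: float = 0.0) -> ThresholdPlane:
    """Threshold plane of the 3D piecewise-linear model.

    The middle-segment Jacobian must have three real eigenvalues with
    exactly one dominant positive one; the plane is spanned by the
    eigenvectors of the other two (the stable and the weakly unstable
    eigenvalue), anchored at the (possibly virtual) middle equilibrium.
    """
    A = model.region_jacobian("middle")
    vals, vecs = np.linalg.eig(A)
    if np.any(np.abs(vals.imag) > 1e-10):
        raise SepxError(
            f"middle-segment spectrum is not real: {np.sort_complex(vals)}"
        )
    vals = vals.real
    vecs = vecs.real
    order = np.argsort(np.abs(vals))  # two smallest |lambda| span the plane
    i_span, j_span, i_dom = order[0], order[1], order[2]
    if vals[i_dom] <= 0 or vals[i_dom] <= max(abs(vals[i_span]), abs(vals[j_span])):
        raise SepxError(
            f"no dominant positive eigenvalue: spectrum {np.sort(vals)}"
        )
    e_dom = vecs[:, i_dom]
    if e_dom[0] < 0:
        e_dom = -e_dom
    span = vecs[:, [i_span, j_span]]
    normal = np.cross(span[:, 0], span[:, 1])
    normal = normal / np.linalg.norm(normal)
    # middle-segment equilibrium (real or virtual)
    Areg, c = model.region_affine("middle", i_e)
    point = np.linalg.solve(Areg, -c)
    firing_side = int(np.sign(normal @ e_dom))
    if firing_side == 0:  # pragma: no cover - degenerate geometry
        raise SepxError("dominant eigenvector lies in the threshold plane")
    return ThresholdPlane(
        normal=normal,
        point=point,
        spanning_eigenvalues=(float(vals[i_span]), float(vals[j_span])),
        spanning_eigenvectors=span,
        dominant_eigenvalue=float(vals[i_dom]),
        dominant_eigenvector=e_dom,
        firing_side=firing_side,
        i_e=i_e,
        validity=(model.f.v_l, model.f.v_r),
    )


def separatrix_for(model: NeuronModel, i_e: float = 0.0):
    """Analytic separatrix object for models that have one."""
    if isinstance(model, QIFModel):
        return qif_threshold(model, i_e)
    if isinstance(model, PWL2DModel):
        return pwl2d_separatrix(model, i_e)
    if isinstance(model, PWL3DModel):
        return pwl3d_separatrix(model, i_e)
    raise SepxError(
        f"{model.name} has no analytic separatrix; use trace_manifold or "
        "bisect_boundary to sample the quasi-separatrix"
    )


# ---------------------------------------------------------------------------
# manifold tracing
# ---------------------------------------------------------------------------


def trace_manifold(
    model: NeuronModel,
    saddle: Equilibrium,
    which: str = "stable",
    sign: int = +1,
    horizon: float = 200.0,
    i_e: float = 0.0,
    delta: float = 1e-6,
    dt: float = DEFAULT_DT,
    bbox: tuple[float, float] = (-50.0, 60.0),
    state_bound: float = 1e4,
) -> SampledBoundary:
    """Trace a saddle manifold by integrating from an eigenvector offset.

    The stable manifold is traced *backward* in time (the unstable one
    forward), starting at ``saddle + sign * delta * e`` where ``e`` is the
    unit eigenvector of the matching real eigenvalue.  For a virtual saddle
    the seed is shifted along the eigenvector into the saddle's
    neighbouring validity region first.  Tracing stops when the voltage
    leaves ``bbox`` or any coordinate exceeds ``state_bound`` (the boundary
    is then flagged truncated).
    """
    if which not in ("stable", "unstable"):
        raise ValueError("which must be 'stable' or 'unstable'")
    vals = saddle.eigenvalues
    real = np.abs(vals.imag) < 1e-10
    want_neg = which == "stable"
    cand = [
        i
        for i in range(len(vals))
        if real[i] and ((vals[i].real < 0) == want_neg) and vals[i].real != 0
    ]
    if not cand:
        raise SepxError(
            f"saddle has no real {which} eigenvalue (spectrum {vals})"
        )
    # strongest matching direction
    idx = max(cand, key=lambda i: abs(vals[i].real))
    e = saddle.eigenvectors[:, idx].real
    e = e / np.linalg.norm(e)
    seed = saddle.state + sign * delta * e

    # virtual saddle: push the seed along the eigenvector into the region
    if saddle.reality == "virtual" and hasattr(model, "f"):
        lo, hi = model.f.region_interval(saddle.region)
        margin = 1e-9 * max(1.0, abs(saddle.v))
        if not (lo <= seed[0] < hi):
            for target in (
                min(hi - margin, saddle.v) if math.isfinite(hi) else None,
                max(lo + margin, saddle.v) if math.isfinite(lo) else None,
            ):
                if target is None:
                    continue
                s = (target - saddle.state[0]) / e[0] if e[0] != 0 else None
                if s is not None and s != 0:
                    cand_seed = saddle.state + s * e
                    if lo - 1e-12 <= cand_seed[0] <= hi + 1e-12:
                        seed = cand_seed
                        break

    direction = -1.0 if which == "stable" else 1.0

    def f(t, y):
        return direction * model._rhs(y, i_e)

    from .dynamics import _rk4_step

    n = int(round(horizon / dt))
    pts = [seed.copy()]
    y = seed.copy()
    truncated = False
    for i in range(n):
        y = _rk4_step(f, y, i * dt, dt)
        if not np.all(np.isfinite(y)) or abs(y[0] - np.clip(y[0], *bbox)) > 0 or np.any(
            np.abs(y) > state_bound
        ):
            truncated = True
            break
        pts.append(y.copy())
    return SampledBoundary(
        points=np.array(pts), parameterization="time", truncated=truncated
    )


# ---------------------------------------------------------------------------
# classifier-based bisection
# ---------------------------------------------------------------------------


def make_classifier(
    model: NeuronModel,
    i_e: float = 0.0,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> Callable[[np.ndarray], np.ndarray]:
    """Batched spike/no-spike classifier over initial states.

    Returns a callable mapping (N, dim) initial states to a boolean (N,)
    array by free evolution under constant drive ``i_e``.
    """

    def classify(states: np.ndarray) -> np.ndarray:
        fired, _, _ = classify_states(model, states, i_e=i_e, t_end=t_end, dt=dt)
        return fired

    return classify


def bisect_boundary_batch(
    classifier: Callable[[np.ndarray], np.ndarray],
    anchors: np.ndarray,
    direction: np.ndarray,
    lo,
    hi,
    tol: float = 1e-6,
    max_iter: int = 200,
    check_bracket: bool = True,
) -> np.ndarray:
    """Vectorised bisection of a classifier flip along rays.

    Ray i is ``anchors[i] + s * direction[i]``; the flip is bracketed by
    ``s in [lo[i], hi[i]]`` and refined until ``hi - lo < tol``.  Returns
    the (N,) midpoint offsets.
    """
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    N = anchors.shape[0]
    direction = np.asarray(direction, dtype=float)
    if direction.ndim == 1:
        direction = np.broadcast_to(direction, anchors.shape)
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (N,)).astype(float).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (N,)).astype(float).copy()
    if check_bracket:
        c_lo = classifier(anchors + lo[:, None] * direction)
        c_hi = classifier(anchors + hi[:, None] * direction)
        bad = c_lo == c_hi
        if np.any(bad):
            raise BracketError(
                f"no classifier flip in bracket for rays {np.where(bad)[0][:10]}"
            )
    else:
        c_lo = classifier(anchors + lo[:, None] * direction)
    span = np.abs(hi - lo)
    n_iter = min(max_iter, int(np.ceil(np.log2(max(span.max() / tol, 1.0)))) + 1)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        c_mid = classifier(anchors + mid[:, None] * direction)
        same_as_lo = c_mid == c_lo
        lo = np.where(same_as_lo, mid, lo)
        hi = np.where(same_as_lo, hi, mid)
        if np.all(np.abs(hi - lo) < tol):
            break
    return 0.5 * (lo + hi)


def bisect_boundary(
    model: NeuronModel,
    classifier: Callable[[np.ndarray], np.ndarray] | None,
    anchor,
    direction,
    bracket: tuple[float, float],
    tol: float = 1e-6,
    i_e: float = 0.0,
    t_end: float = DEFAULT_T_END,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Deterministic bisection of the spike/no-spike boundary on one ray.

    ``classifier`` defaults to free evolution under constant ``i_e``.
    The classifier must differ at the two bracket ends; repeated calls
    along a family of rays sample the quasi-separatrix of smooth models.
    Returns the boundary state (ray midpoint at tolerance).
    """
    if classifier is None:
        classifier = make_classifier(model, i_e=i_e, t_end=t_end, dt=dt)
    anchor = np.asarray(anchor, dtype=float)
    s = bisect_boundary_batch(
        classifier,
        anchor[None, :],
        np.asarray(direction, dtype=float),
        [bracket[0]],
        [bracket[1]],
        tol=tol,
    )[0]
    return anchor + s * np.asarray(direction, dtype=float)
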