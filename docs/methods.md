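# Methods

## Scope and viewpoint

`sepx` treats the firing threshold of an excitable neuron as a *state
threshold*: a separatrix in state space, as opposed to a *parameter
threshold* such as the DC rheobase, which is a bifurcation phenomenon.
Everything in the package follows from one definition — the instantaneous
threshold voltage θ(**X**; i_e) is the voltage at which instantaneously
shifting the membrane potential, with all other coordinates frozen at
**X**, flips the spike/no-spike outcome of the subsequent evolution under
drive i_e.  Hyperpolarized thresholds (below rest) are first-class: strong
inhibition can create a firing boundary on the hyperpolarized side, which
is exactly the mechanism of post-inhibitory facilitation.

## The model zoo

All dimensionless models use membrane capacitance C = 1; every
recovery/gating variable obeys the adaptation form
dx/dt = (x_∞(v) − x)/τ_x(v), which is what makes voltage-clamp relaxation
exactly solvable.

**QIF** — dv/dt = (v − v_r)(v − v_t) + i_e with reset v ← v_reset at
v_peak.  Defaults v_r = 0, v_t = 30, v_peak = 40, v_reset = −5, chosen so
that a drive of 50 is comfortably subthreshold (the rheobase, where the
two roots of dv/dt = 0 merge, is (v_t − v_r)²/4 = 225).  Thresholds and
resting potentials are the two roots of the quadratic; there is no
separatrix at or beyond rheobase and the package raises rather than
extrapolating.

**Classic FHN** — dv/dt = v − v³/3 − w + i_e,
dw/dt = (k_w v + b_w − w)/τ_w with τ_w = 15, k_w = 1.25, b_w = 0.875.
One stable equilibrium (type II): the threshold is a canard-type
quasi-separatrix, sampled by classifier bisection, never claimed analytic.

**Boltzmann-FHN** — the w-nullcline is replaced by the sigmoid
w_∞(v) = a/(1 + exp((b − v)/c)), a = 2, c = 0.27, τ_w = 8, driven at
i_e = 0.62.  The half-activation is b = 0.3, placing the sigmoid's rise on
the middle branch of the cubic nullcline; this is what produces the type I
portrait the fixture is specified by — exactly three equilibria, a stable
node, a saddle and an unstable node in order of increasing v — and the
saddle's stable manifolds are then genuine (real) separatrices.  The
fixture validates this portrait at construction time and refuses parameter
sets that break it, because every downstream demonstration (manifold
tracing, threshold bisection brackets) assumes it.

**2D piecewise-linear** — C·dv/dt = f(v) − w + i_e,
dw/dt = (k_w v − w)/τ_w, with the three-segment f(v): slopes
(−0.5, 0.5, −0.25), intercepts (0, −1.5, 17.25), breakpoints 1.5 and 25.
τ_w = 5, k_w = 0.45.  Segments use the half-open convention
(middle = [v_l, v_r)); f is deliberately discontinuous at the breakpoints.
The middle segment's fixed point is a *virtual saddle* (it lies in the
right region), yet its stable-manifold line

    w = k_θ v + b_θ,   k_θ = k_m/C − λ_s,
    b_θ = (i_e + b_m)(k_w − k_θ)/(k_w − k_m)

(λ_s the stable eigenvalue of the middle-region Jacobian) is the exact
firing threshold inside the middle region; the hyperpolarized continuation
is the backward-time trajectory through that line (the winding branch
around rest).  k_θ > k_m > k_w holds for the defaults, so depolarizing
current shifts the line up and lowers the threshold voltage.

**3D piecewise-linear** — adds a second recovery current:
C·dv/dt = f(v) − u − w + i_e, du/dt = (k_u v − u)/τ_u,
dw/dt = (k_w v − w)/τ_w, with k_m = 0.95, b_m = −2.175, b_r = 57.825,
right breakpoint 50, k_u = 0.45, τ_u = 5, k_w = 0.6, τ_w = 10.  The
middle-region Jacobian has three real eigenvalues, one dominant positive
(≈ 0.792); the plane spanned by the eigenvectors of the two smallest-|λ|
eigenvalues (≈ +0.01598 and −0.15799 — one weakly unstable, one stable),
anchored at the (virtual) middle equilibrium at v = −21.75, is dynamically
invariant and is the threshold plane.  The transverse dominant direction
is the fast firing direction and fixes the firing side.

**Hodgkin–Huxley** — the classic squid-axon equations in the modern
voltage convention (rest near −65 mV): C_m = 1 µF/cm², ḡ_Na = 120,
ḡ_K = 36, ḡ_L = 0.3 mS/cm², E_Na = 50, E_K = −77, E_L = −54.4 mV, and
the standard rate functions with the removable singularities of α_m
(V = −40) and α_n (V = −55) filled by their limits via a short series
expansion (no NaN anywhere on [−120, 60] mV).  All parameters are
overridable through the config layer.

## Numerical conventions

* **Integration** is classic fixed-step RK4, dt = 0.01 (time units or ms)
  by default.  During a voltage clamp the voltage coordinate is pinned
  exactly (the v-derivative is zeroed and the coordinate reset each step);
  impulses are exact state jumps Δv = q/C between steps, with a narrow
  rectangular realisation available for validation; the QIF reset accepts
  the overshooting step and records the (cappable) peak before jumping to
  v_reset.  The closed-form affine solution of each linear region
  (matrix exponential of the augmented system, which also covers defective
  Jacobians) serves as the integrator's accuracy oracle: RK4 at dt = 1e−3
  agrees to better than 1e−6 and the empirical convergence order exceeds
  3.5.
* **AP criteria.** HH fires if V_max ≥ 0 mV; the piecewise-linear models
  if v_max reaches the right breakpoint of f(v); the FHN family if
  v_max ≥ 1; QIF iff a reset occurred.  Near the right breakpoint of the
  2D model the v_max criterion cannot distinguish a genuine regenerative
  excursion from a subthreshold poke past the breakpoint — this is the
  corner where the separatrix border and the dv/dt = 0 border of the clamp
  map merge, and quantitative boundary-vs-analytic comparisons are made on
  the depolarized middle region away from that junction (v_c ≲ 20).
* **Thresholds** are found by bisection over the voltage axis after a
  20-point pre-scan; when several flips exist (graded, quasi-threshold
  responses, or the coexistence of depolarized and hyperpolarized
  boundaries), the flip nearest the resting potential is reported and a
  warning is issued; local brackets select a specific branch.  All
  bisections are batched: one vectorised classifier call per iteration,
  whatever the number of rays.
* **Classification horizons.**  Spike/no-spike decisions use 60–100 time
  units for the dimensionless models (dt = 0.02 in the test suite — the
  eigenvalues are all ≪ 1/dt, so RK4 error is orders of magnitude below
  every asserted tolerance) and 50 ms at dt = 0.01 for HH.  A trajectory
  bisected to within ε of the separatrix lingers for a time growing like
  log(1/ε), so the horizon bounds how tightly a threshold can be resolved;
  both routes of every cross-validation use the same classifier settings,
  which keeps identities such as V_c = θ(X(V_c, τ_c); 0) consistent.
* **Threshold-evolution traces** integrate
  dθ/dt = ∂θ/∂i_e·di_e/dt + Σ ∂θ/∂x·ẋ along protocols where the gating
  path is known in closed form: voltage clamps (and pure-current protocols
  for QIF, where θ depends on i_e alone).  This is also the regime in
  which the single-exponential reduction is exact — under a clamp x_∞ is
  constant, so the 2D threshold relaxes with τ_θ = τ_w identically, while
  under free subthreshold evolution v(t) varies and the reduction is only
  approximate.  Partial derivatives are analytic for QIF and the
  piecewise-linear models (differentiating the closed-form separatrix) and
  central finite differences of the bisection threshold for HH
  (fd step 1e−3 per gating unit; the perturbed bisections run at a
  1000-fold tighter tolerance so that bisection noise divided by the small
  step does not pollute the gradients).  Quadrature is cumulative Simpson;
  for analytic integrands the grid is refined 10× internally, and for HH
  the node grid must resolve the sub-millisecond m-gate transient at clamp
  onset — the shipped analyses use 41 quadratically clustered nodes over a
  6 ms clamp, which keeps the ODE-vs-bisection discrepancy below half the
  5×(bisection tolerance) budget.
* **Scans** compute the settled rest once (200 time-unit free run), relax
  gating through the clamp in closed form, and classify all grid cells as
  one batch.  Default grids: v_c ∈ [−30, 40] step 0.5 with τ_c ∈ (0, 20]
  step 0.1 for the 2D model; V_c ∈ [−90, −30] mV step 2 with
  τ_c ∈ (0, 25] ms step 0.5 for HH — coarse enough for desk-scale runs,
  fine enough to resolve both borders, and freely overridable (the test
  suite and the acceptance script state their own, mostly coarser, grids).
  Boundary extraction refines each fire/no-fire flip by batched bisection
  in the scanned parameter; the high-voltage dv/dt = 0 border of clamp
  maps is extracted from the "rises above the clamp voltage" indicator
  instead of the AP flag.

## What the demonstrations do and do not show

The analytic models are exactly solvable caricatures: their separatrices
are straight objects and every numerical claim about them has a closed-form
oracle.  Passing those checks validates the machinery (integration,
classification, bisection, quadrature), not any biological quantity.  The
HH demonstrations show that the same separatrix-crossing structure —
depolarized-clamp suppression, hyperpolarized-clamp facilitation with a
monotone boundary, threshold self-consistency on the low-voltage border —
appears in a biophysical model, but HH here is a single isopotential
compartment without noise, temperature dependence, or morphology; nothing
in the package speaks to multi-compartment initiation sites or to
stochastic channel gating.  The hyperpolarized clamp border of HH crosses
the self-consistency identity at a glancing angle, which amplifies
bisection tolerance; the quantitative identity check is therefore stated
for the depolarized (low-voltage) border where the crossing is transversal.

## Known limitations

* Only one clamp segment per protocol is supported by the threshold-ODE
  integrator, and current protocols during/after the clamp are assumed
  zero (the post-clamp system is autonomous).
* The quasi-separatrices of the smooth models are sampled point sets, not
  fitted surfaces; no continuation under parameter sweeps is provided.
* `eq1_reduction_fit` fits a single exponential only; it flags, but does
  not model, multi-exponential traces.
* Thresholds are only as sharp as the classification horizon allows; for
  quasi-threshold (type II) models the reported θ is the flip of a
  "fires within the horizon" classifier, which is the operationally
  meaningful quantity but not a mathematical invariant.
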