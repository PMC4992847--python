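# sepx — separatrix-crossing analysis of spike-threshold variability

The voltage at which a neuron fires an action potential is not a constant:
it moves with the stimulus history and with the state of every ion channel.
`sepx` is a toolkit for studying the dynamical-systems account of this
variability, in which the firing threshold is the **separatrix** — the
boundary in state space dividing initial conditions that fire from those
that do not.  The *instantaneous threshold voltage* θ(**X**; i_e) is the
voltage coordinate of that boundary at a frozen gating state **X** and
drive i_e, and its evolution in time obeys

    dθ/dt = ∂θ/∂i_e · di_e/dt + Σ_x ∂θ/∂x · (x_∞(v) − x)/τ_x(v)

for any model whose gating variables follow the adaptation form
dx/dt = (x_∞(v) − x)/τ_x(v).  When one gating variable with a constant
time constant dominates and θ is linear in it, this collapses to the
classic first-order threshold equation
θ(t) = θ_∞ + (θ₀ − θ_∞)·exp(−t/τ_θ).

The package is aimed at computational neuroscientists who want exact,
checkable threshold objects rather than ad-hoc dV/dt criteria.  It ships:

* **a model zoo** with analytic structure — quadratic integrate-and-fire
  (threshold = a point that moves with i_e), FitzHugh–Nagumo and a
  Boltzmann-nullcline type I variant, 2D and 3D piecewise-linear models
  (threshold = an exactly computable line / plane, the stable manifold of
  a possibly *virtual* saddle), and the classic Hodgkin–Huxley equations
  (threshold = a hypersurface, sampled numerically);
* **deterministic RK4 integration** under DC/step/ramp/impulse stimuli and
  ideal voltage clamp, with batched evolution of thousands of initial
  conditions;
* **separatrix computation** — analytic coefficients, backward-time
  manifold tracing, and classifier bisection for quasi-separatrices;
* **threshold machinery** — instantaneous-threshold search, closed-form
  voltage-clamp gating relaxation, threshold-evolution traces by two
  independent routes (the ODE above vs direct bisection), and the
  single-exponential reduction fit;
* **parameter-plane scans** — maximum-voltage maps over (clamp voltage,
  clamp duration) or (pulse amplitude, duration) with fire/no-fire
  boundary extraction and analytic oracles for the 2D model.

## Worked example

```python
import numpy as np
from sepx import (get_model, pwl2d_separatrix, instantaneous_threshold,
                  post_clamp_fires, rest_state)
from sepx.scans import analytic_clamp_boundary

m = get_model("pwl2d")                 # piecewise-linear 2D neuron
line = pwl2d_separatrix(m, i_e=0.0)    # the threshold line w = kθ·v + bθ
print(f"k_theta = {line.k_theta:.6f}, b_theta = {line.b_theta:.6f}")

theta = instantaneous_threshold(m, [0.0]).theta
print(f"threshold at rest recovery (w=0): {theta:.4f}")

tau_star = analytic_clamp_boundary(m, 15.0)
rest = rest_state(m)
print(f"clamp at v_c=15 fires iff held < {tau_star:.4f} time units:",
      post_clamp_fires(m, rest, 15.0, tau_star - 0.1),
      post_clamp_fires(m, rest, 15.0, tau_star + 0.1))
```

prints

```
k_theta = 0.530278, b_theta = -2.408327
threshold at rest recovery (w=0): 4.5416
clamp at v_c=15 fires iff held < 8.6188 time units: True False
```

Read: the separatrix line has slope 0.530 (steeper than both nullclines,
so depolarizing current *lowers* the threshold); from rest the line is
crossed at v = 4.54; and a depolarized voltage clamp at v = 15 stops
triggering a spike once it is held longer than 8.62 time units, because the
recovery current relaxes across the separatrix during the clamp — the same
mechanism that makes *long hyperpolarized* clamps facilitate firing
(post-inhibitory facilitation).

## Command line

```bash
sepx simulate   --model hh --out traj.csv        # one trajectory + events
sepx equilibria --model pwl2d --out eq.csv       # fixed points, stability
sepx separatrix --model pwl2d --out sep.csv      # line/plane + JSON sidecar
sepx threshold  --config clamp.toml --method ode --out theta.csv
sepx clamp-scan --model hh --out vmax.csv --boundary-out border.csv
sepx stim-scan  --model fhn --kind step --amp-grid 0,0.3,31 \
                --dur-grid 1,15,15 --out pulse.csv
```

All subcommands are deterministic (byte-identical CSV across runs); logs
go to stderr, results to files.

## Layout

| module | contents |
|---|---|
| `sepx.models` | model zoo, equilibria, Jacobians, HH rate functions |
| `sepx.dynamics` | protocols, RK4 integration (single + batched), classification |
| `sepx.separatrix` | threshold point/line/plane, manifold tracing, bisection |
| `sepx.threshold` | instantaneous thresholds, clamp relaxation, threshold ODE |
| `sepx.scans` | V_max maps, boundary extraction, analytic clamp boundaries |
| `sepx.config` / `sepx.io` / `sepx.cli` | TOML/JSON config, CSV/JSON output, CLI |

See `docs/methods.md` for the models, conventions, numerical choices and
known limitations.
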