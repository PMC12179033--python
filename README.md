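# mlsconflict

Simulator for a PDE model of multilevel selection with pairwise
group-level conflict. A population of groups is described by a density
`f(t, x)` over the within-group cooperator fraction `x ∈ [0, 1]`;
within-group replicator dynamics transport the density toward the
individually favored composition while pairwise group conflicts — won
with probability `ρ(x, y)` by the group with composition `x` — reweight
it toward collectively successful compositions:

```
∂f/∂t = ∂/∂x [ x(1−x) π(x) f ]  +  λ f [ 2 ∫ ρ(x, u) f(t, u) du − 1 ]
```

Here `π(x) = −(β + αx)` is the defectors' payoff advantage and
`λ` the relative strength of between-group conflict. The package
provides:

- **games** — 2×2 payoff matrices, the shorthand coefficients
  `(α, β, γ, P)`, group average payoff `G(x) = P + γx + αx²`,
  game classification (PD/HD/SH/PDel), and the distinguished cooperation
  levels (interior equilibrium, payoff-maximizing and payoff-matching
  fractions).
- **victory** — built-in victory kernels (fraction difference, local
  update, Fermi/tanh, normalized difference, Tullock contest, additively
  separable) plus a lattice validator of the kernel axioms
  (`0 ≤ ρ ≤ 1`, `ρ(y,x) = 1 − ρ(x,y)`, dominance above a threshold).
- **solver_fv** — conservative first-order upwind finite-volume
  discretization with explicit Euler stepping, exact zero boundary
  fluxes, pre-tabulated kernel matrix, and CFL validation.
- **solver_particles** — measure-valued oracle solver: atoms transported
  along the exact replicator characteristics with weights fixed by
  Picard iteration on the implicit exponential-reweighting formula;
  Wasserstein-1 distance for cross-validation.
- **analysis** — diagnostics (mean cooperation, success against the
  all-cooperator group, tail masses), analytic thresholds
  `λ*_PD = θπ(1)/(ρ(1,0) − ρ(0,1))` and
  `λ*_HD = θπ(1)/(ρ(1,x_eq) − ρ(x_eq,1))`, the steady-state success
  prediction `1/2 − θπ(1)/(2λ)`, tail (Hölder) exponent estimation, and
  steady-state residuals/detection.
- **cli / presets / io** — YAML configs, the published figure presets
  (`fig1-left` … `fig9-right`), and CSV/JSON outputs.

## CLI

```bash
# run a config file (YAML or JSON)
mls run --config examples/pd.yaml --out out/

# run a named figure preset, optionally shortened
mls scenario fig1-right --steps 2000 --out out/
mls scenario x --list

# analytic threshold report as JSON
mls thresholds --config examples/pd.yaml

# sweep lambda and compare against the analytic prediction
mls sweep --config examples/pd.yaml --lambda-grid 1:48:8 --out sweep.csv

# cross-validate the finite-volume and particle solvers
mls compare-solvers --config examples/pd.yaml --t 1.0
```

A minimal config:

```yaml
game: {alpha: -1, beta: -1, gamma: 1.5, P: 1}   # or {R: 1.5, S: 0, T: 3.5, P: 1}
kernel: {family: fermi, s: 1.0}
lambda: 14
dt: 0.003
n_steps: 1400
```

or simply `preset: fig1-right` with optional overrides.

## Notes

- Mass is conserved exactly by both sub-steps (zero boundary fluxes for
  advection; kernel complementarity for the conflict term, written with
  the discrete mass so roundoff is not amplified at rate `e^{λt}`).
  Renormalization is off by default and drift is reported in the run
  metadata.
- The bistable (stag-hunt) presets use `β = −1` where the published
  caption prints `β = 0`: the caption's own `x_eq = 0.5` requires
  `β = −1`, and `β = 0` is inconsistent with the stag-hunt ordering.
  See the preset provenance notes.
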