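# gba — growth balance analysis

Tools for modeling and analyzing **balanced cellular growth** with nonlinear
reaction kinetics. A cell is described as a self-replicator: transporters
bring nutrients across the surface, enzymes interconvert internal
metabolites, and a ribosome reaction produces the proteins that catalyze
everything — including itself. Given such a model, `gba` finds the resource
allocation that maximizes the balanced growth rate and exposes the full
mathematical structure of that optimum: shadow prices, marginal economic
values of each flux, and sensitivities of optimal growth to kinetic and
environmental parameters.

It is aimed at systems biologists studying optimal resource allocation,
proteome economics, and metabolic control in coarse-grained whole-cell
models.

## The model

A growth balance model is a triple **(M, τ, ρ)** plus an environment **x**:

* **M** — the *mass fraction matrix*: the stoichiometric matrix of the closed
  system, mass-weighted row-wise and column-normalized so negative entries
  sum to −1 and positive entries to +1, with external-reactant rows dropped.
  Internal columns (enzymes `e`, ribosome `r`) then conserve mass exactly
  (column sums γ<sub>e</sub> = γ<sub>r</sub> = 0) while transport columns
  carry net mass across the surface (γ<sub>s</sub> ≠ 0).
* **τ(c, x)** — a *turnover time* per reaction (inverse of the saturation
  factor of its rate law, so that catalyst concentration and flux satisfy
  p = v τ); constant, irreversible and reversible Michaelis–Menten dialects
  are built in, with optional non-competitive inhibition, all in mass units.
* **ρ** — the fixed total mass density of the cell interior, and **x** the
  fixed external concentrations.

At balanced growth every variable scales out except the dimensionless *flux
fractions* f = v/(μρ). Mass conservation gives the biomass fractions
b = M f = c/ρ, and the growth rate becomes an explicit function

&nbsp;&nbsp;&nbsp;&nbsp;μ(f) = M<sub>ra</sub> f<sub>r</sub> / (fᵀ τ(ρMf, x)),

maximized subject to γᵀf = 1 (density constraint as a surface flux balance),
f ⊙ τ ≥ 0 (non-negative proteins) and Mf ≥ 0 (non-negative concentrations).
At the optimum the Karush–Kuhn–Tucker conditions yield *balance equations*
(∂<sub>j</sub>μ + λγ<sub>j</sub>) f<sub>j</sub> = 0 that decide which
reactions are active, with the density shadow price
λ = (μ²/bᵃ) fᵀE f and protein shadow prices θ<sub>j</sub> =
−(∂<sub>j</sub>μ + λγ<sub>j</sub>)/τ<sub>j</sub>, where E is the matrix of
indirect elasticities ∂τ/∂f. The package computes all of these, the economy
decomposition of each marginal value into production / investment /
opportunity terms, growth and enzyme control coefficients, and adaptation
coefficients A<sub>π</sub> = (π/μ*) dμ*/dπ via the envelope theorem.

## Worked example

The minimal self-replicator (built-in model `A`) has one transporter and the
ribosome, M = [[1, −1], [0, 1]], ρ = x = 1 and unit Michaelis–Menten
kinetics. Its optimum is known in closed form: f<sub>r</sub>* = 2 − √2,
μ* = (2 − √2)/4.

```python
import gba

m = gba.builtin_model("A")
res = gba.maximize_growth(m, n_starts=20, seed=1)
print("mu* =", res.mu_star)
print("lambda =", res.lambda_)

rep = gba.analyze(m, res.f_star)
print("phi =", dict(zip(m.reaction_ids, rep.phi)))
print("A_tau =", dict(zip(m.reaction_ids, rep.adaptation.A_tau)))
print("A_x =", rep.adaptation.A_x)
print("A_rho =", rep.adaptation.A_rho)
```

prints

```
mu* = 0.14644660940672624
lambda = -0.051776695296636886
phi = {'s': 0.5, 'r': 0.5}
A_tau = {'s': -0.5, 'r': -0.5}
A_x = {'glc_ext': 0.25}
A_rho = 0.353553391
```

Reading: the optimal cell grows at μ* = (2 − √2)/4 ≈ 0.1464 per unit time
and allocates exactly half its proteome to uptake and half to the ribosome
(φ). A 1% slow-down of either catalyst costs 0.5% of optimal growth
(A<sub>τ</sub> = −φ); a 1% richer medium buys 0.25% growth (A<sub>x</sub>);
a 1% denser cell buys √2/4 ≈ 0.354% growth (A<sub>ρ</sub>), consistent with
the density shadow price through −λ = μ·A<sub>ρ</sub>.

The same is available from the shell:

```sh
gba fixture --name A --out A.toml
gba optimize A.toml --starts 20 --seed 1
gba analyze A.toml --result A_result.json
gba sweep A.toml --param x.glc_ext --grid 0.2:2:10 --reoptimize
```

## Layout

| module | contents |
| --- | --- |
| `gba.model` | `GBAModel`, matrix construction and structural validation |
| `gba.kinetics` | turnover-time laws, direct/indirect elasticities |
| `gba.growth` | growth function, constraints, scaled/physical conversion |
| `gba.optimize` | multistart SLSQP + active-set polish, active-set report |
| `gba.analysis` | gradient, KKT multipliers, balance equations, economy, control, adaptation |
| `gba.fixtures` | reference models A/B/C/redundant, random models, grid oracle, CV utility |
| `gba.io`, `gba.cli` | TOML model files, result JSON, `gba` command |

See `docs/methods.md` for the mathematical conventions, solver details and
known limitations.
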