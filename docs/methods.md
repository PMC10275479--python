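# Methods

## Model and assumptions

A growth balance model represents a cell at balanced growth — the
non-equilibrium steady state in which every component accumulates at a
common rate μ — as a triple (M, τ, ρ) with environment x:

* Internal reactants are metabolites `m` plus a single pooled total-protein
  species `a`. All proteins are assumed to share one amino-acid composition
  and are produced by a single ribosome reaction `r` (itself pure protein);
  the ribosome column of M is the only one touching the `a` row, with
  M[a,r] > 0.
* Every reaction j is catalyzed by a protein with concentration
  p_j = v_j · τ_j(c, x). The turnover time τ_j is the inverse of the
  saturation factor of the rate law; τ_j < 0 encodes a backward-running
  reaction. Rate laws never depend on the protein pool (no macromolecular
  crowding), so the `a` row of the elasticity matrix ε = ρ ∂τ/∂c is zero.
* ρ, the summed mass concentration of all internal components, is constant
  across conditions. All quantities are in mass units ([mass][volume]⁻¹,
  [time]⁻¹); no mole-based interface exists, to preclude silent unit mixing.

In flux fractions f = v/(μρ) the whole problem closes over f alone:
b = M f, τ = τ(ρMf, x), μ(f) = M[a,r] f_r / (fᵀτ), with constraints
γᵀf = 1, f⊙τ ≥ 0, M f ≥ 0.

## Structural conventions

* Reactants are rows, reactions are columns; every operation addresses
  entries by identifier, never by position. The builtin models keep the `a`
  row and `r` column last by convention only.
* All structural checks (column normalization, protein-row sparsity) use an
  absolute tolerance of 1e−9 — safe for hand-entered double-precision
  fractions.
* A transport column with γ_s = 0 (a mass-neutral antiporter) is admitted
  with a warning rather than rejected: the density constraint only needs
  one transporter with γ ≠ 0 to be satisfiable.
* `construct_mass_fraction_matrix` refuses mass-imbalanced columns instead
  of rebalancing them; an imbalance almost always means a ubiquitous
  reactant (water) was silently omitted, and guessing would hide that.

## Kinetic dialects

Three law kinds are provided. Multi-substrate irreversible Michaelis–Menten
multiplies (1 + K/c) factors; the reversible law is the standard
one-substrate/one-product form

  τ = (1 + Σ_s c_s/K_s + Σ_p c_p/K_p) / (k⁺ Π_s c_s/K_s − k⁻ Π_p c_p/K_p),

and non-competitive inhibition multiplies any law by (1 + c_i/K_I). These
are the package's reference dialects; the law registry is extensible without
interface changes. Concentration derivatives are hand-coded closed forms;
central finite differences serve as an independent test oracle (never as a
fallback).

## Optimization

The growth maximization is smooth but non-convex (parallel pathways create
disconnected optima), and no algorithm with a global guarantee is known for
this problem class. The package uses the honest baseline:

1. **Starting points.** An interior "center" is found by a linear program
   maximizing the smallest concentration slack subject to γᵀf = 1, f ≥ 0.
   Random forward-orthant directions are normalized onto the density plane
   and blended toward that center until M f ≥ ε_b (ε_b = 1e−6). One seeded
   generator drives all draws, so point lists are reproducible.
2. **Local solves.** SLSQP with the analytic growth gradient, the linear
   constraints γᵀf = 1 and M f ≥ ε_b, and the nonlinear protein constraint
   f⊙τ ≥ 0 with its analytic Jacobian diag(τ) + f Eᵀ-row structure. During
   the search, required concentrations are clipped at 1e−10·ρ so transiently
   infeasible iterates keep finite turnover times; the clip is inactive at
   any interior solution. Default 20 starts; ties broken by lower start
   index.
3. **Polish.** The best candidate's active set is detected
   (|f_j| > 1e−6·max|f|; several coarser thresholds are also tried),
   inactive reactions are pinned at exactly zero, one active transporter is
   eliminated through the density constraint, and BFGS plus a few Newton
   steps on the reduced gradient (which coincides with the growth control
   coefficients Γ) drive the stationarity residual toward machine precision.
   The interior margin is relaxed to 1e−12 and the final point is re-checked
   against the true constraints M f ≥ 0, f⊙τ ≥ 0; metabolites driven to the
   boundary are reported.
4. **Certification.** The returned optimum always carries the first-order
   residual max_j |(∂_jμ + λγ_j) f_j|, required to be ≤ tol·μ*; a candidate
   violating it (or feasibility) raises instead of being returned silently.

Starts are sampled in the all-forward orthant by default: f_j τ_j ≥ 0 slices
the feasible set into orthant pieces and enumerating all of them is
exponential. Models whose laws admit τ < 0 can be searched with negative
bounds via the internal `allow_negative` path of the feasibility LP.

## Analytical layer

All formulas are evaluated at any state f, with μ/bᵃ implemented as
1/(fᵀτ) so the gradient stays finite at zero ribosome flux:

* gradient ∂_jμ = (μ/bᵃ)(M[a,j] − μτ_j − μ(fᵀE)_j);
* multipliers λ = (μ²/bᵃ) fᵀEf and θ_j = −(∂_jμ + λγ_j)/τ_j, with the
  transporter-local alternative λ = −Σ_s (∂_sμ) f_s / Σ_s γ_s f_s asserted
  equal at optima;
* balance residuals in three equivalent forms: the KKT surface
  (∂_jμ + λγ_j)f_j, per-kind simplifications (ribosome / enzyme /
  transporter), and the unscaled physical-variable form, which equals the
  scaled form times ρbᵃ > 0 (the package reads the elasticity contraction
  in the unscaled form as ∂τ/∂c, which makes the two vanish together —
  verified at all fixture optima);
* the economy triple (production M[a,j], investment −μτ_j, opportunity
  −μ(fᵀE)_j) and its proteome-derivative twin, computed literally by
  perturbing f at frozen μ and re-evaluating φ_l = μ f_l τ_l / (Mᵃf);
* growth control coefficients Γ with the eliminated transporter s′ chosen
  as the active transporter of largest |f| when not specified (the theory
  requires only "one active transport reaction"); the report records the
  choice;
* enzyme control coefficients C[e,l] = −(f_e/τ_l) E[l,e] and the optimum
  identity p_e = Σ_l p_l C[e,l];
* adaptation coefficients A_τj = −φ_j, A_x = −Σ_s φ_s (x/τ_s) ∂τ_s/∂x,
  A_ρ = −(μ/bᵃ) fᵀEf, cross-checked by `envelope_check`, which re-optimizes
  a relatively perturbed model (default δ = 1e−4, same seed policy) and
  compares the empirical coefficient (π/μ*)Δμ*/Δπ; an active-set change
  under perturbation is flagged because the envelope argument assumes it
  fixed.

θ sign convention: with L = μ + λ(γᵀf − 1) + θᵀ(f⊙τ) and maximization over
a ≥-inequality, dual feasibility is θ ≥ 0; tests assert it with a tolerance
of 1e−6 on the scale max(max|θ|, μ*²), since θ carries units of μ² and all
θ vanish when every reaction is active.

## Finite-difference conventions

Central differences with step h = 1e−6·(1 + |value|) throughout. The
finite-difference oracles sample feasible states with an interior margin of
0.02 rather than the optimizer's 1e−6: τ ~ K/c diverges at the positivity
boundary and its third derivative (~K/c⁴) would otherwise dominate the
truncation error.

## Fixtures and what they do (not) show

The builtin models A/B/C/redundant are this package's own reference
self-replicators: minimal chain topologies with unit parameters, chosen so
optima and sensitivities have closed forms (model A: f_r* = 2 − √2,
μ* = (2 − √2)/4, φ = (½, ½), A_x = ¼, A_ρ = √2/4) or are reachable by
exhaustive grids. Model C adds a 30% mass leak exported as a CO₂-like waste
so that the density constraint genuinely couples two transport fluxes;
`redundant` duplicates an enzyme at half speed so M is column-rank-deficient
and the optimizer must deactivate one branch. The random generator produces
seeded chain models with log-uniform parameters in [0.1, 10], the spread
spanning the two orders of magnitude typical of measured kcat/Km
variability.

These fixtures validate the mathematics — gradients, multipliers,
identities, active-set structure — not biological realism: they are far
smaller than genome-scale networks, use idealized single-substrate kinetics,
and say nothing about the numerical behavior of the solver on models with
thousands of reactions or near-degenerate alternative optima.

The grid oracle (`brute_force_optimum`) supports at most two free
dimensions after eliminating one transporter; model A is swept at step 1e−6
and model B at 1e−3 (10⁶ points each, vectorized), sizes chosen to resolve
the optima to the tolerances the tests assert.

## Degenerate inputs and edge cases

* μ = 0 at f_r = 0 is a value, not an error; only the scaled→physical
  conversion (`unscale_state`) requires μ > 0, since f = v/(μρ) is
  undefined at zero growth. The behavior of the formalism *at* μ = 0 is
  otherwise left undefined.
* `growth_rate` raises on non-positive required concentrations rather than
  clamping: the mathematical object stays exactly the growth function, and
  interiority is the optimizer's job.
* Reversible laws at thermodynamic equilibrium (zero net turnover) raise a
  singular-turnover error.
* The amino-acid variation utility uses the sample (n−1) standard
  deviation for its coefficients of variation; the population convention is
  the documented fallback if a reference table is ever matched against.

## Known limitations

* No global-optimality certificate; multistart plus oracle cross-checks is
  the supported strategy. Mixed-orthant (backward-flux) searches are not
  enumerated exhaustively.
* No Hill/convenience kinetics, no thermodynamic (Haldane) coupling of k⁻
  to equilibrium constants, no crowding-dependent K_m(ρ).
* No SBML import, no time-dependent environments, no stability analysis of
  the balanced-growth state.
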