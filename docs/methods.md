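# Methods

This note records the modelling assumptions, parameter conventions and
numerical choices behind `vasotone`, and what the shipped tests do and do
not establish.

## Model structure and assumptions

The model is steady-state and sequentially coupled: luminal pressure drives
the signalling network, the network's outputs (cross-bridge fraction
`n_XB`, F-actin level `xi7`) parameterize the contractile machinery, and
the machinery's active strain energy enters the wall equilibrium. There is
no feedback from mechanics to chemistry — wall stress influences the cell
only through the normalized pressure stimulus `p_bar = min(P/P_max, 1)`.
Pressures above `P_max` (150 mmHg) saturate every intracellular process.

The signalling network is a seven-node DAG. Three assumptions matter:

* Pathways act in parallel, not sequentially: Ca²⁺ (via MLCK), ROCK (via
  MLCP inhibition and cofilin phosphorylation) and PKC (via HSP27) each
  receive the pressure stimulus through their own logistic edge.
* pLC₂₀ follows a kinase/phosphatase mass balance rather than a logic rule;
  its steady state is `chi5/(chi5 + 1 - chi6)`.  The degenerate case
  `chi5 = 0` with `chi6 = 1` (kinase off, phosphatase fully inhibited) has
  no defined equilibrium fraction and raises `SingularEquilibriumError`
  rather than returning an arbitrary value; it does not occur with the
  shipped coefficients.
* G-actin is down-regulated by pCofilin and pHSP27 through an OR gate, so
  F-actin is the product `chi7(xi4) * chi8(xi2)`.

Because the graph is acyclic, steady states are computed exactly in
topological order; the relaxation ODEs (all time constants 1) are retained
and tested as an independent route to the same fixed point, but transient
predictions are unvalidated.

Interventions are node clamps: the clamped node's ODE is removed and its
value substituted wherever it appears (Ca²⁺-free bath: `xi0 = 0.1`; H1152
0.3/0.5 µM: `xi1 = 0.12/0.07`; GF 3 µM: `xi2 = 0.1`). Downstream nodes
still equilibrate.

Cell mechanics follows the filament-sliding picture: only phosphorylated
(cycling) cross-bridges bear force — latched bridges are assumed
force-free, so no four-state cross-bridge kinetics is required. The
filament overlap is a Gaussian in the normalized sliding. The overlap
exponent is implemented *negative* (peak 1 at the optimal sliding), which
is the Gaussian the model intends; with a positive exponent the "overlap"
would grow without bound away from the optimum. Cross-bridge elongation
and cortex elongation are never materialized separately; the reaction
force is written directly in terms of the circumferential stretch and the
sliding, which eliminates them exactly.

The wall is a homogeneous incompressible axisymmetric thick tube at fixed
axial stretch, with a scalar circumferential pre-stretch `k_omega` standing
in for residual strain (no opening-angle model, no multi-layer wall, no
axial force balance). Collagen fibres are circumferential (`phi = 0`) and
carry no compression: the anisotropic energy term and its derivative are
set to zero whenever the fibre invariant `I4 < 1`. External pressure is
taken as zero. The circumferential stretch profile `lambda_theta =
k_omega * r/R` follows from incompressibility together with the radial
stretch `lambda_r = R/(r k_omega lambda_z)`; their product with `lambda_z`
is exactly 1 at every wall point.

The filament sliding is treated as uniform across the wall and driven by
the thickness-averaged circumferential stretch; inside the pressure
integral the active stress is evaluated pointwise in `lambda_theta(R)`
with that single sliding value.

## Parameters

Defaults (in `src/vasotone/data/default_params.yaml`) are the fitted
coefficients for rat middle cerebral arteries: nine logistic triplets
(B₀, K, n) for the network, and CGS mechanical parameters — geometry
(`R_o' = 0.0110 cm` for vessel group 1, `0.0126 cm` for group 2,
`h_w = 0.367`, `lambda_z = 1.364`, `k_omega = 1.373`), passive constants
(`c0 = 9.1633e4`, `c1 = 3.15e4 dyne/cm²`, `c2 = 0.646`) and active
machinery (`u_PS = 1.424e-6 cm`, `k_XB/delta_m = 8.166777e6 dyne/cm²`,
`u_fs_opt = 0.0149`, `s_f0 = 5.87e-7 cm`, `k_ACmax = 10.04 dyne/cm`,
`n_AC = 4.156`, `K_AC = 10.201`, `N_CF = 2.44e10 cm⁻²`,
`L_SMC = 0.01 cm`, `L_m = 3e-5 cm`). Only the ratio `k_XB/delta_m` is
identifiable, never the factors separately. `n_XBmax = 0.55` caps the
phosphorylatable cross-bridge pool.

`N_CU`, the number of contractile units in series per fibre, is not part
of the fitted table; the default of 10 is an order-of-magnitude literature
value for vascular SMC contractile fibres, it is exposed in the parameter
file, and every output manifest records the value used. Reference values
for the box bounds on `u_PS`, `k_XB/delta_m` and `k_ACmax`
([0.1, 10] x reference) default to the shipped fitted values, so the
shipped set sits strictly inside its own bounds; pass explicit
`reference_values` to reproduce a different bounding convention.

Geometry factors carry soft fitted ranges (`0.13 <= h_w <= 0.40`,
`1.0 <= lambda_z, k_omega <= 1.5`): violations are warnings during
validation and penalty terms during fitting, not hard errors.

Units: CGS internally; pressures cross the API in mmHg
(1 mmHg = 1333.22 dyne/cm²) and the CLI prints µm diameters.

## Numerics

* **Wall integral.** Composite Simpson on an odd, uniform reference-radius
  grid. The default is 81 nodes: the exponential collagen term makes the
  integrand sharp enough that 11 nodes leave ~1e-3 relative error, while 81
  nodes agree with a 1e5-node trapezoid reference to ~2e-7 over the
  physiological inflation range (`r_i` in [0.5, 1.25] of the reference
  inner radius, i.e. pressures within the 0–120 mmHg protocol). The node
  count is configurable (`SolverOptions.n_nodes`); a grid-refinement test
  (81 vs 161 nodes, <1e-6 relative) guards the default.
* **Coupled solve.** Chemistry first (closed form), then a simultaneous
  2-D quasi-Newton root solve for `(r_i, u_fs_bar)` (scipy `root`, hybr
  with lm fallback), seeded by continuation along the pressure schedule
  (the previous equilibrium starts the next pressure; the passive radius
  and zero sliding start the first). A restart ladder perturbs the sliding
  guess (0, −0.03, −0.06, +0.03) on failure. Convergence demands
  |ΔP| ≤ 1e-8 mmHg and |F_a − F_c| ≤ 1e-10 dyne; non-convergence raises
  with the failing pressure, last iterate and residuals. When `n_XB = 0`
  (passive vessel) the force equation degenerates to 0 = 0; the sliding is
  set to its fixed point 0 and only the scalar pressure equation is solved
  (bracketed Brent).
* **Degenerate composites.** The series stiffness `k_tCU k_AC/(2 k_tCU +
  k_AC)` is defined as 0 when both stiffnesses vanish (physical limit of
  absent machinery).
* **Logistic edges.** Evaluated in log space (`expit`-style), so fitted
  exponents up to n ≈ 520 neither overflow nor underflow; the endpoint
  values χ(0) = B₀ and χ(1) = 1 are returned exactly.
* **Transient integration.** LSODA with rtol 1e-10; states are clipped to
  the unit box inside the right-hand side to tolerate the tiny overshoots
  of adaptive stepping. Note that the pLC₂₀ relaxation rate is
  state-dependent (`chi5 + 1 - chi6`); interventions that drive both terms
  to zero freeze the node, and no finite integration horizon reaches the
  closed-form fixed point there.

## Calibration

Two stages: chemical (logistic coefficients against phosphorylation/content
observables) then mechanical (geometry/passive/active parameters against
pressure-diameter curves, chemistry frozen). The cost is `L_tot = L_data +
sum_i kappa * delta_i` with `kappa = 1e3` and `L_data` the unweighted L2
norm of simulated-minus-mean residuals after per-row normalization
(pLC₂₀ absolute; pMLCP/pHSP27/pCofilin/G-actin relative to the simulated
control at 10 mmHg; diameters absolute). SD-weighting of residuals is
deliberately not the default — the reference protocol fits plain L2 — but
the SDs are carried in the tables for users who want it. Constraints:

* chemical — EC₅₀ of the pressure-Ca²⁺ edge ≥ 0.1 (EC₅₀ defined as the
  input reaching half the *dynamic range* `B0 + (1-B0)/2`, which stays
  well-posed for high-basal edges; found by bracketed root search);
  Ca²⁺-free pLC₂₀ ≤ the 10 mmHg control value for all P ≤ 120 mmHg; and an
  optional user-supplied pressure-Ca²⁺ envelope band (skipped loudly when
  absent — the reference envelope data is not distributed).
* mechanical — max |ū_fs| ≤ 0.1 over the control sweep; the control
  dD_o/dP must not be positive across the whole 60–100 mmHg band (central
  differences on the sweep grid; the penalty distance is the minimum slope
  in the band when positive); box bounds on `h_w`, `lambda_z`, `k_omega`
  and the scale-bound active parameters.

The optimizer is an in-package (μ/μ_w, λ)-CMA-ES (standard weights, CSA
step-size control, rank-one + rank-µ covariance update), deterministic
given a seed; "multiple runs" is operationalized as a seed list (default 8)
with best-of selection, and all per-seed outcomes are reported. Positive
scale parameters (K, n, stiffness/length scales) are searched in log10;
`B0` and geometry factors linearly. Bounds enter through the penalty, not
clipping. The GF-referenced pLC₂₀ series can be re-anchored to the control
reference with `preprocess_gf_plc20` (default factor 1.1, SDs scaled
alike).

The parameter-recovery harness frees six well-identified coefficients
(χ₂.K, χ₂.n, χ₃.K, χ₃.n, χ₄.B₀, χ₄.K) against pHSP27/pMLCP/pCofilin tables
over 12 pressures (10–120 mmHg) under control, 0.3 µM H1152 and 3 µM GF —
the clamped conditions anchor the absolute scale of the normalized curves —
with CMA-ES at maxiter 200, sigma0 0.3, population 16, best of 4 seeds.
Zero-noise recovery returns each coefficient to ~1e-7 relative.

## Synthetic data

The generator forward-simulates a ground-truth parameter set over a
pressure grid (default 10–110 mmHg every 20) and the five experimental
conditions, applies the observables' normalizations, then adds independent
Gaussian noise per replicate (default 5 vessels), truncated to physical
ranges ([0, 1] for pLC₂₀, non-negative elsewhere), and emits means and
sample SDs. The noise SD is a fraction (default 0.05) of each observable's
dynamic range across the noiseless table. Pressure-diameter tables support
both vessel groups (distinct load-free radii) via extra `group` /
`R_o_prime_cm` columns.

What this emulates: between-vessel scatter with homoscedastic magnitude,
a common normalization anchor, and the group-size difference. What it does
not: the real laboratory's actual SDs and their pressure dependence,
between-animal correlation, or normalization-induced error correlation
(each row's noise is independent even though real normalized rows share
the control denominator). Passing recovery tests therefore demonstrates
identifiability and correctness of the fitting machinery under the stated
noise model, not performance on the original laboratory data — refitting
those requires the unpublished raw tables, which is out of scope.

## Known limitations

* Steady-state only; the transient integrator is plumbing, not physiology
  (no rate data informed the time constants, which are all 1).
* No mechano-chemical feedback, no ion-channel level Ca²⁺ dynamics, no
  Ca²⁺-wave/MLCP or actin-polymerization/Ca²⁺ couplings.
* One homogeneous wall layer; residual stress reduced to the scalar
  `k_omega`.
* The pLC₂₀ equilibrium near the kinase switching threshold (K ≈ 0.423
  with n ≈ 522) is extremely steep in ξ₀; parameter perturbations there
  change low-pressure predictions sharply.
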