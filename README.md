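# vasotone

Multiscale chemo-mechanical simulation of pressure-induced myogenic tone in
small cerebral arteries.

Small cerebral arteries constrict when luminal pressure rises, stabilizing
cerebral blood flow (autoregulation). `vasotone` models the full chain from
pressure to diameter for researchers in vascular physiology and
computational biomechanics: a logic-based smooth-muscle-cell signalling
network (cytosolic Ca²⁺, ROCK-mediated Ca²⁺ sensitization and PKC-driven
cytoskeleton remodelling) feeds a filament-sliding contractile machinery,
whose active stress enters the inflation equilibrium of an incompressible
thick-walled hyperelastic vessel. The package also ships the
penalty-constrained CMA-ES calibration used to identify the model and a
synthetic-data generator for end-to-end parameter-recovery studies.

## Model core

**Chemistry.** Seven normalized node activities ξ₀…ξ₆ (Ca²⁺, ROCK, pHSP27,
pMLCP, pCofilin, pLC₂₀, G-actin) are coupled through logistic
activation/inhibition edges

χ(ξ) = B₀ + (1 − B₀)(1 + Kⁿ) ξⁿ/(ξⁿ + Kⁿ),  χ(0) = B₀, χ(1) = 1,

combined with fuzzy-logic AND/OR/AND-NOT operators; pLC₂₀ obeys the
kinase/phosphatase balance dξ₅/dt = χ₅(ξ₀)(1 − ξ₅) − (1 − χ₆(ξ₃))ξ₅. The
network is a DAG, so steady states are evaluated in closed form. Chemistry
hands the mechanics the cross-bridge fraction n_XB = ξ₅·n_XBmax and the
F-actin level ξ₇ = 1 − ξ₆.

**Cell mechanics.** Contractile units in series with the actin cortex:
cross-bridge stiffness k_tCB = L_m n_XB k_XB/δ_m, Gaussian filament overlap
L̄_fo(ū_fs), reaction force F_a = (λ_θ − 1 − 2N_CU ū_fs)·k_tCU k_AC/(2k_tCU +
k_AC) and power-stroke driving force F_c = L̄_fo (L_m/δ_m) n_XB k_XB u_PS;
the sliding ū_fs evolves until F_a = F_c.

**Tissue.** Luminal pressure from the radial momentum balance
P = ∫ (λ_θ ∂Ψ/∂λ_θ − λ_r ∂Ψ/∂λ_r) dR/(λ_θ λ_z r) across the wall, with
Ψ = Ψ_p + Ψ_a (neo-Hookean plus circumferential exponential collagen term;
active energy Ψ_a = (N_CF/2)·composite-stiffness·(λ_θ − 1 − 2N_CU ū_fs)²),
incompressible mapping and circumferential pre-stretch k_ω.

At each pressure the solver finds (r_i, ū_fs) satisfying wall equilibrium
and cell-level force balance simultaneously.

## Worked example

Solve the control equilibrium at 80 mmHg with the shipped fitted parameters
(rat middle cerebral artery, vessels group 1):

```console
$ vasotone steady --pressure 80
condition           control
pressure            80 mmHg
inner radius        25.51 um
outer diameter      127.07 um
filament sliding    -0.02538
mean lambda_theta   0.6669
n_XB                0.5358
k_tCU               7.8833e-01 dyne/cm
k_AC                2.5720e-04 dyne/cm
xi0                 0.8182
xi1                 0.2989
...
```

At 80 mmHg the Ca²⁺ and ROCK pathways are strongly engaged (ξ₀ = 0.82,
pLC₂₀ near saturation, n_XB = 0.54 of a 0.55 maximum), the filaments have
slid ~2.5% into contraction and the vessel holds a 127 μm outer diameter —
roughly 60% of the ~210 μm passive diameter at the same pressure, i.e.
pronounced myogenic tone. A pressure sweep shows the autoregulatory
plateau (diameter flat-to-decreasing between 60 and 100 mmHg) and its loss
under Ca²⁺ removal or ROCK inhibition:

```console
$ vasotone sweep --preset control   --pressures 10:120:5 --out control.csv
$ vasotone sweep --preset ca_free   --pressures 10:120:5 --out cafree.csv
$ vasotone sweep --preset h1152_0.3 --pressures 10:120:5 --out h1152.csv
```

(control D_o falls from 145 to 127 μm over 10–120 mmHg; Ca²⁺-free rises
passively from 150 to 217 μm.) Synthetic observables and calibration:

```console
$ vasotone synth --seed 1 --out obs.csv --noise 0.05
$ vasotone fit --stage chemical --data obs.csv \
      --free chemical.chi2.K --free chemical.chi2.n --out fit.json
```

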