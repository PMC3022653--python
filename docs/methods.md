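# Methods

## Model

The package implements a minimal kinetic model of the PKMζ
positive-feedback network in a dendritic spine. Three dimensionless
concentrations evolve by first-order kinetics (time in minutes):
PKMζ protein `P`, the F-actin fraction `F`, and translationally active
PKMζ mRNA `R`:

```
τ₁ dP/dt = j₁ R (1 − P) − P
τ₂ dF/dt = (j₂ + j₃ P)(1 − F) − F
τ₃ dR/dt = j₄ F (P + Stim(t))(M − R) − R
```

Each `jᵢ` is a forward rate relative to the corresponding first-order
decay. The total actin pool (F- plus G-actin) and the total mRNA pool
`M` are conserved; the `(1 − P)` factor caps PKMζ at 1 (biological
resource limitation) without any hard clipping. `Stim(t)` collapses the
upstream Ca²⁺→CaMKII/PKC/MAPK cascade into a single non-negative input
with basal value 0.003; this basal value is applied whenever no stimulus
segment is active, **including during all steady-state and bifurcation
analyses**.

Synaptic strength is read out by an EPSC equation, second order in `P`
because PKMζ stabilizes AMPA receptors through their two GluR2/NSF
sites:

```
τ₄ dE/dt = j₅ (E_UP − E) P²/P_UP² − E + j₆
```

The readout does not feed back on (P, F, R). `P_UP = 0.72` is a fixed
constant of the readout (the default-parameter UP state), deliberately
*not* recomputed when parameters are swept — recomputing it would
silently rescale the EPSC axis during bifurcation scans.

### Parameters

| name | default | meaning |
|---|---|---|
| τ₁ | 1500 min | PKMζ turnover (~1 day degradation, ~10 min translation scale) |
| τ₂ | 0.5 min | actin treadmilling in the spine (tens of seconds) |
| τ₃ | 60 min | mRNA recruitment into the translational machinery |
| τ₄ | 100 min | EPSC relaxation |
| j₁ | 80 | PKMζ synthesis rate / decay rate |
| j₂ | 0.05 | PKMζ-independent actin polymerization / depolymerization |
| j₃ | 0.5 | PKMζ-dependent actin polymerization / depolymerization |
| j₄ | 0.16 | mRNA recruitment / detachment |
| j₅ | 14 | EPSC drive gain |
| j₆ | 0.89 | basal EPSC level |
| Stim_basal | 0.003 | background upstream-kinase activity |
| E_UP | 2 | potentiated EPSC amplitude |
| P_UP | 0.72 | UP-state reference concentration in the readout |
| M | 1 | total PKMζ mRNA pool |

With these defaults the closed-form EPSC fixed point at the UP state is
(j₆ + j₅·E_UP)/(1 + j₅) evaluated at P = P_UP, i.e. **1.926** — the
"potentiated amplitude 2" is this value at display rounding. We
implement the readout literally rather than retuning j₆ to make the
fixed point exactly 2.

### mRNA-pool extension

The recruitment equation generalizes the conserved total from 1 to `M`
via the `(M − R)` factor, the minimal extension in which total mRNA is
conserved and `M = 1` reproduces the base model exactly. A
fractional-occupancy variant `(1 − R/M)` was considered and rejected: it
changes the small-M behaviour qualitatively (the bistable window in `M`
collapses) and has no mechanistic reading as a conserved pool.

## Simulation engine

Protocols are piecewise: square-wave stimulus segments plus timed
perturbations (variable clamps, parameter overrides, removal of the
F-actin decay term). Integration uses `scipy.integrate.solve_ivp`
(LSODA, rtol 1e-8, atol 1e-10) and **restarts at every boundary time**,
so the adaptive stepper never smooths across a discontinuity; all
boundaries are known a priori, so no event detection is needed.

Clamp semantics: during a clamp the variable's ODE is dropped and the
clamped value is what every coupled equation sees; on release,
integration resumes from the clamped value. An exogenous clamp above 1
(PKMζ perfusion, P = 10) therefore releases from 10, after which the
`(1 − P)` term drives `P` back below 1 within a few hundred minutes;
only the final attractor matters for outcomes. "Reactivation" is
modeled purely as a brief P = 0 clamp (an active PKMζ-destruction
process), with no separate mRNA degradation.

Outcomes are classified from the final sample: UP if `P > 0.3` (any
threshold strictly between the saddle, 0.078 at defaults, and the UP
state, 0.724, is equivalent once relaxed), guarded by a relaxation check
`|dP/dt| < 1e-9 min⁻¹` and an ambiguity check that rejects endpoints
sitting on the saddle. The default horizon is 20,000 min (≫ τ₁);
trajectories that decay back from a sizeable excursion — e.g. the weak
stimulus — need more than that to satisfy the relaxation tolerance, so
`run_outcome` doubles the horizon on failure (at most three times, also
used near the switching separatrix where critical slowing sets in).

Time constants set rates only, not equilibria: multiplying τ₁–τ₃ by a
common factor and rescaling the stimulus schedule by the same factor
time-rescales the (P, F, R) trajectory exactly (verified in the test
suite). Note the *outcome* of a fixed-duration pulse is **not**
invariant under scaling the τ's alone — a 30-min pulse that switches the
default network fails to switch a uniformly 10×-slower one — whereas the
equilibria themselves are exactly τ-invariant.

## Equilibria and bifurcation analysis

At fixed `P` the F and R equations are linear with stable closed-form
fixed points:

```
F*(P) = (j₂ + j₃P)/(1 + j₂ + j₃P)
R*(P) = qM/(1 + q),   q = j₄ F*(P) (P + Stim)
```

so every system equilibrium is a root of
`g(p) = j₁ R*(p)(1 − p) − p` on [0, 1] (all equilibria have `p < 1`
because of the `(1 − p)` factor, and `g(0) > 0 > g(1)` at positive basal
stimulus). Equilibrium finding scans `g` on a 10,000-point grid
(configurable), brackets every sign change, and polishes each root with
Brent's method to machine precision. Exhaustive bracketing was chosen
over pseudo-arclength continuation: the reduced problem is scalar, so
bracketing cannot lose branches, and the grid resolves the closest root
pairs near folds before refinement.

Stability is classified by the eigenvalues of the analytic 3×3 Jacobian
of (P, F, R). The sign of `g′(p)` is an independent cross-check (tested
on sweeps): both agree because the (F, R) sub-dynamics are
unconditionally stable at fixed P, so no Hopf bifurcation occurs and
stability is τ-independent.

One-parameter sweeps (default 400 steps) record all equilibria per
value; a saddle-node fold is detected wherever the equilibrium count
changes 1 ↔ 3 and is refined by bisection on the count to an absolute
parameter tolerance of 1e-4 — finer than the rounding of any reference
value. The two-parameter fold curve stacks one-parameter sweeps: each
`j₃` grid value contributes its lower fold to the SN2 branch (where the
UP state is born) and its upper fold to SN1 (where the DOWN state
annihilates); the cusp is located by interval bisection on the `j₃`
value at which the bistable window in `j₂` collapses. At the defaults
this cusp sits near (j₂, j₃) ≈ (0.077, 0.15). Quasi-static hysteresis
sweeps follow, at each parameter step, the stable equilibrium nearest in
`P` to the previously occupied one (the adiabatic limit of a slow ramp).

Stimulus thresholds (smallest 30-min pulse that switches the system UP)
are found by bisection on pulse strength to a relative tolerance of
1e-3, short-circuited by the equilibrium structure: no DOWN state →
threshold 0; no UP state → +∞.

## Reference values and their reproduction

Under the defaults the analysis yields: UP state at P = 0.7244
(EPSC 1.927); saddle-node folds at j₁ = 52.29 and 98.00; j₂ = 0.0646
(single fold in [0, 0.2]); j₄ bistable on [0.1042, 0.1960]; the
stabilizer slice j₃ = 10·j₂ bistable on [0.0300, 0.0621]; and the mRNA
pool bistable on [0.6536, 1.2251]. The reference report for this model
quotes these quantities to two significant figures (53/100, 0.066,
0.10/0.19, 0.031/0.063, 0.67/1.2); our recomputed folds agree with those
figures to within 1–3% but not all to the last printed digit. The
deviations have mixed signs, are insensitive to integrator and grid
settings, and are confirmed by an independent closed-form branch
parametrization (solving `g(p) = 0` for the swept parameter and locating
the extrema of that curve), so they reflect the precision of the quoted
figures rather than a numerical artefact. Setting the steady-state
stimulus to 0 instead of the basal 0.003 makes the agreement much worse
(the upper j₁ fold moves to 131), confirming the basal-stimulus
convention. The nine virtual-experiment outcomes and all qualitative
properties (bistability, hysteresis, monotone strength–duration
boundary, decreasing mRNA–threshold curve) reproduce exactly.

## Problem sizes and determinism

Default analysis sizes — 400-step parameter sweeps over a 10,000-point
root grid, 20,000-min horizons sampled at 1–50 min — were chosen so the
refinement tolerances above, not the grids, limit precision; every
reported quantity is stable under doubling any of them. The tool has no
stochastic component anywhere: repeated runs produce byte-identical
outputs, and TSV writers emit shortest round-trip float representations
to keep outputs regression-diffable.

## Limitations

The model is deliberately minimal: no mass-action expansion of
translation or polymerization, no stochasticity (a single synapse's
molecule counts are small enough that noise-induced state flips are a
real concern not addressed here), no spatial/dendritic structure, no
delay terms, and the entire upstream induction cascade is collapsed into
`Stim(t)`. The EPSC readout is phenomenological. Bifurcation detection
covers saddle-node and cusp structure only — the model exhibits no Hopf
or global bifurcations in the scanned ranges, and none are searched for.
Passing tests demonstrate the dynamical claims about this idealized
network, not quantitative agreement with slice electrophysiology.
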