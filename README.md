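# pkmz-switch

Simulator and bifurcation-analysis suite for the **PKMζ bistable-switch
model** of long-term synaptic memory.

Protein kinase Mζ (PKMζ) is a constitutively active, brain-specific PKC
fragment required for the maintenance of late-phase long-term potentiation
(L-LTP) and of several forms of memory. PKMζ stimulates translation of its
own mRNA — directly, and indirectly by promoting actin polymerization,
with F-actin in turn facilitating local protein synthesis. The convergence
of these two pathways makes the positive feedback loop ultrasensitive, and
ultrasensitive positive feedback can produce **bistability**: a persistently
potentiated (UP) and an unpotentiated (DOWN) state that survive molecular
turnover. This package implements that network as a small ODE model and
provides the tooling to interrogate it: time-course simulation under
arbitrary stimulus/drug protocols, exhaustive equilibrium finding,
saddle-node and cusp bifurcation analysis, and stimulus-threshold scans.

## The model

Three coupled ODEs (concentrations dimensionless, time in minutes),
driven by `Stim(t)`, the aggregate activity of the upstream kinases
(CaMKII, PKC, MAPK; basal value 0.003):

```
τ₁ dP/dt = j₁ R (1 − P) − P                     PKMζ protein
τ₂ dF/dt = (j₂ + j₃ P)(1 − F) − F               F-actin fraction
τ₃ dR/dt = j₄ F (P + Stim(t))(M − R) − R        active PKMζ mRNA
```

with total mRNA pool `M = 1` by default, plus a second-order EPSC readout
of synaptic strength:

```
τ₄ dE/dt = j₅ (E_UP − E) P²/P_UP² − E + j₆
```

Defaults: τ₁=1500, τ₂=0.5, τ₃=60, τ₄=100, j₁=80, j₂=0.05, j₃=0.5,
j₄=0.16, j₅=14, j₆=0.89, E_UP=2, P_UP=0.72.

At a fixed P, the F and R equations have closed-form fixed points, so
every equilibrium of the system is a root of a scalar residual
`g(p) = j₁ R*(p) (1 − p) − p` on [0, 1]. Equilibria are found by
exhaustive sign-change bracketing of `g` (which cannot lose branches),
stability comes from the eigenvalues of the full 3×3 Jacobian, and folds
(saddle-node bifurcations) are refined by bisection on the equilibrium
count. See `docs/methods.md` for the numerical details.

## Worked example

```python
from pkmz_switch import (ModelParams, Protocol, StimSegment, DOWN,
                         find_equilibria, bifurcation_1d)
from pkmz_switch.protocols import run_outcome

params = ModelParams()  # published defaults

for eq in find_equilibria(params):
    print(f"P = {eq.p:.4f}  {eq.stability}")
# P = 0.0053  stable      <- DOWN state (unpotentiated)
# P = 0.0778  unstable    <- saddle separating the basins
# P = 0.7244  stable      <- UP state (potentiated)

# a 30-minute LTP-inducing stimulus from rest potentiates the synapse
pulse = Protocol(stim_segments=(StimSegment(0, 30, 25.0),),
                 t_end=20_000, initial=DOWN)
traj, outcome = run_outcome(pulse, params)
print(outcome, f"P = {traj.p[-1]:.4f}", f"EPSC = {traj.epsc[-1]:.4f}")
# UP P = 0.7244 EPSC = 1.9268

# bistable window of the PKMζ synthesis rate
print(bifurcation_1d("j1", 10, 200, params).fold_points)
# (52.2882080078125, 98.00272623697916)
```

The UP state persists at `P ≈ 0.724` with EPSC `≈ 1.93` (the potentiated
level; the basal level is `j₆ = 0.89`). The two fold points bound the
range of the synthesis rate `j₁` over which the switch is bistable —
outside it, memory cannot be stored (low `j₁`) or is on permanently
(high `j₁`).

The same analyses are available from the shell:

```sh
pkmz-switch steady
pkmz-switch bifurcate --param j1 --min 10 --max 200 --folds folds.json
pkmz-switch protocol --name zip --outcome outcome.json
pkmz-switch reproduce-all --out report.tsv
```

`reproduce-all` recomputes every published scalar plus the nine
virtual-experiment outcomes (ZIP wash-in, exogenous PKMζ perfusion,
protein-synthesis inhibition, actin inhibitors/stabilizer, reactivation)
and writes a computed-vs-printed report.

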