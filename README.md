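# plecswitch

A mechanistic model of the bistable PleC histidine-kinase switch that
drives the swarmer-to-stalked cell transition in *Caulobacter crescentus*.

## The science

*Caulobacter* divides asymmetrically: a sessile stalked cell that
replicates immediately, and a motile swarmer cell that must first
differentiate into a stalked cell. The decision hinges on the bifunctional
histidine kinase PleC — a homodimer that interconverts between a
phosphatase conformation (R) and a kinase conformation (T) in a concerted,
Monod–Wyman–Changeux fashion, with its own response regulator DivK as the
allosteric ligand. Because DivK~P stabilizes the kinase fold more than
unphosphorylated DivK does, and because the kinase fold produces DivK~P
while the phosphatase fold destroys it, the system contains a positive
feedback loop:

```
            DivJ (starter kinase)
              │  phosphorylates
              ▼
  DivK  ⇌  DivK~P ──── binds, stabilizes ───►  PleC (T, kinase)
    ▲                                            │ autophosphorylation +
    │         hydrolysis by PleC (R) ◄───────────┘ phosphotransfer
```

The package builds this loop as a network of elementary reactions (52
species in the full model; a reduced variant lumps rapid binding
intermediates), assigns every species a baseline free energy in units of
RT, and derives all mass-action rate constants through
`kf/kr = exp(−ΔG⁰)`, so the Principle of Detailed Balance holds exactly
around every null cycle — a thermodynamic requirement for any
closed-loop binding/conformational scheme. Rising DivJ then flips the loop
through a saddle-node bifurcation with hysteresis: the model-level
statement of why the swarmer-to-stalked transition is robust and one-way.
Downstream, DivK~P inactivates DivL, DivL promotes the CckA kinase form
(the model's single phenomenological Hill step), and CckA sets the
phosphorylation state of CtrA (the replication-blocking master regulator)
and CpdR.

## Worked example

```python
import numpy as np
from plecswitch import (ModelConfig, Model, find_steady_state,
                        bistable_interval, check_detailed_balance)

cfg = ModelConfig(variant="reduced")
model = Model(cfg.updated("DivJ_tot", 0.0))

# thermodynamic consistency of the derived rate constants
residuals = check_detailed_balance(model.network, model.params)
print(f"null cycles: {len(residuals)}, "
      f"max |log residual|: {max(residuals.values()):.2e}")

# the two cell states
x_sw, _ = find_steady_state(model, model.initial_state("swarmer"))
stalked = Model(cfg.updated("DivJ_tot", 1.2))
x_st, _ = find_steady_state(stalked, stalked.initial_state("stalked"))
for name, m, x in (("swarmer", model, x_sw), ("stalked", stalked, x_st)):
    o = m.observables(x)
    print(f"{name}: PleC kinase {o['pleC_kinase_fraction']:.3f}  "
          f"DivK~P {o['divKp_fraction']:.3f}  CtrA~P {o['ctrAp_fraction']:.3f}")

# the hysteresis window in total DivJ
print("bistable interval:",
      np.round(bistable_interval(cfg, "DivJ_tot", (0.0, 0.6), n=41), 3))
```

prints

```
null cycles: 27, max |log residual|: 3.55e-15
swarmer: PleC kinase 0.148  DivK~P 0.098  CtrA~P 0.562
stalked: PleC kinase 0.986  DivK~P 0.950  CtrA~P 0.000
bistable interval: [0.224 0.243]
```

At zero DivJ, PleC is almost entirely phosphatase, DivK stays
unphosphorylated and CtrA~P is high (the swarmer program: replication
blocked). Above the upper fold the switch is on: PleC is kinase, most DivK
is phosphorylated, DivL is sequestered, and CtrA~P collapses (the stalked
program). Between 0.224 and 0.243 both states coexist and the one you
reach depends on where you came from — hysteresis.

The command line exposes the same pipeline
(`plecswitch sweep`, `plecswitch region`, `plecswitch experiment fig9`,
`plecswitch export --format sbml`, ...); see `plecswitch --help`.

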