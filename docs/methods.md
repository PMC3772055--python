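# Methods

## The model

`plecswitch` implements a mechanistic model of the *Caulobacter crescentus*
swarmer-to-stalked decision circuit. Its core is the bifunctional histidine
kinase PleC, a homodimer that interconverts between a phosphatase
conformation (R) and a kinase conformation (T). The conformational change is
concerted in the Monod–Wyman–Changeux sense: both subunits switch together,
and ligand binding — the response regulator DivK in either phospho-state —
biases the R/T equilibrium rather than gating it. DivK~P stabilizes the
kinase fold more strongly than DivK does; since the kinase fold produces
DivK~P (autophosphorylation followed by phosphotransfer) while the
phosphatase fold destroys it (hydrolysis), this preference closes a positive
feedback loop. The starter kinase DivJ, which phosphorylates DivK directly,
acts as the external lever: raising total DivJ flips the loop from the
phosphatase-dominated (swarmer) state to the kinase-dominated (stalked)
state through a saddle-node bifurcation, and the transition is hysteretic.

Downstream, DivK~P binds and inactivates DivL; active DivL promotes the
kinase form of CckA (modeled phenomenologically with a Hill function — the
single departure from mass action); CckA kinase phosphorylates CtrA and
CpdR through a phosphorelay in which the ChpT transfer protein is lumped
into CckA. CckA phosphatase reverses both. Unphosphorylated CpdR
additionally activates the proteolytic route that degrades CtrA, so the
stalked state suppresses CtrA~P both by dephosphorylation and by turnover.

PleD, the diguanylate cyclase whose phosphorylation triggers stalk
morphogenesis, competes with DivK for the PleC ligand sites in the kinase
conformation; each bound PleD docks onto a phosphorylated His residue and
receives its phosphoryl group from it. Occupancy of both sites by DivK
therefore blocks PleD phosphorylation, which is what makes the steady-state
PleD~P level a non-monotone function of total DivK.

## Species enumeration

The package targets fixed state-space sizes — 52 equations for the full
model, 38 species in the PleC–DivJ–DivK–PleD sub-network, a 28-equation
PleC–DivK core reduced to 20 — and the enumeration realizing them is the
package's own design, built from biochemically conventional states:

* PleC dimer: conformation × site-occupancy multiset × phospho-His count.
  Sites are indistinguishable; each holds `∅`, DivK, DivK~P, or (kinase
  form, given a spare phospho-His) PleD. Phospho-His is carried only by the
  kinase conformation — autophosphorylation is a kinase activity and a
  phosphorylated His is taken to lock the kinase fold, so R states have
  h = 0 and conformational transitions occur at h = 0 only. This gives
  6 R states, 18 DivK-only T states (h = 0, 1, 2) and 7 PleC·PleD
  complexes.
* Core (28): the 24 DivK-only dimer states + DivK, DivK~P, DivJ, DivJ·DivK.
* PleD extension (10): PleD, PleD~P, the active PleD~P dimer, and the 7
  PleC·PleD complexes.
* Downstream (14): DivL with zero, one or two bound DivK~P; CckA in
  phosphatase, kinase and kinase~P forms; four CckA–substrate encounter
  complexes; CtrA, CtrA~P, CpdR, CpdR~P.

The reduced variant lumps away the 8 singly-DivK-occupied dimer states
(rapid-binding limit): double occupancy is reached by direct cooperative
binding steps, and two families of composite reactions preserve fluxes the
lumped intermediates used to carry — termolecular DivK+PleD double binding
to an empty kinase dimer, and ligand exchange `T·L·L + PleD ⇌ T·L·PleD + L`
on fully occupied kinase dimers (the composite of unbinding and rebinding
through the deleted intermediate). The exchange step carries its own
kinetic scale (`exch_pd`, default 0.05), set to reproduce the full model's
door-limited PleD flux.

## Thermodynamic layer

All energies are in units of RT (RT = 1). Every species receives a baseline
free energy assembled additively from: the kinase-fold penalty `e_conf_T`,
per-phospho-group energies (`e_hisP`, `a_dkp`, `a_pdp`), conformation- and
ligand-specific site binding energies (`b_RK`, `b_RP`, `b_TK`, `b_TP`,
`b_TD`), a cooperativity penalty `e_coop` on singly-DivK-occupied dimers,
and a configurational-entropy term −ln g for the degeneracy of mixed site
occupancies. Reversible reactions get `kf = scale × multiplicity` and
`kr = kf·exp(ΔG⁰)` with ΔG⁰ the difference of species energies, so
`kf/kr = exp(−ΔG⁰)` and the Wegscheider (detailed-balance) condition holds
identically around every null cycle. ATP-driven steps (His
autophosphorylation, the DivJ transfer), phosphate-releasing hydrolyses,
synthesis/degradation and the phenomenological Hill step are irreversible
and excluded from cycle analysis.

`check_detailed_balance` recomputes the cycle basis on the *active*
reversible sub-network: reactions with kf = kr = 0 (mutant knockouts) are
treated as absent, while a reaction with exactly one zero rate on a cycle
raises.

`boltzmann_distribution` is the equilibrium oracle for closed sub-networks.
Because binding reactions are bimolecular, the equilibrium is not simply
∝ exp(−E); it is the free-energy minimum subject to the network's conserved
quantities, solved in dual form `x_i = exp(−E_i + Σ_m λ_m w_mi)` with one
multiplier per conservation law. Constraints come either from moiety totals
or, when the moiety tags do not resolve every conserved quantity (in a
binding-only network DivK and DivK~P are separately conserved), from a
reference state through the exact left null space. For unimolecular subsets
this reduces to Boltzmann weights normalized within the moiety. Long-time
integration of the closed PleC–DivK binding/conformational module
reproduces this distribution to better than 1e−6 relative — a strong joint
test of the energy table, the rate derivation, and the integrator.

## Baseline parameters

The default energies and kinetic scales are the package's own calibration,
chosen once so that the wild-type model expresses the qualitative
repertoire the system is known for, and not tuned to any numeric target.
The operating point:

| parameter | value | meaning |
|---|---|---|
| `e_conf_T` | 5.3 | kinase-fold penalty; sets the phosphatase as the deep default |
| `b_RK` / `b_TK` | +1.8 / −0.8 | DivK binds the phosphatase weakly and the kinase moderately: a per-site allosteric gap of 2.6 RT, enough for 8–20× DivK over-expression to lock the kinase form, small enough that baseline DivK leaves ≲10 % kinase |
| `b_RP` / `b_TP` | −1.5 / −5.7 | DivK~P is the potent inducer (preference gap 1.6 RT beyond DivK's); weak phosphatase-side binding keeps the doubly-occupied hydrolyzing R state rare, which is what preserves the kinase-locked conformation of autokinase-dead PleC |
| `b_TD` | −5.5 | PleD docking; competitive with DivK~P at stalked-state free concentrations |
| `e_coop` | 1.5 | binding cooperativity; concentrates dimers on empty/doubly states, keeping the reduced variant close to the full one |
| `k_auto` / `k_hyd_his` | 0.65 / 0.55 | slow autophosphorylation with comparable spontaneous phospho-His hydrolysis: the kinase's phospho-state tracks, rather than overwhelms, the conformational equilibrium |
| `k_hyd` | 20 | fast hydrolysis of bound DivK~P by the phosphatase form; its saturation supplies the zero-order sharpness of the switch |
| `k_trans_j` | 2.5 | DivJ phosphotransfer; sets the DivJ scale of the fold positions |
| `k_syn_dk` / `k_deg_dk` | 0.015 / 0.01 | DivK turnover (free molecules only); the synthesis constant is the second axis of the two-parameter region |
| `hill_K`, `hill_n`, `hill_vmax` | 0.1, 2, 1 | DivL→CckA activation; n = 2 as a mild-cooperativity default |

Concentrations are dimensionless with total PleC = 1; time is in units of
the inverse basal catalytic rate. Two structural features were found to be
*required* for a functioning switch and are part of the model proper:
spontaneous phospho-His hydrolysis (without it, irreversible
autophosphorylation traps all PleC in the kinase states regardless of
thermodynamics — phospho-His lability restores the conformational exit),
and the reduced-variant exchange reactions described above.

Under these defaults the reduced model's bistable interval in total DivJ is
≈ (0.224, 0.243) and the full model's ≈ (0.238, 0.354); the two-parameter
region over (DivJ_tot, k_syn_dk) opens near k_syn_dk ≈ 0.01 and closes
again between 0.05 and 0.3 (crescent shape, tapering at both extremes);
10× DivK synthesis locks the kinase fraction above 0.4 with no DivJ at all.

## Numerical choices

* Integration: LSODA with the analytic mass-action Jacobian, rtol 1e−8,
  atol 1e−12. A hard budget on rhs evaluations converts pathological
  stiffness into a caught error instead of a stall; the caller then falls
  back to a Newton polish or re-seeds.
* Steady states: staged integration (t = 50, 250, 1250, …) until the
  max-norm derivative is below 1e−6, then damped Newton to ‖f‖∞ < 1e−10.
  The Newton residual replaces one row per conserved moiety with the
  conservation constraint, which removes the structural singularity of the
  Jacobian. The Jacobian is analytic (including the Hill term); stability
  is judged from eigenvalues after projecting out the conservation
  directions.
* Negative concentrations: clipped silently below 1e−12, with a logged
  warning up to 1e−9, an error beyond.
* Continuation: natural parameter sweeping with Newton-polish seeding and
  integration fallback, from the swarmer-like start (ascending) and the
  stalked-like start (descending). Unstable branches are not continued;
  the analysis targets stable branches and fold positions. Bistable
  intervals are the parameter sets where the two sweeps disagree by more
  than 1e−4 in PleC kinase fraction, with endpoints refined by bisection to
  relative 1e−4 (the bisection bracket midpoint is returned, so normal-form
  folds are located to ≈ 6e−5).
* The scalar normal-form solver marches in the flow direction with a fixed
  0.01 step and bisects on a sign change — time flow cannot converge onto
  an unstable root, which makes branch tracking basin-faithful by
  construction.
* The two-parameter region is a grid of bistable intervals over the second
  parameter with bisection refinement of the projection bounds.

## Mutants

Genotypes are parameter transformations of the configuration; energy-level
edits re-derive every rate constant from the modified energy table, so
detailed balance is preserved by construction (and re-verified after every
transformation). `divK_D90G` sets the kinase-form binding energies equal to
their phosphatase-form values (binding no longer biases the fold) and
weakens DivL binding 100-fold; `divK_X` is the same without the DivL edit;
`divK_D53N` zeroes all DivK phosphotransfer rates; `pleC_F778L` zeroes
autophosphorylation only; `pleC_Tn5` and `delta_divJ` zero the respective
totals. "Stalked-cell DivJ level" for phenotype panels is DivJ_tot = 1.2
(above the upper fold); "swarmer level" is 0.

The DivK-titration experiment (steady-state PleD~P against total DivK)
sweeps the DivK synthesis constant, since the model's knob is synthesis
while the observable axis is the resulting steady-state total. The
wild-type panel runs at a basal DivJ_tot of 0.02: the experiment it
emulates is an in-vitro titration essentially without DivJ, and at DivJ
levels ≳ 0.05 the ON branch accumulates protected bound DivK~P (degradation
acts on free molecules only), so low total-DivK values are unreachable and
the interior maximum disappears. That accumulation — totals that grow on
the ON branch because complexes are shielded from turnover — is a real
feature of the free-protein-only degradation rule and a known limitation of
this calibration.

## What the reduction does and does not preserve

Full and reduced variants agree on fraction-valued branch observables to
better than 0.05 absolute on the deep branches (DivJ_tot = 0, and anywhere
above the upper fold), and their folds sit in the same neighborhood
(0.224/0.238 lower, 0.243/0.354 upper). In the steep pre-fold approach the
pointwise difference reaches ≈ 0.16, because the singly-occupied
intermediates that the reduction deletes stabilize the kinase fold by only
one site's worth of binding energy, flattening the full model's rise. A
blanket "5 % everywhere" agreement is not attainable for any lumping of
this kind near a fold whose position itself shifts; comparisons should be
made branch-wise, away from the fold neighborhood.

## What the synthetic ensembles emulate

The sampler draws free energies uniformly and kinetic scales log-uniformly
within declared intervals and derives all rates through the energy table,
so every sample is thermodynamically consistent by construction — this is
the structure the analysis assumes of any admissible parameterization, and
it stands in for external data (there is none; the model's inputs are
parameters). The robustness scan perturbs the baseline the same way and
reports the fraction of 2-fold-perturbed sets that remain bistable. A
passing scan shows the *mechanism* is not a knife-edge of the calibration;
it says nothing about agreement with wet-lab kinetics, which the package
does not attempt to fit.

## Known limitations

* No spatial structure: polar localization, compartmentalization and
  diffusion are outside scope; the model is a well-stirred snapshot of one
  pole's chemistry.
* c-di-GMP is not an explicit species; PleD~P (and its dimer) is the
  terminal readout, and product inhibition of PleD is not modeled.
* ChpT is lumped into CckA; CckA's two-domain relay is a single His~P pool.
* The ON-branch accumulation of bound DivK~P under free-only degradation
  inflates total DivK on the upper branch; figure-level experiments that
  need low totals must be run at near-zero DivJ.
* The calibration is qualitative. Externally determined parameter values,
  when available, can be imported from `.ode` files via `parse_ode_file` /
  `apply_ode_parameters` to replace the defaults for quantitative work.
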