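# Methods

## The model

`bh3sim` simulates the commitment step of intrinsic apoptosis — mitochondrial
outer membrane permeabilization (MOMP) — in B-cell lymphoma cells, as a
deterministic mass-action reaction network of the BCL2 protein family.

The network tracks three functional groups at two locations (cytosol and the
mitochondrial outer membrane, MOM):

* **Effectors** BAX and BAK. Both are synthesised into the cytosol; BAX
  shuttles reversibly between cytosol and MOM (and is mostly cytosolic at
  rest), BAK inserts effectively one-way. Membrane effectors are activated
  catalytically by membrane-resident direct activators, and
  autocatalytically by already-active effectors. Active effectors dimerise,
  and two dimers form a tetramer, which the model treats as the
  membrane pore. The **MOMP signal** is the summed pore concentration
  (BAX tetramer + BAK tetramer); everything downstream of MOMP (caspase
  activation, PARP cleavage) is considered inevitable and is not modelled.
* **Anti-apoptotic guardians** BCL2, BCL-xL, MCL1 and BCL2A1, which traffic
  between cytosol and MOM and neutralise the pro-apoptotic machinery in
  three binding modes: sequestration of BH3-only proteins (at the MOM and,
  more weakly, in the cytosol), sequestration of *active* effectors
  (selectively: BCL2/BCL-xL/BCL2A1 hold active BAX; BCL-xL/MCL1 hold active
  BAK), and a retrotranslocation mode in which any guardian captures an
  *inactive* membrane effector and extracts it from the membrane (modelled
  as capture followed by first-order turnover of the captured effector with
  recycling of the guardian — so guardian abundance sets the clearance rate
  of membrane effectors, and no unbinding reservoir accumulates).
* **BH3-only proteins** BID, BIM and PUMA (direct activators) and NOXA (a
  sensitizer that binds only MCL1 and BCL2A1). A constant lumped
  "apoptotic signaling" input species catalyses their mobilisation to the
  MOM, standing in for upstream death-receptor/stress signaling.

BH3-mimetic drugs are explicit species: one high-affinity competitive
groove binder per guardian (effective dissociation constant 1e-4 a.u.,
orders of magnitude below protein abundances) that binds both the cytosolic
and membrane form of its target.

All kinetics are elementary mass action. The canonical network has **80
species, 202 reactions and 203 parameters** (one rate constant per reaction
plus the clamped apoptotic-signal level). It is defined programmatically
and round-trips through a four-file CSV dialect (`species.csv`,
`reactions.csv`, `ratelaws.csv`, `parameters.csv`).

### Units and default rates

Concentrations are in arbitrary abundance units (a.u.); the most abundant
anti-apoptotic protein of a fitted line is anchored at 300 a.u. Time is in
hours. Defaults: protein turnover 0.05/h (≈14 h half-life), oligomer
turnover 0.25/h, MOM heterodimer association 0.5 a.u.⁻¹h⁻¹ with
dissociation 0.1/h for activators and 0.5/h for NOXA, active-effector
sequestration 0.5/0.02, activator-catalysed effector activation
0.1 a.u.⁻¹h⁻¹, autocatalysis 0.12 a.u.⁻¹h⁻¹, dimerisation 0.5 and
tetramerisation 2.0 a.u.⁻¹h⁻¹, retrotranslocation capture 0.005 a.u.⁻¹h⁻¹
with 0.1/h turnover. These rates were chosen once so that (i) naive
(untreated) populations are dynamically stable over ≥82 h, (ii) inhibiting
the guardian that holds most of a line's pro-apoptotic load drives the MOMP
signal up by one to four orders of magnitude, and (iii) inhibiting a
guardian with a minor share moves it by well under the death-threshold
margin. The two-step oligomerisation makes the pore signal roughly
fourth-order in free active effector, which is what produces the sharp
naive/committed separation.

## Integration and steady states

The network compiles to index arrays; right-hand side and analytic Jacobian
are evaluated in vectorised NumPy. Trajectories use `scipy.solve_ivp` with
LSODA (relative tolerance 1e-6, absolute 1e-9) and a BDF retry on the rare
sharp permeabilization transients where LSODA aborts. Pre-treatment steady
states are found by run-to-convergence integration in geometrically growing
chunks until `max |dx/dt| / max(|x|, 1) < 1e-8`; root-finding was
deliberately avoided so that the *reachable, stable* branch is always
returned (several parameterisations are bistable). Steady-state evaluations
inside the fitting loop always start from the same cold initial condition
for the same reason: warm-started continuation can silently hop branches.

## Virtual cell lines

A line is parameterised from two semi-quantitative measurements: total
abundance of each family protein normalised to the most abundant guardian
(IP densitometry), and the fraction of each partner bound to each guardian
(co-IP densitometry). Proteins undetected in a line are pruned from the
network together with every species and reaction that involves them.

The free parameters per line are the ten protein synthesis rates and one
efflux rate per MOM heterodimer (19 pairs), the latter representing
translocation of heterodimeric complexes out of the modelled compartment.
The fit minimises squared log-ratio error on normalised abundances plus
squared absolute error on bound fractions at steady state, with a gauge
anchor pinning the top guardian to 300 a.u. A damped multiplicative
fixed-point pass (synthesis rates scaled toward abundance targets, efflux
rates toward bound-fraction targets) warm-starts a bounded trust-region
least-squares polish in log space; seeded random restarts run only if the
objective stays above a ceiling. On noiseless synthetic profiles the fit
recovers normalised abundances to well under 5% and bound fractions to
under 0.05 (median).

Genetic lesions are named multiplicative rate modifiers applied on top of a
fitted line (defaults: MYC translocation ×2 BAX/BIM synthesis, BCL2
amplification ×2 BCL2 synthesis, TP53 mutation ×0.5 MCL1 synthesis, p300
truncation ×2 MCL1 degradation); magnitudes are configurable study
parameters, only the directions are biology.

## Heterogeneous populations and the death criterion

A population (default 100 cells) is sampled by scaling every protein's
total abundance in the fitted steady state by an independent lognormal
factor with mean 1 and CV 0.32; a species is scaled once per *distinct*
constituent so complexes co-vary with their members and each monomer total
scales exactly by its factor. A 10 h drug-free pre-run re-equilibrates
complexes before the treatment clock starts.

Treatment adds the drug species for each target at a total amount
calibrated by bisection so that the requested fraction of the target
protein is drug-bound at the mean cell's post-drug steady state (full
inhibition is calibrated to the 99.95% practical ceiling of a reversible
binder). A cell dies at the first time its MOMP signal reaches
`threshold_factor` (default 1.10) times the naive baseline, linearly
interpolated on a 0.1 h output grid. The baseline statistic is the
**maximum** MOMP level present across the naive population at treatment
start (the `mean` and `per_cell` alternatives are switchable): with 32%
per-protein variability the naive pore-level spread across cells far
exceeds 10%, so a mean-referenced threshold would score the upper tail of
an *untreated* population as dead, while the max-referenced threshold makes
a stable untreated population 100% viable by construction and is crossed
only by genuinely treatment-driven excursions. Viability at 72 h is the
fraction of cells that never cross.

Dose–response grids run 10 equally spaced inhibition fractions (0…1) on one
shared population sample (common random numbers), which makes the grid
monotone up to dynamics rather than sampling noise. Survivor-vs-dying
contrasts compare pre-treatment states per species (plus derived pro-/
anti-apoptotic load aggregates) with two-sided Mann-Whitney tests and
Benjamini-Hochberg adjustment.

## Synergy

Combination matrices run every pair of inhibition fractions (default 5×5
including the zero margins) on one shared population. Effect is
`1 − viability`; the Bliss-independent expectation of the single-agent
margins is `e_a + e_b − e_a·e_b`; the excess is reported in percentage
points and the summary score averages the excess over cells where both
doses are nonzero, so single agents cannot contribute.

## Synthetic ground truths

Because the real densitometry inputs are external, every pipeline stage is
tested against seeded synthetic lines. The generator draws synthesis rates
log-uniformly from per-archetype ranges and efflux rates from 1e-3–0.2/h,
then **poise-calibrates** each draw: a bisection on a common multiplier of
the direct-activator synthesis rates pins the naive MOMP baseline to a
target level (0.25 a.u. for dependent archetypes — primed but uncommitted;
1e-5 for broadly resistant — unprimed). Draws are rejected until the
archetype invariant holds on the realised steady state:

* *dependent* archetypes: the dominant guardian holds ≥50% of the bound
  activator/effector load, a designated secondary guardian (MCL1, or BCL-xL
  for MCL1-dependent lines) holds 7.5–10%, and every other guardian holds at
  most half the secondary share. The secondary band is the regime in which
  full inhibition of the secondary target kills an intermediate fraction of
  the population at death-threshold factors anywhere in 1.05–1.20 — the
  graded high-dose second vulnerability that the annotated dependence
  categories show;
* *broadly resistant*: no guardian holds ≥40%.

A named co-dependence fixture complements the archetypes: a BAX-driven line
buffered by large BCL2/BCL2A1 pools in which BCL-xL and MCL1 — the only two
guardians able to sequester active BAK — each hold a small share. Either
alone absorbs the BAK load freed by inhibiting the other; inhibiting both
leaves BAK unguarded, so the combination kills far in excess of Bliss
independence. Its comparator is a BCL2-dependent line generated on a
BAK-pruned network, where the pair's joint function does not exist and the
summary score collapses to ≈0.

Synthetic densitometry applies multiplicative lognormal noise to
abundances, additive clipped noise to co-IP fractions, and a detection
limit below which proteins are reported undetected; the noiseless model
reproduces the exact steady-state summary.

### What the synthetic data do not emulate

Fixture archetypes reproduce the *qualitative* response patterns of
published dependence categories, not any real line's numbers. The noise
model is an assumption (densitometry error structure is unknown), antibody
cross-reactivity and IP efficiency differences are not represented, and
cell-to-cell variability enters only through initial conditions — protein
synthesis rates are shared within a population, so sampled heterogeneity
decays on protein-lifetime timescales (fast for membrane effectors, whose
totals are slaved to guardian-mediated clearance). Passing tests therefore
demonstrate internal consistency and qualitative fidelity of the pipeline,
not quantitative prediction for real cell lines.

## Known limitations

* A broadly resistant archetype that survives *full* inhibition of any
  single guardian is not attainable in this model: under the relative
  (1.10×) death threshold and the steep pore response, complete inhibition
  of any guardian holding more than roughly a tenth of the bound load
  raises the MOMP signal past the naive spread in nearly every cell. Lines
  lacking any response to all single BH3-mimetics presumably rely on
  mechanisms outside this network (e.g. additional buffering compartments);
  the resistant archetype here is resistant in the sense of an unprimed,
  spread-load state, and the co-dependence fixture covers the
  combination-only-response phenotype.
* The max-referenced death threshold is an extreme statistic of the naive
  sample: its expectation grows slowly with population size, so the
  viability of a *threshold-straddling* target drifts upward when much
  larger populations are simulated. Comparisons across targets, doses and
  threshold factors at a fixed population size (the supported analyses) are
  unaffected; cross-size comparisons should either match n or fix a common
  threshold. This trade-off is inherent: a mean-referenced 1.10× threshold
  would instead mark the upper tail of an untreated population dead at
  time zero.
* Fractional occupancy is the dose variable; no pharmacokinetic mapping to
  molar drug concentrations or real EC50 values is attempted.
* The exact species list of the published 80/202/203 network is not public;
  this enumeration is a reconstruction constrained to those counts and the
  documented interaction map, and the MOMP readout (summed pore
  concentration) is one of several defensible choices.

## Problem sizes used in the shipped checks

Populations of 24–50 cells, 5×5 combination grids at 30 cells, and 20
ground-truth refits are used in the test suite and acceptance script;
population-level results at 100 cells (the default) agree within binomial
error but cost proportionally more CPU.
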