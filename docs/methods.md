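# Methods

## Scope and model

`agmacap` predicts the *agmatine production capacity* of a gut microbial
community: the maximal rate (mmol per gram microbiota per day, mmol/gM/d)
at which the community can secrete agmatine — the decarboxylation product
of arginine — given the diet available to it.  Around that core it
implements the steps a cohort-scale analysis needs: homology-guided
refinement of strain reconstructions, conversion of food-frequency
records into exchange-flux diets, community assembly from relative
abundances, in-silico supplementation screens, group comparison, and the
statistics of a drug x nutrient plate screen read out in bacterial
growth and a host reporter.

All fluxes use mmol/gM/d rather than the conventional
mmol/gDW/h: dietary intake is normalized to the amount available per
gram of colonic microbiota (assumed total mass 200 g) per day, and the
steady-state balance propagates that unit to every reaction.

## Flux balance analysis with a total-flux penalty

A network with stoichiometric matrix S and flux bounds lb ≤ v ≤ ub is
solved at steady state (S·v = 0).  The capacity objective is

    maximize  v_target − ε · Σ_j |v_j| ,      ε = 10⁻⁶

so the target outflow dominates while the tiny penalty suppresses
futile cycles and yields a parsimonious flux distribution.  |v_j| is
linearized with epigraph variables t_j ≥ v_j, t_j ≥ −v_j; because each
t_j carries positive cost the optimizer pins t_j = |v_j| without a
complementarity constraint.  This is algebraically equivalent to
splitting each flux into directional halves, but it also handles
reactions with strictly positive lower bounds (the community biomass
floor) without special cases.  All reactions, exchanges included, enter
the penalty by default (`penalize_exchanges=False` is available for
sensitivity analysis).

LPs are solved with HiGHS through `scipy.optimize.linprog` on a
sparse constraint matrix.  Variables are id-sorted, so repeated solves
return the identical vertex.  Tolerances: feasibility 10⁻⁹, steady
state checked to 10⁻⁶.  Only the objective value is contractual;
alternate optima may differ in individual fluxes, so per-reaction
fluxes (and hence side-product yields and species attributions) are
reported from the penalized optimum and inherit its tie-breaking.
The independent cross-check in the tests solves the same LPs with
cobrapy/GLPK (a different solver and, for the penalized objective, a
different linearization — directional splitting).

The sign convention is fixed once: an exchange reaction touches exactly
one metabolite with coefficient −1; negative flux is uptake, positive
is secretion.  Unannotated reversible reactions default to
[−1000, 1000] mmol/gM/d, irreversible ones to [0, 1000].

## Strain-model refinement

Draft gut reconstructions usually lack agmatine transport and the
extracellular arm of arginine decarboxylation.  From homology-hit
tables (12-column BLAST tabular output) the refinement adds:

* a reversible agmatine transporter for strains with a transporter-query
  hit at bitscore strictly above 50 and query coverage ≥ 75 %;
* an extracellular arginine-decarboxylase reaction (`ARGDC_EXT`,
  extracellular arginine → agmatine + CO₂) for strains with a speA
  homolog at bitscore strictly above 200, with stoichiometry copied
  from the strain's cytosolic `ARGDC` template (canonical stoichiometry
  with a warning when the template is absent);
* an irreversible agmatine outflow for every strain that received
  either.

Threshold strictness (">" at 50 and 200, "≥" at 75 %) follows the
stated cut-offs read literally; all three are parameters.  Transporters
are added reversible — the outflow reaction supplies directionality.
Refinement is additive and idempotent: it never deletes reactions or
alters existing bounds.  Screens then flag growth (max biomass ≥ 0.01
mmol/gM/d on the diet, inclusive) and production (max agmatine outflow
> 0).  The report keeps separate denominators for the growth screen and
the producer screen rather than conflating them.

## Participant diets

Pipeline order: compound mapping and mass→flux conversion → nucleotide
augmentation → polyamine augmentation → caloric normalization →
reference blending → (optional) absorption adjustment.  All steps are
linear and preserve non-negativity; a provenance log records totals
after each step.  Since the conversion steps are all scalings, their
order affects absolute fluxes but not capacity ratios; the implemented
order is fixed and logged so results are auditable.

* **mass→flux**: grams/day ÷ molecular weight × 1000 ÷ 200 g
  microbiota = mmol/gM/d.
* **Nucleotides**: purine classes come from per-food content tables
  (group-average imputed along the food hierarchy when an item is
  unmeasured — nearest group first); each class is split 50/50 across
  its ribo/deoxyribo species.  Pyrimidines are extrapolated from
  purines: thymidine + uracil together equal the adenosine class
  (50/50 split by default, configurable) and cytosine equals the
  guanosine class.
* **Polyamines**: cadaverine, putrescine, spermidine, spermine from
  content tables; ornithine taken as measured when available, otherwise
  extrapolated as 3.28 × the item's total polyamine content (the median
  ornithine:polyamine ratio of foods with complete data).
* **Caloric normalization** to 8799 kJ/day (the cohort median),
  multiplicative on every amount.  Augmented trace compounds are
  treated as calorically negligible.
* **Blending**: 90 % participant diet + 10 % reference ("Western")
  diet, except phosphate, copper, manganese, zinc, iron(III) and
  chloride, which keep the reference value outright — these minerals
  strongly limit growth of individual strains and food-frequency data
  under-reports them.  The reference diet is an input file and the
  fractions are parameters.
* **Absorption**: each compound optionally discounted by its
  small-intestinal absorbed fraction, amount × (1 − f).

A missing molecular weight is a hard error: silently dropping a
compound would bias the nitrogen supply that the capacity prediction is
most sensitive to.

## Community assembly

Relative abundances are filtered at a detection cutoff — ≥ 0.1 % for
16S amplicon profiles, ≥ 0.01 % for shotgun metagenomes — and
renormalized to sum to one.  Member models are strain-tagged and joined
through a shared lumen compartment `u`:

* member exchange reactions become reversible transports between the
  member's extracellular compartment and the lumen, so members
  cross-feed through the lumen but cannot bypass the dietary boundary;
* one fresh community exchange `EX_<met>_u` per lumen metabolite; the
  diet constrains only these;
* member biomass outflows are blocked ([0, 0]) and a community biomass
  reaction consumes each member's biomass metabolite with coefficient
  −f_k (its abundance fraction), enforcing the observed composition;
  community biomass flux is bounded to [0.4, 1.0]/day by default (about
  one gut turnover; configurable — several tests open it to [0, 1000]
  so the growth floor does not mask what they probe);
* coupling constraints −c·v_bio,k − u ≤ v_j ≤ c·v_bio,k + u for every
  reaction j of member k tie flux magnitudes to that member's biomass
  production, so a low-abundance taxon cannot act as an unbounded
  enzyme bag.  Defaults c = 400, u = 0.01 follow the community-modeling
  literature this construction comes from; both are parameters and are
  recorded on the model.

## Capacity, attribution, supplementation, comparison

Capacity is the penalized-FBA optimum of the community agmatine
exchange.  Species contributions are each member's net export of
agmatine into the lumen, summed over strains of a species; at steady
state they total the capacity (checked to 10⁻⁶).  Side products are
community-level secretions (not member-lumen transports) per mole of
agmatine.  Supplementation relaxes one exchange lower bound additively
(−1 mmol/gM/d by default for communities; +5 mmol/L for the
single-strain growth-medium screen) and reports the capacity ratio;
monotonicity (ratio ≥ 1) is asserted on every run because adding
uptake can never reduce an LP maximum.  Group differences use pairwise
two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment
across pairs; tie handling follows `scipy.stats.mannwhitneyu`'s
automatic policy (exact for small tie-free samples, otherwise the
normal approximation with tie correction).

## Screen statistics

Growth is summarized as log₂ of the trapezoidal area under the OD
curve; no smoothing.  The host reporter is summarized per well as the
90th percentile of log₂ per-worm intensities (linear-interpolation
quantile, configurable) — a robust maximum for a wide, non-normal
intensity distribution.  Per nutrient, a two-factor linear model with
interaction is fitted on log₂ responses over the 2×2 cells
{nutrient} × {drug}, with the no-nutrient cells shared across nutrients
as on a real plate.  Interaction p-values are BH-adjusted across
nutrients; a significant positive interaction (nutrient suppresses the
drug effect) is called antagonistic, a negative one synergistic.

The residual variance is pooled across the nutrient models of a plate
by default: all wells share one measurement process, and with only
4 cells × 4 replicates a per-nutrient variance estimate (12 residual
degrees of freedom) is itself the dominant noise source — pooling is
the standard screen-analysis remedy and is valid under the
homoscedasticity the design implies.  `pool_variance=False` restores
fully independent per-nutrient fits (cross-checked against statsmodels
OLS in the tests).  Replicates enter as fixed effects; a random-effect
formulation per plate would be the natural extension but is not
implemented.  Class enrichment of hit sets uses the upper-tail
hypergeometric test with BH across classes.

## Synthetic data: what it does and does not emulate

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes — fidelity is structural,
not biochemical:

* **Strain panel**: producers carry arginine uptake → cytosolic
  decarboxylase → agmatine export over a glucose-fueled biomass core,
  with per-strain intrinsic caps; non-producers have only the core.
  A nitrogen-gated family makes maximal agmatine proportional to the
  transferable nitrogen atoms of the fed compound (agmatine carries
  four N), producing discrete capacity steps, with a carbon-only
  "sugar" control; a cross-feeding pair (arginine secretor + converter)
  is productive only jointly.
* **Cohort**: Dirichlet-distributed profiles; the treated group's
  producer concentration parameters are multiplied by the effect size
  (3 by default, n = 30 per group), so treated communities carry more
  producer biomass; effect size 1 makes groups exchangeable.  The
  cohort pipeline runs the toy communities at coupling c = 10, where
  the coupling bound c·f_k·v_bio is the binding constraint and capacity
  is proportional to aggregate producer abundance — the mechanism by
  which the planted abundance contrast reaches the capacity readout.
  (The c = 400 default remains for realistically sized models.)
* **FFQ**: five foods in a two-level hierarchy, a compound map with
  molecular weights and caloric densities, purine/polyamine tables with
  deliberate gaps (beer's purines; ornithine everywhere but beef) to
  exercise imputation and extrapolation, and a reference diet.
* **Screen**: logistic growth OD(t) = K/(1+e^(−r(t−t₀))) with K
  modulated on the log₂ scale by drug (−1), nutrient and planted
  interaction effects (+1 log₂ on 30 of 337 nutrients by default);
  per-worm log₂ intensities normal with a drug upshift that planted
  nutrients suppress; and a direct long-format response table
  (σ = 0.2, n = 4) for the null/power simulations of the interaction
  models.

One master seed feeds fixed-label substreams per generator, so adding a
generator never perturbs another's stream.

Passing tests on these data therefore demonstrate correctness of the
algebra, the LP formulation, the estimators and their error control —
not biochemical realism: real reconstructions have thousands of
reactions, real diets hundreds of compounds, real abundance profiles
heavier tails, and real plate data edge effects and batch structure
that the generators do not model.

## Problem sizes in the default runs

The test suite and the acceptance script run at desk scale by design:
50 random networks of ≤ 8 reactions for oracle equivalence, 20 random
communities for conservation, 200 supplementation triples, 100 seeded
cohort runs per arm (10 strains, 30 participants per group), 100 screen
seeds at the full 337-nutrient width, and the complete enumeration of
hypergeometric cases up to universe size 25.

## Known limitations

* Alternate LP optima: only objective values are reproducible across
  solvers; flux-level outputs are vertex-dependent.
* Side-product yields and species attributions are taken from the same
  penalized optimum, not from a secondary optimization.
* No flux-variability analysis, gene–protein–reaction logic,
  thermodynamic constraints or dynamic FBA.
* The coupling constants and community biomass bounds are
  literature-convention defaults, not fitted values; capacity can be
  sensitive to both (they are parameters and are logged with results).
* 16S-to-strain assignment, read processing and differential-abundance
  testing of taxa are upstream of this package; profiles arrive
  pre-mapped.
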