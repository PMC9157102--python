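# Methods

## The model

The package models a split CRISPR homing suppression drive inserted in a
haplosufficient female-fertility gene, with Cas9 supplied from an
unlinked, fixed locus.  The population is an infinite-population (or, in
the simulators, finite multinomial) genotype-frequency distribution over
two unlinked loci — drive locus alleles {wt, drive, r1, r2}, off-target
locus {intact, disrupted} — and sex: 10 × 3 × 2 = 60 states.  Allele
pairs are unordered; the canonical ordering (wt < drive < r1 < r2, intact
< disrupted, females first) fixes serialization and test stability.

Generations are discrete and non-overlapping (the experimental design the
model mirrors ran on a 12-day cycle) with sexes produced 1:1.  A
generation consists of:

1. **Sterility.**  Females whose drive locus carries no wt or r1 allele
   do not reproduce.  The rule is female-specific; males are unaffected.
2. **Parental weighting.**  Fertile females are weighted by their
   fecundity multiplier, males by mating success (random mate choice
   proportional to frequency × mating success).
3. **Germline.**  In drive/wt heterozygotes with Cas9, drive conversion
   and germline resistance formation are *competing events applied
   simultaneously* to the wt allele: it becomes a drive allele with
   probability c (sex-specific), r1 with ρ·g, r2 with (1−ρ)·g, and stays
   wt with 1 − c − g.  With the default c = 0.767 and g = 0.222 only 1.1%
   of heterozygous-germline wt alleles survive, consistent with germline
   cutting being nearly complete.  The alternative reading (resistance
   applied only to the non-converted residue) would leave ~18% wt and is
   not used.  Intact off-target alleles in any Cas9-bearing drive carrier
   are disrupted at rate q (default 1) in the germline only.
4. **Embryo cleavage.**  Offspring of drive-carrying mothers have each
   remaining wt drive-locus allele cleaved independently with the embryo
   cut rate e, split ρ : (1 − ρ) into r1 : r2.  No off-target cleavage is
   modelled in embryos.  Cleavage is all-or-nothing per allele; mosaic
   phenotypes are out of scope.
5. **Viability selection** on offspring, then renormalization per sex.

A single effective cut site is modelled.  For a 4-gRNA construct this
slightly understates drive performance (real constructs retain partially
cut, still-convertible wt alleles); the equilibrium genetic load of the
carrier-only-breeding protocol is correspondingly predicted slightly
*higher* here (99.8%) than a multi-site model gives (~98%).

**Fitness.**  Six architectures: neutral; somatic-cleavage fecundity cost
confined to female drive/wt heterozygotes (parameter = net heterozygote
fitness); direct viability; direct fecundity + male mating success; and
the same two keyed on disrupted off-target alleles.  Costs are
multiplicative with heterozygotes at √w of homozygote fitness w.  All
fitness parameters express costs *additional* to the engineered female
sterility.

**Genetic load** is 1 − (mean viable offspring per female relative to an
all-wild-type population): with neutral fitness it reduces exactly to the
sterile-female fraction.  The replacement-threshold calculator
(1 − 2/(eggs × survival)) gives the load needed to shrink a population
whose females lay `eggs` eggs with egg-to-adult survival `survival` at a
1:1 sex ratio.

**Founders.**  Release-generation carriers are drive/wt heterozygotes
whose off-target alleles are disrupted with probability 0.5 each,
independently (the carriers derive from drive-heterozygous fathers that
cut at rate 1).  Treating the 50% as a per-allele fraction rather than
forcing every founder to be an off-target heterozygote matters only under
the off-target fitness models, and negligibly.

## Parameters

| parameter | meaning | default | basis |
|---|---|---|---|
| conversion_female/male | germline wt→drive conversion in drive/wt hets | 0.767 | sex-averaged measured rate (72.7% / 80.7%) |
| germline_resistance_total | germline wt→r1+r2 rate | 0.222 | set so germline cutting is nearly complete |
| embryo_cut_rate | per-allele embryo cleavage by maternal Cas9 | 0.522 | sterility assay (12/22 vs 1/20 baseline) |
| relative_r1_rate ρ | fraction of new resistance alleles that are r1 | 0 | no functional resistance observed |
| offtarget_germline_cut_rate | off-target disruption in drive carriers | 1.0 | simplest mostly-cut off-target model |
| initial_offtarget_cut_fraction | founder-carrier disrupted fraction | 0.5 | founders from drive-het fathers |
| homozygote_fitness w | fitness of cost-allele homozygotes | 1.0 | fitted per model; heterozygotes √w |

All rates are probabilities in [0, 1]; conversion + germline resistance
must not exceed 1 per sex (the measured male rate 0.807 is therefore only
usable with a proportionally smaller resistance rate — the sex-averaged
default is the configuration actually analysed).

## Inference

The observable is the per-generation count of DsRed drive carriers versus
non-carriers.  Each transition is conditioned on the data: the predicted
genotype distribution at generation t is rescaled so its carrier mass
equals the observed carrier frequency (within-phenotype proportions kept
from the model), advanced one generation, and the observed count at t+1
scored with Binomial(n_{t+1}, predicted carrier frequency).  Sexes are
pooled in the observation model because phenotyping does not distinguish
them.  The transition out of the release generation is excluded: founder
adults in the experiments had atypical fitness.  A dataset with G
generations therefore contributes G − 2 transitions.

The single fitness parameter is maximized by deterministic bounded search
on (0.001, 1.5]; fits are bit-for-bit reproducible.  Model comparison
uses AICc = 2k − 2lnL + 2k(k+1)/(n−k−1) with n = transitions used and
k = 0 for the neutral model.  95% intervals are profile-likelihood
intervals at a 1.92 log-unit drop (χ²₀.₉₅,₁/2); the same drop is used for
the one-sided r1 upper bound, a deliberately conservative choice.  The
relative r1 rate is profiled on [0, 0.05] with the fitness parameter
re-optimized at each value (grid of 26 points plus local refinement);
multiplying the relative bound by the germline resistance rate or the
embryo cut rate converts it to absolute formation rates.  Pooled fits sum
cage log-likelihoods with shared parameters.

**Calibration caveat.**  Because the binomial likelihood captures only
phenotype-sampling noise and not the extra multinomial noise in the
genotype composition of a finite cage, the profile CI is modestly
anti-conservative: in the package's own recovery study (100 cages of
4,000 adults, 8 generations, viability w = 0.8) the MLE is unbiased and
the empirical coverage of the nominal 95% interval is ≈90%.  The same
limitation applies to any carrier-frequency-only inference of this type.

## Simulators and synthetic data

`simulate_cage` emulates the large-cage design: a fixed census N drawn
multinomially each generation from the deterministic next-generation
distribution conditioned on the realized tallies.  Defaults follow the
experiments: N = 4,000, release frequencies 8.8%/41.3%, and founder
composition as above.  `simulate_artificial_selection` emulates the
small-cage protocol: all non-carrier adults are discarded before mating,
and the next census is Poisson with mean fertile-females × eggs ×
survival × mean relative output (defaults 20 eggs, 80% survival), with
multinomial genotype assignment.  `generate_cross_dataset` produces
per-parent binomial offspring phenotypes and sterility-assay counts for
the estimator module.  A seed plus configuration fully determines every
output.

What the simulators deliberately omit: phenotyping error (none was
reported), density dependence and larval competition (vial crowding in
real cages caps the first-generation boom the selection simulator shows),
age structure, overlapping generations, and mosaicism.  Passing tests
therefore validate the sampling and bookkeeping of the model, not these
ecological features of real cages.

## Numerical choices

Carrier-frequency convergence uses tol 1e-6 per generation with a
1,000-generation cap — far below the ~1% precision of any quantity the
model is compared against.  The cost-for-equilibrium solver bisects on
cost in [0, 1) to 1e-4 (equilibrium is monotone decreasing in cost, so
the root is unique); targets above the zero-cost equilibrium raise an
error.  Zero reproductive output (all females sterile, or no viable
offspring) raises a distinct extinction signal rather than producing
NaNs, because the selection protocol reaches it by design.  Distributions
are renormalized defensively and asserted to sum to 1 within 1e-9.

Problem sizes used in the test suite and acceptance script (chosen to
match the experiments or to keep Monte-Carlo error well below the asserted
tolerances): cage census 4,000, 8–17 generations; law-of-large-numbers
checks at N = 10⁵ with 8 replicates; the recovery study at 100
replicates.

## Known limitations

- Single effective gRNA site: partial-resistance intermediates of a
  multi-gRNA construct are not represented, biasing the selection-protocol
  load prediction slightly upward and the drive performance slightly
  downward.
- The r1 parameterization forms r1 within the total embryo cut rate e
  (split ρ : 1−ρ).  An alternative keeps the r2 rate at e and adds r1 at
  ρ·e; below ρ = 0.005 the two differ by under 0.5% relative, so the
  choice is immaterial in the regime of interest.
- Fitness-cost *type* is weakly identified from carrier trajectories
  alone (viability and fecundity/mating architectures are near-twins);
  the package reports AICc ranks rather than claiming the type is known.
- No batch/vial random effects: the pooled estimators in `cross_stats`
  ignore between-vial heterogeneity (subcounts are retained in
  `CrossCounts.batches` for users who want to model it).
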