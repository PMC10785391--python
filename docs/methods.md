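# Methods

## Scope and data model

`cnvrpipe` analyzes copy-number variation in a pedigreed cattle herd
genotyped on a SNP array. Its inputs are (i) per-sample CNV calls in a
PennCNV-like dialect with per-sample array quality metrics, (ii) a
pedigree (animal, sire, dam; `0` = unknown), (iii) raw phenotype records
(weighings, feeding-day intakes, bunk tag reads) or pre-derived trait
values, and (iv) optional gene/QTL interval annotations. Coordinates are
1-based inclusive everywhere inside the package (`length = end − start + 1`);
BED input/output is converted at the boundary. Upstream CNV *calling*
(the intensity HMM and GC-wave correction of the array signal) is out of
scope: the pipeline starts from calls.

## Quality control

Sample-level: a sample is removed when any of its array noise metrics
strictly exceeds its threshold — LRR SD > 0.30, BAF drift > 0.01,
|GC wave factor| > 0.05. Boundary values pass; the thresholds are
configurable (`QcThresholds`). Call-level: calls from failing samples,
calls off the 29 autosomes, calls with fewer than 3 supporting SNPs, and
calls shorter than 1,000 bp or longer than 5,000,000 bp are removed.
Each removed call is attributed to the *first* failing rule in the fixed
order sample → chromosome → SNP count → length, so per-rule counts plus
kept calls always sum to the input count and filtering is idempotent.

## CNVR inference

Regions are the transitive closure of calls sharing at least one base:
after sorting by (chromosome, start), a call starting at or before the
current region envelope's end joins the region. Under inclusive
coordinates, calls `100–200` and `200–300` share base 200 and merge;
`100–200` and `201–300` are adjacent but disjoint and do not. A region
is a `deletion` if every member call has copy state < 2, `duplication`
if every member has > 2, `mixed` otherwise. Genotype coding per sample
and region is −1 (any overlapping deletion call), +1 (any duplication
call), 0 otherwise; a sample with both in one region is inexpressible on
this scale and is coded 0 with a logged conflict — conservative toward
the null. Carrier frequency is the fraction of QC-passing samples with a
nonzero code; a configurable floor (default report flag at 1%) can
restrict the association scan to common regions.

## Trait derivation

* **W210** `= ((WW − BW)/AAW)·210 + BW` (kg); weaning weight adjusted
  linearly to 210 days.
* **ADG** (kg/day): OLS slope of test-period weights on days-on-test;
  the intercept estimates on-test start weight. Weighing gaps above 28
  days are flagged, not fatal.
* **DMI** (kg/day): mean over valid feeding days of as-fed intake times
  that week's diet dry-matter proportion.
* **RFI** (kg/day): residual of OLS `DMI ~ 1 + ADG + BW^0.75`, fitted
  within contemporary test group; residuals average zero per group.
  `BW^0.75` uses the mid-test weight read off the ADG regression line at
  the median day on test — the text basis for which body weight enters
  the metabolic-weight term is ambiguous, and this choice is consistent
  with the regression already fitted.
* **TF / FF**: tag-read streams are segmented into meal events. An event
  opens at a tag's first read and closes when the same tag's inter-read
  gap exceeds 300 s (a gap of exactly 300 s continues the meal) or when
  a different tag is read at the bunk where the animal was last seen;
  reads of one animal at different bunks within the gap window remain
  one meal. Event duration is last read minus first read (the stream has
  no exit records), intake is the sum over constituent reads. Events
  with intake < 1 kg AND duration < 3 s are discarded — the conjunction
  is the literal reading of the source rule; an `either` mode is
  provided because the conjunction is plausibly a writing slip. TF is
  summed duration per test day in minutes (the hour-scale unit that
  sometimes appears in trait tables is treated as a typo); FF is events
  per test day.
* **WSel** (experimental): weight interpolated linearly to a target age
  (378 d males / 550 d females) from the two nearest bracketing
  weighings; no standard formula is published for this adjustment.

## Fixed-effect pre-adjustment

Each trait is adjusted by an ordinary fixed-effects linear model:
dummy-coded contemporary groups (weaning group = birth year × month ×
line × sex; feedlot group = test year × month × installation × sex;
birth month) plus covariates (dam age linear + quadratic, ages at
weaning/selection/test start), per the default `DEFAULT_TRAIT_SPECS`
mapping, all configurable. The adjusted phenotype is the OLS residual —
mean zero within fitted groups; a toggle re-adds the grand mean.
Contemporary groups with a single record yield zero residuals; they are
retained but flagged, since no minimum group size is defined. Singleton
handling and the residual (rather than residual + intercept) definition
only shift location, which the association intercept absorbs.

## Pedigree and relationship matrix

The pedigree is topologically sorted (stable: an already-sorted table is
returned unchanged; cycles are reported by name). **A** is built by the
tabular method: `a_ij = ½(a_j,sire(i) + a_j,dam(i))` for earlier j,
`a_ii = 1 + ½ a_sire(i),dam(i)`, unknown parents contributing zero. The
matrix is dense — at herd scale (hundreds to a few thousand animals)
dense algebra is simpler and fast, and no sparse A⁻¹ machinery is
needed. Unknown-parent groups are not implemented.

## Association model

Per trait, with pre-adjusted phenotypes y:

* **Null model** `y = 1μ + u + e`, `u ~ N(0, Aσ²ᵤ)`, `e ~ N(0, Iσ²ₑ)`.
  Variance components are estimated by EM-REML. A is eigendecomposed
  once (`A = UDU'`); in the rotated basis V is diagonal, so each
  iteration costs O(n). The EM updates
  `σ²ᵤ ← σ²ᵤ + (σ⁴ᵤ/n)(y'PAPy − tr(PA))` and
  `σ²ₑ ← σ²ₑ + (σ⁴ₑ/n)(y'PPy − tr(P))` keep both components
  non-negative and the restricted likelihood non-decreasing (asserted in
  tests). Convergence: relative parameter change < 1e-8 or 500
  iterations; hitting the cap flags the result rather than raising —
  near the σ²ᵤ = 0 boundary EM converges slowly but the fitted V it
  returns is already stable to well below test tolerances. EM was chosen
  over AI-REML for guaranteed monotonicity at this scale; the algorithm
  is isolated behind `estimate_variance_components` and replaceable.
* **Region test**: variance components are held fixed across all
  regions of a trait (estimated once from the null model — not
  re-estimated per region). For code vector g, GLS with
  `V = Aσ²ᵤ + Iσ²ₑ` fits intercept + g; `SE` comes from
  `(X'V⁻¹X)⁻¹`; `t = β/SE`; the p-value is two-sided on a t
  distribution with `n − 2` degrees of freedom — the printed convention
  (intercept + region effect), kept even though a GLS effective-df
  argument could differ. Monomorphic regions are skipped with a logged
  reason; animals without a trait record are dropped per trait.
* **Multiplicity**: Bonferroni, significant iff `p < α/m` strictly,
  with m defaulting to the total number of CNVRs in the genotype matrix.

Validation is dual-route: the V⁻¹-based GLS is checked against
Henderson's mixed-model equations on the same data (1e-8), against the
closed-form OLS t-test when σ²ᵤ = 0 and σ²ₑ equals the OLS residual mean
square (the only reading under which that degenerate equality is exact),
and by simulation — null type-I error within the binomial 99% CI of
0.05 at 2,000 replicates, KS agreement of the t statistics with t(n−2),
unbiased recovery of variance components and effect sizes within 3
Monte-Carlo SE, and ≥ 95% probability that a causal region attains the
smallest p among 50 candidates at β = 1 residual SD, carrier frequency
0.1, n = 600.

## Annotation and enrichment

Significant regions are intersected with user-supplied gene (GFF3 or
BED) and QTL (BED with a type-label column) annotations; no network
fetches. For each QTL type, enrichment is the upper-tail hypergeometric
probability `P[X ≥ k]` with N database QTLs, K of the type, n distinct
QTLs overlapping the candidate regions and k of those of the type.
Enrichment p-values are reported raw (no multiple-testing correction),
matching how such scans are conventionally reported.

## Synthetic-data generator

The generator emulates the study conditions a closed experimental herd
provides:

* **Pedigree**: discrete generations, random mating; defaults 100
  founders, 4 generations, 50 matings/generation × 3 offspring → 700
  animals, of which ~630 pass array QC at the default 10% failure
  fraction (study scale ~620).
* **CNV landscape**: 500 regions, exponential lengths with mean 170 kb,
  placed without overlap (≥ 1 kb buffer) on the 29 ARS-UCD1.2 autosomes
  with probability proportional to chromosome length; type mix 45.6% /
  43.7% / 10.7% deletion/duplication/mixed; carrier frequencies uniform
  on [0.005, 0.10].
* **Genotypes**: carrier status is drawn independently per animal at
  the region frequency — *not* transmitted through the pedigree. The
  association model treats the code as a fixed covariate, so Mendelian
  transmission is unnecessary for testing and independent assignment
  keeps frequency control exact; a transmission mode could be added.
  Mixed regions split carriers evenly between the −1 and +1 classes.
* **Calls**: one call per carrier spanning the true region; optional
  fragmentation splits a call at a shared breakpoint base (so merging
  re-derives the region exactly); optional Poisson false calls. QC
  metrics are drawn from pass/fail normal mixtures rather than from a
  simulated intensity model — thresholding behavior, not metric
  generation, is what downstream code consumes.
* **Phenotypes**: `y = μ + CG effect + Σ code·β + u + e`. Breeding
  values cascade down the pedigree: founders `u ~ N(0, σ²ᵤ)`, offspring
  get the parent average plus Mendelian sampling with variance
  `σ²ᵤ·½(1 − (F_s + F_d)/2)` (¾ or 1 factors with unknown parents).
  Defaults σ²ᵤ = 1, σ²ₑ = 2 give h² = ⅓, mid-range of published
  heritabilities for these traits (0.17–0.51).
* **Feed events**: reads every 1.0–6.3 s within meals, meal durations
  2–20 min, > 300 s (default 400 s–1 h) between meals, intakes ≥ 1 kg —
  so noise-free event derivation recovers TF/FF exactly; truth is
  computed from actual read times with the same last-minus-first
  duration convention.

Identical configuration and seed give byte-identical tables; all
randomness flows through `numpy.random.Generator` streams derived from
the config seed.

What the generator does **not** emulate: LRR/BAF intensity tracks,
linkage between regions and the pedigree (no transmission), genotyping
batch effects, equipment malfunction days, or selection. Passing tests
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to real-data artifacts such as call-boundary
jitter or population structure beyond the pedigree.

## Numerical choices and degenerate inputs

* Eigenvalues of A are clipped at zero when ≥ −1e-8 (relative);
  anything lower raises as non-PSD.
* REML requires n ≥ 10; the RFI regression n ≥ 4 per group; ADG needs
  two distinct days-on-test.
* Ties/boundaries: QC keeps boundary metric values; call length bounds
  are inclusive; a meal-read gap of exactly 300 s continues the meal;
  `p` exactly equal to the Bonferroni threshold is *not* significant.
* Region ids are assigned in (chromosome, start) order, making merge
  output order-invariant to input shuffles.
* Problem sizes in the validation suite (600-animal pedigree, 2,000
  null replicates, 200 recovery replicates, 1,000 merge oracle sets,
  100 pedigree oracle sets) keep the full run in tens of seconds while
  leaving Monte-Carlo error well below the tolerances tested.

## Known limitations

* Two-stage adjustment (residualize, then test) is the implemented
  procedure; it is slightly conservative relative to a joint fit when
  region codes correlate with fixed effects.
* df = n − 2 ignores the uncertainty in the REML variance components;
  simulation shows the resulting test is mildly conservative
  (type-I ≈ 0.046 at nominal 0.05) at n = 600.
* The −1/0/+1 coding collapses copy states 0/1 and 3/4 and cannot
  express within-region deletion+duplication carriers.
* CNVR frequency control in the generator is per-animal i.i.d.;
  estimates of association power under true familial transmission would
  require the (unimplemented) transmission mode.
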