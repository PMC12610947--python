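# Methods

This note documents the models, conventions, and numerical choices behind
`agerank`: a consistency-first meta-analysis of age-related differential
expression coupled to a *C. elegans* RNAi lifespan-screen analysis, plus the
synthetic-data generators used to exercise both arms.

## Per-dataset differential expression

Each dataset is a genes-or-probes × samples matrix of normalised log-scale
expression values with every sample labelled *young* or *old*.  The contrast
is the old-minus-young mean difference per probe, tested with an
empirical-Bayes moderated t-statistic:

- the pooled per-probe variance `s_g²` (residual df `d_g = n₁ + n₂ − 2`) is
  modelled as a draw from a scaled-F prior with parameters `(d₀, s₀²)`;
- the prior is fitted by moment matching on `log s_g²`, whose sampling mean
  and variance are known in terms of digamma/trigamma functions: the excess
  dispersion of `log s_g²` beyond its sampling component identifies `d₀`
  (via a Newton inversion of the trigamma function), and the centring
  identifies `s₀²`.  Zero excess dispersion yields `d₀ = ∞`, i.e. all probes
  share the common variance `s₀²`;
- the moderated variance is the posterior mean
  `s̃_g² = (d₀ s₀² + d_g s_g²) / (d₀ + d_g)`, and
  `t = effect / (s̃_g · √(1/n₁ + 1/n₂))` is referred to a t distribution
  with `d₀ + d_g` df.

With `d₀ = 0` this is exactly the ordinary pooled two-sample t-test (asserted
to machine precision in the tests).  The full path is cross-checked against
limma's `eBayes` through `Rscript` on a shared fixture and agrees to ~1e-8
relative error.  Probes with zero variance in both groups are not testable;
they are flagged, excluded, and counted in the log rather than silently
dropped.

Raw p-values are Benjamini-Hochberg adjusted **within each dataset** (never
pooled across datasets, since calling is per-dataset by design), and a probe
is called at adjusted p < 0.25.  The permissive threshold trades specificity
for sensitivity deliberately: the cross-dataset consistency requirement
downstream is what controls false discovery at the gene-ranking level, so
each dataset only needs to cast a reasonably sensitive vote.

**Probe → gene collapse.** A gene is called if any of its probes passes; its
direction comes from the passing probe with the smallest adjusted p.  If
passing probes disagree in direction, the gene contributes to *neither*
direction for that dataset.  This is the convention most faithful to a
consistency-first ranking: an internally contradictory dataset should not
vote.

**Symbol harmonisation.** Records from non-human datasets are mapped to
human symbols through a homolog table keyed by (species, native symbol).
Unmapped records are dropped and counted; conflicting duplicate map entries
are a validation error rather than a silent first-wins choice.

## Vote-counting rank and its binomial null

For each gene `i`, `S_i^up` and `S_i^down` count the datasets with a
significant up or down call.  The signed total and rank are

```
S_i = S_i^up − S_i^down        R_i = |S_i|
```

Effect sizes are discarded on purpose: magnitudes are not comparable across
species, tissues, and platforms, whereas direction-consistent recurrence is.
Genes with opposing calls cancel and cannot rank highly.  The score table
distinguishes genes whose calls cancelled (`rank 0, cancelled=True`) from
genes never called anywhere (omitted from the table).

If one gene carries both an up and a down call in the same dataset — which
can happen after homolog merging maps two native genes onto one human
symbol — that dataset contributes to neither count, mirroring the probe
collapse rule.

**Null model.**  Each dataset is treated as an independent Bernoulli trial
that calls a given gene (in either direction) with probability equal to the
average per-dataset DEG rate, estimated as the ratio of means: mean DEG
count over mean genes tested (the mean-of-ratios alternative is reported
alongside).  Rank significance is the upper tail `P(X ≥ R)` for
`X ~ Binomial(n_datasets, rate)`, computed with the numerically stable
survival function (and verified against brute-force pmf summation to 1e-12
for all n ≤ 30).  Because the null pools both directions into one success
class while the rank is an absolute *difference* of directional counts, the
printed p-value is conservative for R.  This is documented, not "corrected":
it keeps the p-value interpretable as the probability that undirected
recurrent calling alone reaches the rank.  The trials count stays at the
full dataset count even for genes absent from some platforms; per-gene
coverage is reported so users can judge, but shrinking n per gene would
change the meaning of the published rank thresholds.

**Tissue breakdown.**  For a gene and tissue, `s_tissue` is the signed call
sum restricted to that tissue's datasets and the displayed fraction is
`s_tissue / n_tissue` (so ±100% means every dataset of that tissue voted the
same way).  Fractions aggregate: `Σ_tissue s_tissue = S_i`.

**Candidate selection.**  Genes at or above a rank cutoff, ordered by rank
descending then symbol ascending (rank ties carry no information, so the
tie-break is alphabetical).  Two cutoffs are carried through the pipeline:
a looser one intended for pathway-level analyses (default 6, where the
binomial tail is ≈0.003) and a stricter one for the screen panel (default 7).

## Ortholog and clone selection

The ortholog table is compendium-style: one row per (human gene, worm gene,
RNAi clone) with the number of orthology-prediction methods supporting the
assignment and the row's position in the original results listing.  The
original listing order is materialised as an explicit `list_position`
column at load time because the tie-break depends on it and must be
reproducible from a file on disk.

Selection: maximal support count wins; ties break by earliest list
position; if the preferred clone is unavailable (failed culture or sequence
verification — wet-lab facts consumed as an availability table), the next
row in preference order is used and marked `fallback`; genes with no usable
row are `unavailable`.  The same first-listed rule is applied uniformly
whether the tie is between different worm genes or different clones of one
gene.  The panel summary reports, per direction, candidates, conserved
genes, conserved percent (nearest integer), and clones obtained.

## Lifespan analysis

Lifespan is days from the first day of adulthood; each animal contributes a
day and an event flag (1 = observed death, 0 = censored, e.g. wall
crawlers).  Group curves are Kaplan-Meier product-limit estimates
(via lifelines).  Summary conventions:

- **mean** = restricted mean survival time, the exact area under the KM
  step function up to the last observed day, with the standard
  Greenwood-type variance
  `Σ_i A_i² d_i / (n_i (n_i − d_i))` where `A_i` is the area under the
  curve from death time `t_i` to the horizon.  Computed in closed form from
  the step function (no numerical quadrature).  With no censoring the RMST
  equals the arithmetic mean of death days exactly and its SE equals the
  (biased) sample SD over √n — both identities are asserted in the tests;
- **median** = first day the curve reaches 0.5 or below;
- **maximum** = mean of the longest-lived decile of observed deaths
  (rounding the decile size up, so at least one animal).  "Maximum
  lifespan" has no single standard definition; the decile mean is a common
  robust convention and both the single-longest-survivor and
  90th-percentile alternatives are available via `max_method`.

Group comparisons use the standard two-group log-rank test (hypergeometric
variance over pooled event days, χ² with 1 df), validated against an
explicit hand-computed O−E table and an exact permutation oracle on small
fixtures.  Tied death days — which arise when assays are scored every few
days — are handled by the usual risk-set arithmetic.  Death days carry no
interval-censoring midpoint adjustment: the day an animal is first scored
dead is its death day.

**Multiple testing and the two-stage hit rule.**  Raw log-rank p-values are
Bonferroni-multiplied by the number of *test clones* in the same batch
(negative/positive control comparisons are excluded from the family).  A
clone is a hit iff (initial screen: mean-lifespan extension ≥ 5% **and**
corrected p < 0.05 against the within-batch negative control) **and**
(validation screen: corrected p < 0.05).  The ≥5% criterion is applied to
the *mean* extension (configurable); clones absent from a stage without a
legitimate reason (i.e. other than having failed the initial screen) are
`not_evaluable` and never hits.  Percent extensions are reported as signed
floats and displayed with half-away-from-zero integer rounding.

## Synthetic data: what it emulates and what it does not

**Expression collections.**  Datasets share one gene namespace (non-human
datasets use species-native spellings, e.g. capitalised rodent symbols, so
harmonisation is exercised for real).  Values are log-scale with per-gene
baselines ~ Normal(8, 2) and i.i.d. Normal noise — the simplest model under
which the two-group t-test is exactly calibrated.  Species and tissues
cycle through configurable pools (defaults: 4 species, 6 tissue classes);
a configurable fraction of genes carries a second probe.

Two signal layers:

- *drivers*: named genes with a fixed direction and standardized effect
  size, planted independently in each dataset with probability
  `penetrance`;
- *transcriptional drift*: in each dataset an independent random subset of
  non-driver genes receives a large transient effect with a random sign.
  This is what makes the binomial null meaningful — every gene really is
  called in each dataset with roughly the target probability,
  independently.

`null_deg_rate` (default 0.06) is the *target realized call rate*, not the
raw planting rate.  BH at level q rejects, alongside essentially all
planted drift genes, a share of true nulls at its adaptive threshold, so
planting at rate ρ would realize roughly ρ/(1 − q(1 − ρ)) calls.  The
generator therefore plants at `ρ(1 − q)/(1 − qρ)` (≈0.0457 for ρ=0.06,
q=0.25), derived from the BH fixed point under near-unit drift power; the
realized rate then lands on the target (the calibration test allows ±0.01
absolute for the fixed-point and power approximations).  Drift effects
default to 4 standardized units so their detection probability is ≈1 at
the thresholds in play; the compensation assumes this.

Homolog tables map a configurable fraction (default 0.95) of filler genes
per non-human species; driver genes are always mapped, modelling the fact
that screen candidates come from well-annotated genes.

Not emulated: platform-specific artifacts, probe chemistry, RNA-seq counts,
normalisation failures, covariate structure (sex, strain), or correlated
genes.  Passing tests therefore demonstrate the statistical logic of the
pipeline under a clean generative model, not robustness to real-world
array pathologies.

**Ortholog tables.**  1–3 candidate worm genes per conserved human gene,
integer support counts in 1–6, Ahringer-style clone coordinates, global
list positions, and deliberately planted support-count ties.

**Lifespan cohorts.**  Death days are inverse-transform draws from a
Gompertz distribution with survivor function
`S(t) = exp(−m·(a/b)(e^{bt} − 1))`, where `b` is the shape (default
0.35/day), `a` the baseline rate, and `m` a per-group proportional-hazard
multiplier.  The default rate is solved so the control median is ≈22 days,
the scale of a wild-type assay at 20 °C; a multiplier of 0.3 (a 70% hazard
reduction) then yields mean extensions around 15%, matching the strongest
effects such screens report.  Censoring is uniform on (0, death day) with a
per-animal probability (default 0.05): no mechanistic censoring model is
claimed for wall crawlers, and uniform is the neutral choice.  Animals are
split evenly over batches and plates (~20/plate).  Death days are
continuous; scoring-interval discreteness is not simulated by default
(tied-day handling is tested with explicit fixtures instead), and plate
effects are i.i.d. noise only.

## Pipeline and reproducibility

`run_pipeline` executes simulate (or load) → DEG → rank → panel → simulated
two-stage screen → hit calls, writing every stage table as TSV plus a
manifest (config, config hash, seed, package versions, per-dataset DEG and
drop counts).  All randomness derives from the config seed through
`numpy.random.SeedSequence` spawning, so a rerun with the same config is
byte-identical; `write_report` renders a deterministic summary and is
idempotent.  In the simulated screen, clones whose human gene is a planted
driver receive the configured hit hazard multiplier, giving the pipeline an
end-to-end ground truth.

## Problem sizes and tolerances in the test suite

Simulation-based tests use scaled problem sizes chosen to keep Monte-Carlo
error well inside the asserted bands: driver-recovery runs 20 seeds of
25 datasets × 2,000 genes; null-rank calibration uses one 25 × 20,000
collection (expected null fraction at rank ≥ 6 is ≈3e-4, an order of
magnitude under the asserted 0.003 × 1.5 bound); log-rank type-I error uses
400 replicates at n = 50/group with a 3σ binomial band; moderated-t type-I
uses 500 replicates of 2,000 genes with a ±0.005 band; the screen-funnel
check runs 10 seeded two-stage screens at n = 100/150.  Numerical
tolerances on dual-route identities (survival function vs pmf sum, RMST vs
quadrature, package vs hand oracles) are 1e-9 to 1e-12.

## Known limitations

- The binomial rank p-value is conservative for the absolute-difference
  rank (by design, see above); it is not a calibrated frequentist p-value
  for R.
- The moderated test fits the two-group contrast only; no covariates.
- The generator's drift-rate compensation assumes near-unit drift power;
  configurations with small samples or small `drift_effect_size` will
  realize call rates below target.
- Restricted means are horizon-dependent: groups are summarised to their
  own last observed day, which is the convention of the field's survival
  tools but makes cross-group mean comparisons mildly dependent on the
  longest survivor.
- No plate- or batch-level random effects; batch structure affects only
  which control a clone is compared against.
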