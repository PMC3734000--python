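# Methods

`tagimpute` studies how tagSNP selection, reference-panel size and
reference-panel composition affect LD-based genotype imputation in a
livestock population genotyped on a dense SNP chip.  Everything runs on
synthetic populations, so every experiment is seeded and exactly
reproducible.

## The imputation model

Imputation and phasing use a diploid Li–Stephens haplotype-copying HMM.  A
test individual's two haplotypes are modelled as mosaics of the H reference
haplotypes; the hidden state at marker m is an ordered pair (k, l) of
reference haplotypes.  Between adjacent markers separated by d bp each chain
independently switches template with probability

    theta = 1 − exp(−4 · Ne · c · d / H)

with Ne the effective population size (default 113, a typical commercial
pig-breed estimate) and c the per-bp recombination rate (default 1e-8).  The
observed dosage is emitted from the state's implied dosage with an
independent per-allele error ε (default 1e-3, the scale of array genotyping
error); missing observations emit uniformly, so posteriors at untyped
markers interpolate between flanking tagSNP.  Forward–backward over the H²
pair states is exact and deterministic; the transition factorizes over the
two chains, giving O(H²) work per marker.  The reported posterior genotype
triple is the posterior distribution of the state-implied dosage class —
the emission error enters the likelihood, not the read-out — so with a
reference of identical haplotypes h the expected dosage is exactly 2h.

This model is a deliberate stand-in for production imputation software
(BEAGLE's localized haplotype-cluster model is not reimplemented).  The
package's claims are therefore about LD-based imputation generically, and
the test suite checks qualitative orderings, not numerical equivalence with
any particular tool.

### Phasing

Unrelated individuals are phased with the classic iterative scheme: phase
is initialized randomly consistent with each genotype; in each of
`n_iterations` rounds (default 10) every individual is re-decoded against
the current haplotypes of all others, drawing `n_samples_per_iteration`
(default 4) backward samples from the exact forward pass and keeping the
most probable.  When the conditioning panel exceeds
`max_reference_haplotypes`, the states are restricted to the most similar
haplotypes — those with fewest conflicts against the individual's
homozygous genotypes (the surrogate-family idea used by large-scale
phasers).  This restriction matters: a random subsample of conditioning
haplotypes gives switch-error rates an order of magnitude worse.

Trios are phased by Mendelian rules: a parent's transmitted allele is
resolved whenever any member is homozygous (or the offspring pins it down);
triple-heterozygous sites are flagged ambiguous and subsequently resolved
against a scaffold of the other trios' haplotypes with a haploid copying
chain.  Mendelian inconsistencies are flagged, set missing, and a trio is
rejected when they exceed 5% of fully-called markers.

## Accuracy statistics

For observed dosage g_ij and posterior expected dosage ĝ_ij at SNP i,
individual j, with N_i called genotypes per SNP and M_j per individual:

* IA = 1 − Σ_ij |g_ij − ĝ_ij| / (2 Σ_i N_i), with SNP-wise (IA_i·) and
  animal-wise (IA_·j) decompositions; the N_i- and M_j-weighted means of the
  decompositions equal the overall value exactly (asserted to 1e-12).
  Expected-dosage comparison is the default; a hard-call mode exists.
* IA_Freq,i = p(AA)_ref·p(AA)_val + p(AB)_ref·p(AB)_val + p(BB)_ref·p(BB)_val —
  the probability that a genotype drawn at random from the reference panel
  matches the testing population; predicted frequencies are per-SNP means of
  posterior triples (hard-call frequencies available as an option).
* IA_MAF = (IA − IA_Freq) / (1 − IA_Freq), the gain over frequency-only
  guessing; zero means no gain, negative means worse than guessing.
* dosage r²: squared Pearson correlation of observed and imputed dosage per
  SNP, undefined (and excluded from weighted means) where the truth is
  monomorphic among evaluated individuals.

One scale caveat is worth stating: IA measures L1 dosage error while
IA_Freq is a genotype-collision probability, so even a frequency-only
imputer has IA slightly above IA_Freq and IA_MAF does not sit exactly at 0;
the test suite verifies the intended content of the argument (raw
concordance is inflated at low MAF; Eq-style baseline equals the
Monte-Carlo match rate of random genotype assignment) rather than a literal
zero.

Interval summaries use the empirical shortest-window HPD: among all
contiguous windows of ⌈mass·n⌉ sorted values, the narrowest (ties to the
lower start).  The smoothed accuracy-versus-position/MAF curves use locally
weighted polynomial regression (tricube kernel times observation weights,
degree ≤ 2, default span 0.3) — written in-package because the statistics
stack's lowess does not accept the N_i observation weights.

## TagSNP selection

* Even spacing: each chromosome span [0, L] (L defaults to the largest
  marker position) is cut into k equal segments; the SNP nearest each
  segment center is tagged; empty segments contribute nothing.
* Statistical (LD set cover): greedy cover of the r² graph at threshold
  rt2 — every segregating SNP must be a tag or have r² ≥ rt2 with one.
  Coverage ties break toward higher MAF, then lower position (high-MAF tags
  impute better).
* Predictive: forward search that masks the training split down to the
  candidate tag set, imputes, and keeps the candidate with the best mean
  accuracy; ties within 1e-12 break toward higher MAF then position.  It is
  orders of magnitude more expensive than the other selectors and exists to
  demonstrate that the cheap selectors match it.
* Weighted spacing: a reconstruction (not a reimplementation) of
  commercial-panel design: greedy score Σ_pop w_pop·MAF_pop(i) +
  min(d/target_spacing, 1), with the target spacing halved inside the
  configurable end windows so chromosome ends get double density.  The
  target spacing carries a half-marker-spacing discretization correction so
  the realized count matches k on a regular grid.

## The synthetic populations

Forward Wright–Fisher simulation, chosen over a coalescent for transparency:
founders carry independent biallelic sites with frequencies from a
configurable spectrum (default U(0.05, 0.5)); each generation is random
mating with Poisson crossovers (no interference) at rate c per bp; LD is
created entirely by drift and recombination.  Defaults: Ne = 113 diploids,
100 generations, 300 markers evenly spaced over 15 Mb (50 kb spacing,
matching a ~60K-chip marker density), c = 1e-8.  Under these settings mean
r² at 1 Mb equilibrates to ≈ 0.15–0.20, the level reported for commercial
Yorkshire pigs, which is the calibration anchor the acceptance suite
checks.  Markers with realized MAF < 0.01 are dropped (they would fail chip
QC anyway); the surviving spectrum always includes MAF < 0.1 so
MAF-stratified analyses are exercisable.

What the generator does **not** emulate: mutation, selection, migration,
pedigree loops, genotyping-batch artifacts, and per-chromosome
heterogeneity (a single uniform chromosome stands in for a "medium-sized,
uniformly covered" one).  Passing trend tests on these populations shows
the machinery responds to LD structure, panel size and marker placement the
way the field expects — it does not certify accuracy values for any real
breed.

## Experiment designs and scaled-down geometry

All experiments replicate over independent populations (default 20
replicates) and report Monte-Carlo standard errors; ordering claims are
asserted with 2-SE margins.  The default geometry (300 markers / 15 Mb,
20 test individuals, reference panels up to 192 haplotypes) keeps a full
replicated run in minutes on one core while preserving every contrast of
interest; the exact H² forward–backward makes markers × states the binding
cost.

* Tag density: statistical selection at rt2 ∈ {0.2, 0.3, 0.45} sets the tag
  counts; even spacing is run at the matched counts.
* Panel size/composition: three retained generations emulate the study
  cohort structure — trio parents come from the oldest cohort (a panel
  genotyped "in an earlier study"), supplementary and test individuals from
  the two recent cohorts.  Supplementary individuals are phased jointly in
  one run and sliced into nested panels (16–128 haplotypes, plus the
  cost-equivalent 192 = 1.5 × 128 comparison, reflecting that a trio yields
  4 reference haplotypes for 3 genotyped animals).  "Oldest" panels take the
  earliest-generation supplementary individuals; "combined" panels stack the
  trio haplotypes with randoms phased against them.
* Stratified report: per-SNP accuracy against scaled position (5% extremes
  vs the central 10%) and reference-panel MAF (< 0.1 vs rest), under evenly
  spaced tags and under equal-count weighted-spacing tags with doubled end
  density.

## Numerical choices and degenerate inputs

Missing dosage is the sentinel −1 in int8 matrices; arithmetic never treats
it as 0.  Posterior triples are clipped of round-off negatives and
renormalized; their sums are asserted to 1e-9.  Monomorphic markers have
undefined r² (NaN) and are excluded from selection coverage and weighted
means together with their weights.  Forward–backward is scaled per marker
(no log-space needed at these sizes); determinism is exact because
imputation involves no sampling.  All selector ties are broken
deterministically (higher MAF, then lower position).  QC order follows
chip practice: animal call-rate filter first, then SNP MAF and call-rate
filters, with strict inequalities and zero thresholds acting as no-ops.

## Known limitations

The stand-in imputer and phaser are not numerically comparable to BEAGLE;
phasing switch error (~2–5% at the default schedule) is the main cost when
comparing HMM-phased random panels to Mendelian-phased trio panels.  The
predictive selector is quadratic in markers per step and only sensible on
small candidate sets.  X-chromosome dosage handling, multiallelic sites and
indels are out of scope; only autosome-style diploid data are supported.
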