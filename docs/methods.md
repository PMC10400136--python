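# Methods

## Genome model and coordinates

All analyses run on a 22-autosome genome with hg19-scale arm lengths
(~2.9 Gb interrogated); sex chromosomes are excluded because scar features
on X/Y are confounded by sex-dependent ploidy. Coordinates are 0-based
half-open throughout; a segment's length is `end − start`. Profiles must
tile every arm exactly — contiguous, non-overlapping, never crossing a
centromere — and validation reports the first offending segment.

Copy-number states: LOH means minor copy number 0 with total ≥ 1; a deep
deletion is total copy number 0 (and is therefore *not* LOH); allelic
imbalance means the two allele counts differ.

## Scar features

The exact feature list behind proprietary scar classifiers is unpublished,
so this package implements the established scar canon plus indel features,
and keeps the feature set swappable:

* **gLOH** — summed length of LOH segments divided by the interrogated
  genome, excluding any LOH segment spanning ≥90% of its chromosome arm
  (near-whole-arm LOH reflects aneuploidy, not focal scarring).
* **Interstitial LOH count** — maximal LOH runs (adjacent LOH segments
  merged, including across the centromere) longer than 15 Mb but shorter
  than the whole chromosome.
* **Large-scale state transitions (LST)** — per arm, after merging
  same-state neighbours and discarding segments under 3 Mb, adjacent
  segment pairs that are both ≥10 Mb (parameters configurable).
* **Telomeric allelic imbalance (TAI)** — per arm, an imbalanced run
  touching the telomere counts once unless it spans the entire arm (a
  whole-arm event reaches the centromere and is excluded).
* **Breakpoints** — state transitions between merged segments, per arm.
* **Indel features** — count of deletions ≥5 bp flanked by ≥1 bp of
  microhomology (the signature of microhomology-mediated end joining, the
  backup repair pathway under HRD), the fraction of deletions so flanked
  (defined as 0 when there are no deletions), and the median deletion
  length.

All counting features agree with independent brute-force implementations on
randomized profiles (tested), and feature extraction is invariant to input
segment order.

## Zygosity and allelic status

A gene is biallelic when (1) it carries a deep deletion — a deep-deletion
record or a gene locus inside a total-copy-0 segment (no copy-number
threshold beyond 0 is imposed), (2) it carries two or more pathogenic
alterations (the trans requirement cannot be verified from these inputs and
is not imposed; the rule is any 2+), or (3) a pathogenic short variant lies
in an LOH segment. A single pathogenic short variant called heterozygous is
monoallelic. A pathogenic alteration whose zygosity cannot be assessed — a
rearrangement, or a short variant with no heterozygosity call — is
"unknown"; treating an absent call as unknown rather than monoallelic is
the conservative choice. Germline versus somatic origin is not modelled;
the calling rules do not distinguish it. Sample-level labels over the
14-gene basket: any biallelic gene ⇒ biallelic; else any monoallelic ⇒
monoallelic-only; else any unknown ⇒ unknown-only; else HRRwt.

## The classifier

Training labels come from *called* status, never latent truth: biallelic
*BRCA1/2* ⇒ positive, HRRwt ⇒ negative, everything else excluded (excluded
samples never enter any fold — asserted). The model is an XGBoost ensemble
(default 200 trees, depth 3, learning rate 0.1, subsample 0.8, exact tree
method, single-threaded for reproducibility) with 5-fold stratified
cross-validation producing an out-of-fold score for every labelled sample.

No published threshold rule exists, so the default decision threshold is
the smallest out-of-fold negative score achieving ≥95% specificity on
held-out negatives; when no observed score attains the target (all scores
tied) the threshold is nudged just above the maximum, so the returned
threshold always satisfies the specificity contract. Calls are positive
when score ≥ threshold (boundary inclusive). A prevalence-matching mode —
setting the threshold at the (1 − target prevalence) quantile of cohort
scores — is provided as an alternative. Scores are raw ensemble
probabilities; no additional calibration is applied.

Label noise bounds achievable discrimination: non-genomic HRD samples are
true scar-positives labelled negative (≈4% of negatives at the default
study conditions), and the rare scar-free biallelic-*BRCA* sample is
labelled positive. Out-of-fold AUROC against labels is therefore ≈0.93 at
n = 2000 even though AUROC against latent truth exceeds 0.99.

## Co-occurrence statistics

The two-tailed Fisher exact test is computed with exact integer arithmetic:
with margins fixed, sum the hypergeometric probabilities of all tables
whose probability does not exceed the observed table's. This matches
exhaustive enumeration exactly (no floating-point tie tolerance) and agrees
with `scipy.stats.fisher_exact` to 1e-7. The reported odds ratio is the
sample cross-product estimate (∞ allowed); a Haldane–Anscombe-corrected OR
is emitted separately for volcano plotting only. P-values are
Benjamini–Hochberg adjusted across genes; the 1e-10 cap applies only to the
plotting column, never to the q computation. The landscape partition of
HRDsig(+) samples is mutually exclusive with priority biallelic
*BRCA1/2/PALB2* > other biallelic HRR > non-biallelic HRR alteration >
HRR-wildtype; an empty positive set yields a defined empty result.

## Survival analysis

Patients enter observation at their genomic-report date, after first-line
therapy has begun, so all estimators use delayed-entry risk sets
({i : entry_i < t ≤ time_i}). Estimation is delegated to lifelines
(`KaplanMeierFitter` with `entry`, `CoxPHFitter` with `entry_col`, Efron
tie handling, Newton precision tightened to 1e-12 so coefficients are
optimum-accurate to ~1e-7); the package owns endpoint definitions,
covariate coding, imputation and stratification. Patients whose follow-up
ends at or before entry are excluded with a logged count — a left-truncated
design never observes them.

TTNT (time to next treatment) is defined as first-line start to the
earlier of next-line start or death, censored with overall survival, so
TTNT ≤ rwOS always. Covariate coding: age continuous; ECOG (reference "0")
and CA19-9 (reference "normal") categorical; biopsy tissue reference
"pancreas"; treatment indicator 1 = FOLFIRINOX. Missing ECOG/CA19-9 values
are filled by single random-sample imputation (a uniform draw from the
observed values, deterministic given the seed, originals flagged) — single
rather than multiple imputation, matching the analysis this package
mirrors; imputation uncertainty is therefore not propagated into CIs.

Stratified comparisons are stratum-restricted Cox fits (treatment +
covariates within each stratum) rather than one interaction model; an
interaction model remains available through `cox_fit`'s `extra_columns`.
KM medians use the first time S(t) ≤ 0.5 (undefined if never reached);
landmark survival is the right-continuous step value S(t). A stratum arm
whose truncated risk set empties before its first event, or with fewer than
10 events overall (3 per arm), reports KM statistics or aHR as missing with
a flag instead of an unstable estimate.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes; it
is segment-level and phenomenological, not a mechanistic replication model
— features, not mechanisms, are the classifier's input.

**Latent state and genotypes.** Each patient is HRD+ with probability 0.09.
An HRD+ patient is HRR-wildtype with probability 0.37 (non-genomic HRD);
otherwise one biallelic driver gene is drawn (weights concentrated on
*BRCA2* 0.44, *BRCA1* 0.19, *PALB2* 0.16, the remainder spread over the
basket) with a mechanism mix of 10% deep deletion, 25% two hits, 65% short
variant under LOH. HRD− patients carry independent background alterations
(e.g. *ATM* 5%, *CHEK2* 3%, *BRCA2* 2%), biallelic with probability 0.15 —
biallelic inactivation without scarring is biologically uncommon, and this
choice also supplies the (label-noise) biallelic-*BRCA* HRDsig(−) cases the
real data contain; 10% of non-biallelic background alterations are
rearrangements of unknown zygosity.

**Profiles.** Scarring is drawn directly as segment-level events per class:
HRD+ draws Poisson(10) interstitial LOH events (16–45 Mb), Poisson(7)
long copy-state changes, Poisson(4) telomeric imbalances, 4% per-arm
whole-arm LOH, Poisson(8) microhomology deletions; HRD− background rates
are 1.2 / 1.0 / 0.5 / 1% / 0.8, with Poisson(3) non-microhomology deletions
in both classes. Genotype-driven events (the deep-deletion pocket or the
focal LOH over a driver locus) are placed first so the zygosity caller can
recover the planted genotype; gene-locus LOH events are kept short
(2–8 Mb) so genotype mechanics do not leak scar signal into HRD− samples.
Event placement is rejection-sampled without overlap and arms are tiled
around events with diploid-heterozygous filler.

**Clinical records.** Outcomes follow an exponential proportional-hazards
model anchored at a 5.1-month median for the cohort-average GP-treated
HRD− patient; the covariate contribution to the linear predictor is
centred at its analytic expectation so the anchors describe the average
patient. Treatment hazard ratios are 0.86 (HRD−) and 0.37 (HRD+) for
overall survival and 0.82/0.48 for the latent next-therapy time; the HRD
main effect is 0.87. Covariate log-hazard coefficients (age 0.015/year,
surgery −0.35, ECOG 1 / ≥2 +0.30/+0.70, CA19-9 <59/>59×ULN +0.20/+0.50,
liver/other biopsy +0.25/+0.10) and covariate marginals follow the
clinical-feature distribution of the emulated setting; ECOG is missing
completely at random at 25% and CA19-9 at 32% (MCAR is the assumption under
which random-sample imputation is appropriate). Censoring is independent
exponential calibrated to a 30% censoring fraction; entry delay is
exponential with mean 1 month (the report-lag distribution is not published
anywhere; this is a configurable choice). Times are quantized to 0.1-month
resolution — ceil for event/censor times, floor for entry, so orderings
survive — reflecting the coarse date resolution of EHR-derived data.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: tumour purity/ploidy estimation error,
segmentation noise, assay bait-set footprints, germline/somatic ambiguity,
informative censoring, treatment selection on unobserved prognosis, and
EHR abstraction noise. Parameter-recovery results demonstrate estimator
correctness under the generative model, not robustness to these
violations.

## Problem sizes and numerical choices

Distributional tests use 3-binomial-SD tolerances at their stated n.
The classifier-recovery suite uses a 2000-patient cohort; integration
checks use 5000; the interaction-recovery study uses 200 replicates of
n = 5000 at a true interaction HR of 0.4 (mean estimate within 10%, CI
coverage within (0.90, 0.98)); the acceptance script analyses one
8358-patient cohort (the genomic-database scale of the emulated setting)
and a 100-replicate recovery study. Fisher-oracle parity is exhaustive over
all 2×2 tables with total ≤ 40. Pipeline runs are byte-identical under a
fixed config: one seed is split deterministically per stage
(`numpy.random.SeedSequence.spawn`), XGBoost trains single-threaded with
the exact method, and run manifests record SHA-256 checksums of every
output.

## Known limitations

* The scar feature set is a published-canon reconstruction, not the
  proprietary feature list of any commercial classifier; absolute scores
  are not comparable to commercial HRDsig scores.
* The 95%-specificity threshold rule is this package's choice; prevalence
  calibration gives different calls near the boundary.
* Single imputation understates covariate-coefficient uncertainty.
* The exponential baseline gives heavier long-term survival tails than
  real pancreatic-cancer cohorts (visible in 2-year landmark estimates).
* Whole-chromosome LOH spanning both arms cannot be represented as a
  single segment (arm tiling splits it); the interstitial-LOH merger
  re-joins it, but a two-arm LOH run is then excluded only if it covers
  the full chromosome.
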