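# hrdscar

Scar-based homologous recombination deficiency (HRD) biomarker pipeline for
pancreatic cancer, with a fully synthetic clinico-genomic cohort generator.

## The problem

Metastatic pancreatic-cancer patients choose between two first-line
chemotherapy regimens: FOLFIRINOX (which contains the platinum agent
oxaliplatin) and gemcitabine + nab-paclitaxel (GP). Tumours that cannot
repair double-strand breaks by homologous recombination (HRD tumours) are
preferentially sensitive to platinum, but only a minority carry an
explanatory mutation in *BRCA1/2* or *PALB2*. HRD leaves characteristic
"scars" in the tumour copy-number profile, so a scar-based classifier can
identify HRD tumours — including non-genomic HRD — directly from a
segmented allele-specific copy-number profile.

`hrdscar` implements that analysis end to end for methodologists who want a
tested, reproducible sandbox:

* **synthetic cohorts** — a latent per-patient HRD state drives genomic
  scarring, HRR-gene genotypes, and a differential treatment benefit in a
  proportional-hazards outcome model with delayed study entry
  (left truncation at the genomic-report date);
* **zygosity calling** — per-gene biallelic / monoallelic / unknown /
  wildtype status over a 14-gene HRR basket (*BRCA1, BRCA2, ATM, BARD1,
  BRIP1, CDK12, CHEK1, CHEK2, FANCL, PALB2, RAD51B, RAD51C, RAD51D,
  RAD54L*): biallelic iff a deep deletion, ≥2 pathogenic alterations, or a
  pathogenic short variant under LOH;
* **scar features** — genome-wide focal LOH (gLOH, excluding ≥90%-of-arm
  events), interstitial LOH counts (>15 Mb), large-scale state transitions
  (≥10 Mb after 3 Mb smoothing), telomeric allelic imbalance, breakpoint
  counts, and microhomology-deletion indel features;
* **the HRDsig classifier** — a gradient-boosted tree ensemble (XGBoost)
  trained with biallelic-*BRCA1/2* positives and HRR-wildtype negatives,
  out-of-fold cross-validated scores, and a 95%-specificity decision
  threshold (prevalence-matching available as an alternative);
* **co-occurrence statistics** — per-gene two-tailed Fisher exact tests
  (exact integer enumeration) with Benjamini–Hochberg FDR, and the genomic
  landscape partition of HRDsig(+) samples;
* **outcome analysis** — left-truncated Kaplan–Meier curves, medians and
  1-/2-year landmark survival, and Cox models adjusted for age, surgery,
  ECOG, CA19-9 and biopsy tissue with random-sample imputation, stratified
  by biomarker × treatment for real-world overall survival (rwOS) and time
  to next treatment (TTNT).

The modelling surface follows the statsmodels convention: `HrdsigClassifier`
and `OutcomeAnalysis` are model objects whose `fit()` returns a results
object (`HrdsigClassifierResults`, `OutcomeResults`) carrying estimates,
uncertainties and a `summary()`.

## Worked example

```bash
hrdscar run --out runs/demo --seed 7
hrdscar report runs/demo
```

simulates a 1000-patient cohort, calls zygosity, extracts features, trains
and applies the classifier, and runs the stratified outcome analysis. The
report begins:

```
## HRDsig prevalence
simulated pancreatic carcinoma: 11.0% (110/1000)

## Genomic landscape of HRDsig(+) samples
biallelic BRCA1/2/PALB2: 62 (56.4%)
other biallelic HRR: 17 (15.5%)
monoallelic/unknown HRR: 1 (0.9%)
HRRwt: 30 (27.3%)

## Stratified outcomes (FOLFIRINOX vs GP)
[RWOS]
HRDsig(+): n=91, median FOLF 15.6 vs GP 5.6 mo, aHR 0.36 (0.20-0.65), p=0.000751
HRDsig(-): n=690, median FOLF 6.6 vs GP 5.5 mo, aHR 0.84 (0.70-1.02), p=0.0738
```

Read: 11% of simulated patients are called HRDsig(+) (the generator's
latent prevalence is 9%, plus the classifier's false-positive budget);
27% of positives are HRR-wildtype, i.e. non-genomic HRD (37% in
expectation). In the positive stratum FOLFIRINOX roughly triples median
survival over GP (adjusted hazard ratio 0.36), while the negative stratum
shows only a marginal benefit (aHR 0.84) — the biomarker × treatment
interaction the generator encodes.

The same steps are available as library calls (`simulate_cohort`,
`features_frame`, `call_sample_statuses`, `HrdsigClassifier`,
`cooccurrence_tests`, `OutcomeAnalysis`) and as per-stage CLI subcommands
(`hrdscar simulate|zygosity|features|train|predict|cooccur|outcomes`).

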