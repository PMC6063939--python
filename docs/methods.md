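# Methods

`phenoscore` asks a study-design question: *when the same cohort can be
phenotyped several ways from its electronic health records, which labeling
channel gives genetic association studies the most power?*  It answers it by
simulating a polygenic case/control cohort observed through imperfect
labeling channels, building a p-value-thresholded polygenic risk score (PRS)
under cross-validation for each channel, and comparing the channels by the
discriminative power of their scores.

## Generative model

**Genotypes.** Biallelic autosomal variants on a single pseudo-chromosome,
positions 1..m, alleles coded A/B with dosage counting the A allele.  Each
variant's allele frequency is drawn from Uniform(`maf_low`, `maf_high`)
(default 0.05–0.5) and genotypes are Binomial(2, f) per sample —
Hardy-Weinberg equilibrium by construction, no linkage disequilibrium.
With `n_subpops > 1`, the uniform draw becomes an ancestral frequency and
each subpopulation's frequency comes from the Balding–Nichols beta
distribution Beta(f(1−F)/F, (1−f)(1−F)/F) with F = `fst`; samples are
assigned to subpopulations in contiguous equal blocks.  Missing calls are
injected completely at random at `missing_rate` (default 2%) *after* the
disease is generated, so the phenotype reflects true genotypes while QC
sees realistic missingness.

**Disease.** A liability-threshold model: `n_causal` variants (default 50)
receive i.i.d. normal effects on the standardized dosage scale; the genetic
score is empirically rescaled to variance `h2_liability` (default 0.5); a
N(0, 1−h2) residual is added; disease status is liability above the
standard-normal quantile of 1−`prevalence` (default 5%).  The
liability-threshold model was chosen over a logistic-penetrance model
because it makes heritability a single interpretable knob and is the
standard generative model in statistical genetics.

**Labeling channels.** Each channel labels every sample independently:
true cases are labeled positive with probability `sensitivity`, true
non-cases with probability 1−`specificity`.  The defaults stand in for
three EHR extraction methods:

| channel       | sensitivity | specificity | emulates                        |
|---------------|------------:|------------:|---------------------------------|
| billing       | 0.95        | 0.90        | administrative billing codes    |
| problem_list  | 0.60        | 0.995       | clinician-curated problem list  |
| algorithm     | 0.80        | 0.995       | curated phenotyping algorithm   |

These numbers are design choices, not estimates from any dataset: published
chart-review validations consistently describe billing codes as sensitive
but unspecific and problem lists as specific but insensitive, and curated
algorithms are tuned for high positive predictive value.  At 5% prevalence
the billing channel's 10% false-positive rate swamps its case group
(~380 false vs ~190 true positives at n=4000), which is exactly the
mechanism that makes billing-trained PRS weak.

**Billing counts.** Billed patients receive 1 + Poisson extra occurrences,
with mean 2.0 for billed true cases and 0.3 for billed false positives, so
the positive predictive value of "billed at least t times" rises with t.
The two means are design choices giving a realistic PPV gradient (roughly
0.33 → 0.6 → 0.85 across t = 1, 2, 3 at the default prevalence).

## Pipeline

**QC** (in order): drop non-autosomal variants; call rate ≥ 0.90
(inclusive); minor allele frequency strictly > 0.01; Hardy-Weinberg exact
test at α = 1e-6 (the conventional GWAS threshold; the plain exact test —
the sum of probabilities of heterozygote configurations no more probable
than the observed one, conditional on allele counts — not the mid-p
variant); then LD pruning.  Pruning slides a 50-variant window advancing by
5 variants and repeatedly removes the variant with the largest variance
inflation factor (VIF = diagonal of the inverse window correlation matrix)
until all VIFs are below 10, for three full passes (a pass that removes
nothing is a fixed point, so later passes are skipped).  Ties on the
maximal VIF remove the lower-MAF variant, then the lower index — an
arbitrary but deterministic rule.  A 1e-8 ridge on the window correlation
matrix keeps exactly collinear duplicates finite (VIF ~1e8, removed first)
with bias O(1e-8·VIF²), invisible at the 10 threshold.  Missing dosages are
mean-imputed for correlation computation only.

**PCA.** Top-k components (default 2) of the standardized matrix
(d − 2f)/√(2f(1−f)), mean-imputed, computed once on the full QC'd panel and
reused across folds — per-fold PCA would triple the cost for no material
change in the components, but it does mean the PCs have seen the test
samples' genotypes (not their labels).  ARPACK with a fixed start vector
and a largest-|loading|-positive sign convention makes the result
deterministic.

**Association.** Per-variant logistic regression of the channel label on
the coded-allele dosage plus covariates, Wald test (matching the default
output of standard GWAS tools; not the likelihood-ratio test).  The solver
is a batched Newton-Raphson over all variants simultaneously — the
covariate block is shared, so each step reduces to elementwise work plus
thin matrix products.  Convergence is declared when the Newton decrement
(the second-order estimate of the remaining log-likelihood improvement)
drops below 1e-8, within 25 iterations; the final sub-tolerance step is
still applied, so single fits agree with reference optimizers to ~1e-8.
Quasi-complete separation is flagged by |log OR| > 25 or a Wald SE > 25;
such variants carry no estimate and are excluded from PRS weights and from
λ_gc.  Zero-variance dosage columns are skipped and flagged.  Missing
dosages are mean-imputed per variant (standard GWAS software instead drops
those individuals per variant; mean imputation keeps the design matrix
shared and is consistent with the scoring convention).  Batches above ~4M
genotype entries run in float32 — the elementwise pass is memory-bound and
the quadratic convergence criterion is insensitive to float32 rounding
(coefficients agree with float64 to ~1e-6); small problems keep float64.
λ_gc = median Wald chi-square / 0.45494 (the χ²₁ median).

**PRS.** Classic p-value thresholding: per-variant log ORs from the
training split are the weights; a cutoff selects the variants; each test
sample's score is the *mean* over selected variants of effect-allele
dosage × weight (the PLINK `--score` convention, which keeps scores
comparable across cutoffs with different variant counts).  Missing dosages
impute as 2 × training effect-allele frequency.  The default grid is 12
log-spaced cutoffs on [5e-5, 0.1], endpoints included.  Cross-validation is
stratified 5-fold on the *union-of-channels* case indicator, so every
channel shares the same train/test splits and their statistics are
comparable.  The reported cutoff is the one with the best fold-mean test
AUC; this selection-on-test is optimistically biased (all channels share
the bias, so the *comparison* is fair) and the result object carries a
`selection_bias_note` saying so.  External summary-statistics files
(variant id, effect allele, other allele, OR, p) are harmonized by allele:
a weight whose effect allele matches the panel's other allele is applied to
the complemented dosage; rows matching neither allele are dropped and
counted.

**Evaluation.** Per channel, on test folds only, against the channel's own
labels (controls are simply all samples the channel did not label positive;
no cross-channel exclusions): mean case-control PRS difference; AUC
(rank-based Mann-Whitney, ties half-credited); and odds ratio per standard
deviation (exponentiated logistic slope on the standardized score).  The
"(S.D.)" columns are sample standard deviations (n−1) across the five
folds.  Channels are ranked by fold-mean AUC; exact ties are reported as
ties.  The overlap report counts patients labeled positive by exactly one
channel, each pair, and all channels.  The billing-count sweep redefines
billing cases as "billed ≥ t times" for t = 1, 2, 3 and re-runs the CV
pipeline with the p-value cutoff *pinned to the one selected on the full
(t = 1) billing run* — per-fold weights are still retrained with the
subset's labels.  Evaluation against the simulated true status is also
available (`roc_auc(cv.scores_at_best(), true_status)`), since the
misclassification mechanism is what the comparison explains.

**Orchestration.** `run_all` derives one sub-seed per stage from the global
seed via `SeedSequence(seed, spawn_key=(stage,))` with documented stream
indices, hands everything between stages through plain files, and writes a
manifest with the config snapshot, per-stage counts and sha256 checksums of
every output; identical configs reproduce identical checksums.

## What the synthetic data does and does not show

The generator reproduces the *mechanisms* the comparison depends on —
misclassification diluting case groups, billing-count thresholds raising
PPV, population stratification inflating test statistics — but not several
features of real array data: linkage disequilibrium (variants are
independent, so LD pruning is exercised only by planted collinear blocks
and the clumping-vs-thresholding distinction is moot), genotyping batch
effects, informative missingness, relatedness, or channel errors that
correlate with disease severity or healthcare utilization (label errors
here are independent Bernoulli given true status).  Passing tests therefore
show the statistical machinery is correct and that the qualitative channel
ordering follows from the stated sensitivity/specificity assumptions — not
that any particular real-data AUC would be reproduced.

## Test battery problem sizes

Simulation-backed checks run at reduced sizes chosen to keep the default
`pytest` run to a few minutes on one CPU while preserving each property's
signal-to-noise:

- channel ranking: 6 replicates (seeds 0–5) at the full reference scale
  n=4000, m=5000.  The panel is kept at full size because the ordering
  margin between the two high-specificity channels tightens on smaller
  panels; QC is omitted inside this battery since it removes nothing from
  the clean simulated panel (no LD, MAF ≥ 5%, ~98% call rate) and is
  exercised by the determinism run and the QC tests;
- billing-count sweep: 8 replicates at n=2000, m=1200 (QC skipped; it is
  exercised elsewhere and the property concerns scoring);
- null calibration: one n=2000 × m=5000 cohort (5000 variants give a
  ±0.009 three-sigma band around the 5% type-I rate);
- structure adjustment: 10 replicates at n=2000, m=2000, fst=0.1, medians
  reported.  The scenario keeps the default sparse architecture (50 causal)
  deliberately: a much more polygenic trait maximizes confounding but its
  true signal alone holds the PC-adjusted λ_gc above 1.05, defeating the
  purpose of the diagnostic;
- misclassification ladder: 10 replicates at n=2000, m=800 over channels
  (1.0, 1.0) → (0.8, 0.95) → (0.6, 0.85), AUC measured against true status.

`scripts/acceptance.py` runs the headline study at the full reference scale
(n=4000, m=5000).

## Known limitations

- No LD simulation; pruning and clumping behave identically here.
- Selection of the p-value cutoff on test folds inflates the absolute AUCs
  (the nested alternative is available via `best_threshold_idx`).
- PCA sees test-sample genotypes (never labels); a fully nested variant
  would recompute PCs per fold.
- The per-variant exact HWE test loops over variants in Python; fine for
  1e4-variant panels, slow for array-scale data.
- Sample-level QC (per-individual missingness, relatedness) is not
  implemented; cohorts are assumed unrelated by construction.
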