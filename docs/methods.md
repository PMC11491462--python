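# Methods

## Repertoire quantification

A repertoire is a set of CDR3 beta-chain amino-acid strings with clone
counts. Quantification assigns each *unique* CDR3 to the RFU centroid
nearest in embedding space (squared Euclidean distance; exact ties go to
the lowest centroid index) and counts clonotypes per RFU, so a raw
abundance row always sums to the repertoire's unique-CDR3 count. A
read-weighted mode (summing clone counts instead) is available behind the
`weighted` flag of `RFUAssigner` but is not the default: whether cluster
abundance should be clonotype-based or read-weighted is genuinely open,
and clonotype counting matches the convention of reporting unique CDR3
chains per individual. Repertoires from multiple time points of one
individual are pooled by summing counts of identical CDR3s before
quantification; deeply sequenced repertoires can be truncated to the
top-N clones by count (boundary ties broken lexicographically) to make
cohorts comparable.

### CDR3 encoder

The embedding that originally defines RFU space is an external model; the
package therefore treats the encoder as a pluggable contract (`encode`,
`encode_many`, `dim`) with centroids always supplied as data, never
hard-coded. The default `AtchleyEncoder` places the five Atchley
physicochemical factors of each residue into a center-padded frame of
`max_length` = 25 positions (pad = zero vector) and appends a normalized
length feature, giving dimension 5·25 + 1 = 126. Sequences longer than
the frame are a hard error; 25 comfortably covers observed beta-chain
CDR3 lengths. Any centroid matrix produced by another encoder can be used
as long as the same encoder quantifies the repertoires.

## Quality control

Variant filters follow two named profiles: the discovery profile
(MAF > 0.05, Hardy–Weinberg p > 10⁻⁶) and the biobank profile
(imputation quality > 0.8, call rate > 0.95, MAF > 0.001, pHWE > 10⁻¹⁰).
All thresholds are strict inequalities; the filters are an intersection,
so order is irrelevant, and the report attributes each removal to the
first failing criterion (MAF, then pHWE, call rate, imputation quality).
The HWE test is the 1-df chi-square goodness of fit, returning p = 1 for
monomorphic variants.

Individual-level QC removes heterozygosity-rate outliers beyond ±3 SD of
the cohort mean (computed on the post-filter variant panel — which panel
the rate should use is unstated in general, so it is a documented choice),
relatives with KING-robust kinship φ̂ > 0.0884 (second degree or closer),
and individuals with strictly fewer than 2500 unique CDR3s. Kinship
pruning is greedy: the individual appearing in the most flagged pairs is
dropped first, ties broken by id order. KING-robust is
φ̂ = (N_het,het − 2·N_opp-hom) / (N_het(i) + N_het(j)); a self-comparison
gives exactly 0.5.

RFUs observed (abundance > 0) in at least 20% of individuals are retained
(inclusive boundary). Imputed HLA haplotype probabilities binarize at a
strict 0.7 threshold, and haplotype columns with carrier frequency ≤ 0.05
are dropped.

## Normalization and hidden-factor residualization

Association scans operate on a doubly normalized scale. Stage 1 quantile
normalizes each individual to the *average empirical distribution*: the
target vector is the mean of per-individual order statistics, each
individual's values are replaced by target values at their ranks, and
ties receive the mean of the target values they span. Stage 2 transforms
each RFU column to standard normal quantiles with the Blom offset,
Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties; the offset keeps
extreme ranks finite, which a plain r/n rule would not. The composition
depends only on within-individual ranks, so any strictly monotone
per-individual distortion of the raw counts leaves the output unchanged —
a property the tests assert directly. Columns that are constant after
stage 1 carry no rank information and are dropped with a warning.

Hidden-confounder adjustment emulates expression-residual (PEER-style)
factor correction with an explicit linear construction: OLS-residualize
every column on the known covariates (plus intercept; collinear columns
are dropped by rank-revealing QR with a warning), take the top *k*
principal components of the residual matrix as factor proxies, and freeze
an orthonormal basis of the joint nuisance space. `transform` removes the
projection onto that frozen basis, so the fitted operator is idempotent
and outputs are orthogonal to covariates and factors to machine
precision. *k* defaults to 2 (discovery-style); 8 suits noisier
validation-style data. This replaces a heavyweight Bayesian factor model
with a projection that preserves the contract actually relied on —
removal of dominant hidden structure; the planted-batch-factor test shows
residual correlation with a planted confounder below 0.05.

## rfuQTL scan

Each (variant, RFU) pair is tested by simple linear regression of the
residualized trait on dosage: β = S_xy/S_xx, with the t statistic on
n − 2 degrees of freedom (finite-sample t rather than a normal
approximation — negligible at these n, but fixed for reproducibility).
Traits are residualized once and scanned against raw predictors, the
standard two-step residual approach; at cohort sizes of interest this
agrees with per-test covariate adjustment to within a few percent in β.
Zero-variance predictors yield flagged NA records so downstream counts
remain auditable. Bonferroni bars divide the per-test α by
traits × predictor groups; the five standard bars (e.g. 5×10⁻⁸/4953 =
1.0×10⁻¹¹ genome-wide, 0.05/28/4953 = 3.6×10⁻⁷ for haplotypes) are
reproduced exactly at two significant figures. Annotation enrichment of
hit variants against interval tracks (BED input, converted to 1-based
half-open internally) uses the one-sided Fisher exact test; the
implementation is checked against exhaustive hypergeometric tail sums for
all margins up to 30. Cross-cohort replication is the Pearson correlation
of effect sizes over shared (predictor, trait) pairs.

## Genetic prediction (gdRFU)

Nine variant sets are built per scan: for each locus (TRB, HLA) and their
union, (a) all variants within a 1-Mb window of the locus span, (b)
variants carrying the locus label ("o"), and (c) the inclusive span from
first to last variant with any association p < 5×10⁻⁸ ("s"; empty when
nothing is significant).

Per RFU and variant set, a lasso (or elastic net, l1 ratio 0.5) is fit on
column-standardized dosages over a 100-point log-spaced penalty grid from
λ_max (the smallest all-zero penalty) down to λ_max·10⁻³. Ten-fold
cross-validation (fold assignment a deterministic function of seed and n)
selects the penalty maximizing the mean across folds of the squared
Pearson correlation between held-out predictions and the trait; the
reported cv *R*² is the squared correlation of the pooled out-of-fold
predictions at that penalty, and final weights are refit on all data.
Squared correlation (rather than one-minus-MSE) is the definition under
which the *R*² > 0.01 predictability call means "at least 10% correlation
between predicted and observed". Model selection across candidates takes
the highest cv *R*², ties broken by sparsity then variant-set label; the
predictability call is strict (> 0.01). Standardization statistics are
frozen at training and reused at prediction, and model variants missing
from a target cohort contribute zero after standardization (mean
imputation), with the lost absolute weight mass reported per individual.

Heritability is estimated by single-component REML on the variant-set GRM
A = ZZᵀ/m (Z column-standardized dosages): y ~ N(μ1, σ²_g A + σ²_e I),
profiled over h² = σ²_g/(σ²_g + σ²_e) on [0, 1] after one
eigendecomposition of A, with the estimate constrained to the boundary
rather than allowed negative, so h² is directly comparable with cv *R*²
as its upper bound. The standard error comes from the numerical curvature
of the restricted log-likelihood at the optimum. Benchmarks: simulated
h² = 0.4 (n = 800, m = 500, 20 replicates) is recovered within ±0.1, null
traits estimate near 0, and cv *R*² never exceeds h² + 0.1.

Weights export to a TSV (rfu_id, variant_id, ref, alt, weight, mean, sd)
with a JSON sidecar of intercepts, penalties and cv *R*²; floats are
written at full precision (`repr`), so import→predict is bit-identical to
the in-memory model.

## Phenome and survival association

Binary traits are residualized on covariates once (the same projection
machinery as the trait pipeline with zero hidden factors) and regressed
on each gdRFU with a linear model — a valid test whose effect size is on
the linear-probability scale, not an odds ratio; this mirrors the
TWAS-style workflow the package emulates. Traits with fewer than 20 cases
are skipped with a warning. Significance is Bonferroni over the full
(traits × RFUs) grid. Category enrichment of significant associations is
a chi-square against proportional allocation over disease categories
(Fisher fallback when an expected cell drops below 1); cell-type
enrichment compares each compartment's association fraction against the
remaining annotated RFUs with a one-sided Fisher test, optionally
restricted to pathogenic (positive-β) associations.

Survival uses Cox proportional hazards via lifelines (Efron ties —
the tie convention is a free choice, and Efron is fixed here as the better
default) with
covariates, per (cancer, gdRFU), restricted to cancers with at least 130
events (inclusive); gdRFUs are standardized within each cancer cohort so
log HR is per SD. Non-convergent fits are flagged records, never silently
dropped. q-values are Benjamini–Hochberg across all tests, significant at
q < 0.05. The implementation is cross-checked against an independent Cox
fit (scikit-survival) on tie-free data to 10⁻⁴ in log HR, and a planted
HR = 1.5 (n = 2000, 20% censoring) is recovered within 15% on the log
scale averaged over seeds.

## Annotation

CD4/CD8 labels require a one-sided paired Wilcoxon signed-rank p < 0.05
in *both* sorted datasets with the direction fixed by the first dataset's
median difference; fewer than six pairs leaves the test degenerate.
Subset labels (TN/CM/Treg/Tscm) use a Friedman test per RFU at the
Bonferroni bar 0.05/n_tested (0.05/1351 = 3.7×10⁻⁵ at cohort scale),
labelling by the highest-median subset and refusing ties. Antigen
specificity maps database CDR3s through the same nearest-centroid
assignment; an RFU inherits every antigen whose sequence lands in it.
Prioritization tests whether pathogenic disease-associated RFUs are
enriched for antigen specificity: a one-sided rank comparison of
association z-scores (the association test statistic serves as the
z-score) plus per-N Fisher tests of the specific-RFU count among the top
N associations — the unpaired rank-sum test, since the two groups are
independent samples. The differential-expression contrast between
sample groups restricts to the 2000 highest-variance genes, uses
median-ratio fold changes (zero reference medians flagged), unpaired
rank-sum p-values with Bonferroni adjustment, and calls significance at
strictly fold change > 2 (or < 1/2) and adjusted p < 0.05.

## Synthetic cohort generator

The generator defines the conditions every test runs under.

* **Genotypes.** Dosages ~ Binomial(2, p) per variant with
  p ~ Uniform(maf_range = (0.05, 0.5)), i.e. Hardy–Weinberg proportions,
  at a TRB-like locus (chromosome 7, ~142 Mb) and an HLA-like locus
  (chromosome 6, ~29.6 Mb), 2 kb apart. No linkage disequilibrium or
  ancestry structure is modelled — downstream methods never rely on it.
* **Effects.** Exactly `n_causal_variants_per_rfu` (default 3) variants
  per RFU receive Normal(0, 0.5²) effects on latent log-abundance; the
  causal sets are recorded for recovery tests. The sparse architecture
  matches what penalized regression assumes.
* **Repertoires.** λ_r = base_r + Σ_v dosage·effect + Normal(0, 0.1)
  noise; clone counts ~ Multinomial(size, softmax(λ)) with size uniform
  in `repertoire_size_range` (default 5 000–20 000 unique clonotypes,
  bracketing the observed per-individual scale). No generative model for
  abundance-given-genotype exists upstream; the log-linear/softmax choice
  is this package's stand-in and produces compositional counts consistent
  with the quantification contract. Each multinomial draw becomes one
  unique clonotype: a 1–2-residue substitution mutant of its RFU's
  template CDR3, verified to re-assign to the intended centroid and
  deduplicated (later resampling rounds widen the mutation count so the
  mutant space cannot be exhausted; a stubborn remainder falls back to
  the template itself). The verified round trip guarantees ≥95% — in
  practice ~100% — encoder→centroid recovery.
* **Phenotypes.** Disease ~ Bernoulli(logistic(logit(prevalence) +
  disease_effect·z + 0.2·sex + 0.01·(age − 55))), z the standardized
  genetic value of the driver RFU; survival ~ Exponential with hazard
  h₀·HR^z and independent Exponential censoring tuned so the expected
  censored fraction equals `censoring_rate` at z = 0. Covariates are
  sex ~ Bernoulli(0.5), age ~ Uniform(40, 70), five synthetic
  PCs ~ N(0, 1) — the covariate lists of a real analysis without
  population-structure machinery.
* **Sorted subsets / antigen database.** Subset repertoires draw from
  softmax(base + log propensity) with per-subset propensity vectors
  (ground truth recorded); the antigen table contains verified template
  mutants for designated RFUs, optionally with multiple antigen labels
  per RFU.
* **Determinism.** Every artifact draws from its own named RNG substream
  of the master seed (`SeedSequence`-style keying on a CRC of the stream
  name), so identical configurations are bit-identical and adding an
  artifact never perturbs the others.

What the generator does **not** emulate: linkage disequilibrium and
realistic V(D)J generation (IGoR-style), ancestry structure, antigen
exposure history, sequencing error, or the true RFU embedding geometry.
Passing tests therefore certify the statistical machinery — calibration,
recovery, heritability bounds, multiple-testing control — under the
assumed generative model, not performance on real repertoires, where
unmodelled confounding and embedding mismatch will reduce predictability.

## Numerical choices and benchmark sizes

Tolerances: scan oracle agreement to 10⁻⁸ in β; Fisher vs hypergeometric
to 10⁻⁹; Cox vs external reference to 10⁻⁴ in log HR; residualization
idempotence and monotone-distortion invariance to 10⁻¹⁰; weight
round-trip exact. Degenerate inputs fail loudly (constant traits,
monomorphic-only GRMs, empty variant overlap) or produce flagged records
(zero-variance predictors, non-convergent Cox fits, empty repertoires).

The validation suite (`rfuwas.benchmarks`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses desk-scale
versions of a cohort-scale design: null-scan calibration at n = 500 with
~6 000 tests; heritability recovery at n = 800, m = 500 over 20
replicates; prediction recovery at n = 600, m = 150 over 10 seeds;
phenome recovery at n = 20 000 (10 effect seeds, 20 null seeds of
50 RFUs × 27 traits); survival recovery at n = 2 000 over 10 seeds plus
50 null seeds. These sizes are chosen so each benchmark has the power to
certify its property while the whole suite runs in about a minute.

## Known limitations

* The default encoder is a physicochemical stand-in; absolute RFU
  assignments are only meaningful relative to centroids built with the
  same encoder.
* Binary-trait effects are on the linear-probability scale; no
  logistic/SPA association is provided.
* REML is single-component; partitioned or LD-aware heritability is out
  of scope, as are mixed-model association, fine-mapping and
  colocalization.
* The null phenome family-wise check operates exactly at its nominal 5%
  family-wise error level, so the zero-hit fraction across 20 seeds sits
  near its 0.95 criterion by construction rather than comfortably above
  it.
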