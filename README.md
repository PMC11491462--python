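# rfuwas

Genetic prediction of T-cell receptor (TCR) repertoire components and
phenome-wide association of the predicted abundances.

## The problem

The TCR beta-chain repertoire is shaped by germline variation: variants in
the TRB locus bias V(D)J recombination, and HLA alleles shape thymic
selection. This package quantifies a repertoire into **repertoire
functional units (RFUs)** — clusters of CDR3 amino-acid sequences with
similar embedding coordinates — and treats each RFU's abundance as a
heritable molecular trait, in the mold of transcriptome-wide association
studies:

1. **Quantification.** Each unique CDR3 is assigned to its nearest RFU
   centroid in an embedding space (Euclidean distance, lowest-index
   tie-break); the abundance of RFU *r* is the number of unique clonotypes
   assigned to it.
2. **rfuQTL scan.** After two-stage normalization (per-individual quantile
   normalization to the average empirical distribution, then per-RFU
   inverse-normal transform) and residualization on covariates plus hidden
   factors, each variant–RFU pair is tested with a simple linear
   regression; significance uses Bonferroni bars such as
   *P* < 5×10⁻⁸/4953 = 1.0×10⁻¹¹.
3. **gdRFU models.** For each RFU, cross-validated lasso (or elastic-net)
   regression on locus-based variant sets predicts abundance from
   genotype. An RFU with cross-validated *R*² > 0.01 is *predictable*;
   single-component REML heritability *h*² from the variant-set GRM is the
   accuracy ceiling. Sparse weights serialize to TSV and impute
   **genetically determined RFU (gdRFU)** abundances into any genotyped
   cohort.
4. **RfuWAS.** gdRFUs are scanned phenome-wide against binary
   (phecode-style) traits with covariate-residualized linear models, and
   against cancer survival with Cox proportional-hazards models
   (Efron ties, BH-FDR). Positive effects on disease are *pathogenic*,
   negative *protective*.
5. **Annotation.** RFUs are labelled by T-cell compartment (paired
   Wilcoxon CD4/CD8 rule replicated across two sorted datasets; Friedman
   test across TN/CM/Treg/Tscm subsets) and by antigen specificity
   (database CDR3s of known specificity mapped through the same
   nearest-centroid assignment), and antigen-specific RFUs are prioritized
   by association strength.

Everything runs on a first-class synthetic cohort generator
(`rfuwas.simulate`): Hardy–Weinberg genotypes at TRB-like and HLA-like
loci, sparse variant effects on latent log-abundances, multinomial
repertoires around centroid templates (with verified nearest-centroid
round trips), logistic-link diseases and proportional-hazards survival
driven by gdRFU components. No external data are required.

## Worked example

```python
import numpy as np
import rfuwas as rw

cfg = rw.SimulationConfig(
    n_individuals=400, n_rfus=20,
    n_variants_per_locus={"TRB": 60, "HLA": 40},
    repertoire_size_range=(800, 1200),
    effect_size_sd=0.5, disease_effect=1.0, seed=7,
)
g = rw.simulate_genotypes(cfg)
effects = rw.simulate_rfu_effects(cfg, g)
centroids, templates = rw.simulate_centroids(cfg)
reps = rw.simulate_repertoires(g, effects, centroids, cfg, templates)

raw = rw.RFUAssigner().fit(centroids).transform(reps)
cov = rw.simulate_covariates(cfg, raw.individual_ids)
traits = rw.normalize_pipeline(rw.filter_rfus(raw), cov, n_hidden_factors=2)

scan = rw.association_scan(g, traits)
sets = rw.build_variant_sets(g, scan)
rfu = scan.loc[scan["p"].idxmin(), "rfu_id"]
model = rw.select_best_model([rw.fit_penalized_model(
    g.dosages[sets["TRB+HLA_window1mb"]], traits.data[rfu].to_numpy(),
    seed=1, rfu_id=rfu, variant_set="TRB+HLA_window1mb")])
h2 = rw.estimate_heritability(
    rw.compute_grm(g.dosages[sets["TRB+HLA_window1mb"]]),
    traits.data[rfu].to_numpy())

gdrfu = rw.latent_genetic_values(g, effects)
pheno = rw.simulate_phenotypes(gdrfu, cfg, driver_rfus=("RFU3",), n_null_traits=4)
assoc = rw.phenome_scan(gdrfu, pheno, min_cases=5)
surv = rw.cox_scan(gdrfu[["RFU3"]], pheno,
                   covariates=pheno.covariates[["sex"]], min_events=50)
```

This prints (via the obvious f-strings):

```
cohort: 400 individuals, 998 unique CDR3s each
traits: 20 RFUs after prevalence filtering
rfuQTL scan: 2000 tests, 33 significant at p < 2.5e-09
RFU6: cv R^2 = 0.748 (33 variants), REML h^2 = 0.788, predictable = True
phenome scan: top association disease_RFU3 ~ RFU3 (beta = 0.185, p = 6.26e-10)
survival: log HR = 0.355 (HR = 1.43), q = 3.78e-11, events = 332
```

Reading the numbers: 33 variant–RFU pairs clear the Bonferroni bar
(5×10⁻⁸ divided by the 20 tested RFUs); the most associated RFU is well
predicted from genotype (cv *R*² = 0.75) and stays below its REML ceiling
(*h*² = 0.79); the disease planted on RFU3 is recovered as the top phenome
association; and the planted hazard ratio of 1.5 per SD is estimated at
1.43.

The same workflow is scriptable from the shell:

```bash
rfuwas simulate --config config.yaml --out sim/
rfuwas quantify --repertoires sim/repertoires.tsv --centroids sim/centroids.tsv --out raw.tsv
rfuwas normalize --abundance raw.tsv --covariates sim/covariates.csv --out resid.tsv
rfuwas qtl --traits resid.tsv --genotypes sim/genotypes.tsv --out scan.tsv
rfuwas train --traits resid.tsv --genotypes sim/genotypes.tsv --scan scan.tsv --out weights.tsv
rfuwas predict --weights weights.tsv --genotypes sim/genotypes.tsv --out gdrfu.tsv
rfuwas scan --gdrfu gdrfu.tsv --pheno sim/phenotypes.csv --covars sim/covariates.csv --out assoc.tsv
```

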