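# p53pds

Sample-level **p53 deficiency scores (PDS)** from tumor transcriptomes.

Loss of p53 pathway activity is one of the most common events in cancer,
but TP53 mutation status alone is a coarse readout: pathway function can be
lost without a mutation and partially retained with one. `p53pds` infers a
continuous, per-sample measure of p53 pathway deficiency from gene
expression and evaluates its prognostic and drug-sensitivity associations.
It is aimed at computational cancer biologists who have a gene-by-sample
expression matrix, binary TP53 protein-altering mutation calls, and
(optionally) survival or drug-response data.

## Method

**Signature construction.** For each gene *g*, a univariate logistic
regression is fitted with the gene's standardized expression as covariate
and mutation status (1 = mutant) as outcome. With likelihood-ratio p-value
*p<sub>g</sub>* and slope β<sub>g</sub>, the gene's weight is

&nbsp;&nbsp;&nbsp;&nbsp;*w<sub>g</sub>* = min(−log₁₀ *p<sub>g</sub>*, 10) / 10 ∈ [0, 1],

and genes split into an **up profile** (β<sub>g</sub> > 0, expression higher
in mutants) and a **down profile** (β<sub>g</sub> < 0). Uncorrelated genes
keep small weights; they are not thresholded away.

**Scoring.** For each sample, genes are ranked by expression (descending,
ties broken by gene id). For a weight profile listed in that order, the
enrichment score compares the cumulative foreground
F(i) = Σ<sub>j≤i</sub> w<sub>j</sub> / Σ w against the cumulative
background B(i) = Σ<sub>j≤i</sub> (1−w<sub>j</sub>) / Σ (1−w):

&nbsp;&nbsp;&nbsp;&nbsp;ES = F(i\*) − B(i\*),&nbsp; i\* = argmax |F − B|,

normalized by the mean |ES| over random permutations of the weights across
rank positions (NES). The deficiency score is
**PDS = NES<sub>up</sub> − NES<sub>down</sub>**; a higher score means lower
inferred p53 activity.

**Evaluation.** Median or top-fraction splits feed log-rank tests and
Kaplan–Meier curves; univariate Cox regression (Efron ties) runs on the
continuous score; per-dataset Cox z-scores combine across datasets by the
sample-size-weighted Stouffer method, meta-z = Σ nᵢzᵢ / √Σ nᵢ²; AUC against
mutation status uses Mann–Whitney concordance; drug Activity Area is
compared between deficiency groups with a two-sided Student's t-test.

A synthetic-cohort generator (`p53pds.synthetic_data`) produces expression,
mutation, survival and drug-response tables with known planted structure,
so the whole pipeline is testable without any external downloads.

## Worked example

```python
import p53pds as P

cfg = P.SimulationConfig(n_genes=500, n_up=25, n_down=25, effect=1.0,
                         n_samples=120, surv_log_hr=0.5, seed=7)
cohort = P.simulate_cohort(cfg)

assocs = P.fit_gene_associations(cohort.expression, cohort.mutations)
sig = P.build_signature(assocs, cancer_type_label="synthetic")
print(f"signature: {len(sig.up_weights)} up genes, {len(sig.down_weights)} down genes")

scores = P.pds_series(P.compute_pds(cohort.expression, sig, n_perm=1000, seed=17))
roc = P.auc_vs_mutation(scores, cohort.mutations)
print(f"AUC vs TP53 status: {roc.auc:.3f} ({roc.n_pos} mutant / {roc.n_neg} wild type)")

cox = P.cox_univariate(scores, cohort.survival)
print(f"Cox: HR {cox.hr:.3f} per score unit, z = {cox.z:.2f}, p = {cox.p:.2e}")

lr = P.logrank_test(P.split_by_median(scores), cohort.survival)
print(f"log-rank (median split): chi2 = {lr.chi_square:.2f}, p = {lr.p:.3g}")
```

prints

```
signature: 268 up genes, 232 down genes
AUC vs TP53 status: 1.000 (56 mutant / 64 wild type)
Cox: HR 1.178 per score unit, z = 4.55, p = 5.48e-06
log-rank (median split): chi2 = 18.87, p = 1.4e-05
```

The cohort plants a 1-SD expression shift on 50 of 500 genes in mutants and
a hazard increasing in true deficiency, so the fitted signature separates
mutants perfectly (AUC 1.000) and the score is strongly prognostic: each
score unit multiplies the hazard by 1.18, and the high-deficiency half of
the cohort dies significantly earlier.

The same pipeline is available from the shell:

```bash
p53pds simulate --out-dir cohort/ --seed 7
p53pds build-signature --expr cohort/expression.tsv --mutations cohort/mutations.tsv --out sig.tsv
p53pds score --expr cohort/expression.tsv --signature sig.tsv --out pds.tsv
p53pds survival --scores pds.tsv --clinical cohort/survival.tsv --split median --out surv.json
p53pds evaluate auc --scores pds.tsv --mutations cohort/mutations.tsv --out auc.json
p53pds meta --manifest datasets.tsv --out meta.json
```

Every output gets a `.meta.json` sidecar recording version, parameters and
seed.

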