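# mirpair

Integrative analysis of matched tumor–normal miRNA-Seq and RNA-Seq cohorts:
consensus differential expression with per-patient consistency filters,
canonical seed-site target prediction with regression context scoring,
anticorrelated miRNA–gene pairing, hallmark-style gene-set enrichment, and
percentile-group survival stratification.

The package is aimed at transcriptomics analysts who have feature-by-sample
count matrices for tumor and normal tissue from the *same* patients and want
a stringent, auditable path from raw counts to candidate
miRNA → target-gene regulatory relations. Every stage can also run on
synthetic data with planted ground truth, so the whole pipeline is testable
without any external download.

## The method

**Consensus differential expression.** For each feature (miRNA or gene),
three statistics are computed on the matched design: a moderated paired
*t* on per-patient log2 fold changes `d_p = logCPM_tumor(p) − logCPM_normal(p)`
with empirical-Bayes variance shrinkage (per-feature variances s² modeled as
scaled-χ² around a prior (s₀², d₀) estimated by moment matching on log s²);
a Wilcoxon signed-rank test on the same `d_p`; and a negative-binomial Wald
test on raw counts, `log μ = β₀ + β₁·tumor + log libsize`, with Pearson-moment
dispersion shrunk 50/50 toward a trended mean–dispersion fit. Benjamini–
Hochberg q-values are computed per statistic, and a feature survives the
consensus only if **all three** give q ≤ 10⁻⁵. Two per-patient consistency
criteria then apply: the direction of change must agree in **more than 80%**
of patients, and **at least 70%** of patients must show a ≥ 2-fold change
(|d_p| ≥ 1). miRNA mode additionally requires overall mean logCPM ≥ 3;
mRNA mode instead requires |mean logFC| > 0.5 and relaxes the consistency
fractions by 10 percentage points (70% / 60%).

**Target prediction.** Canonical seed sites are scanned in 3′UTRs — with
miRNA positions numbered 1..n from the 5′ end, a 7mer-m8 site is the reverse
complement of positions 2–8, a 7mer-A1 site is the reverse complement of
positions 2–7 followed by an A, and an 8mer is both. Each site gets four
context features: local AU content of the ±30 nt flanks, log₁₀ UTR length,
log₁₀(1 + target-site abundance across the UTR universe), and seed-pairing
stability from nearest-neighbor thermodynamics. A multiple linear regression
combines them into a repression score; mRNAs whose summed site score is
below −0.3 are putative targets. Predicted relations are merged with
validated knowledgebase lists and with prediction-program lists (kept when
≥ 3 programs agree) into one target map with provenance.

**Integration, enrichment, survival.** Anticorrelated pairs are the
cross-join of DE miRNAs × DE genes filtered to opposite tumor-vs-normal
directions and target-map support. Directional gene queries are tested for
over-representation in gene sets by the upper-tail hypergeometric with BH
correction. Survival cohorts are stratified into bottom/top expression
percentile groups and compared by the Kaplan–Meier product-limit estimator
(Greenwood standard errors) and the two-group log-rank test.

## Worked example

The demo generates every input synthetically — negative-binomial matched
counts with planted fold changes, sequence universes with planted seed
sites, target lists, gene sets and a survival cohort — then runs all stages:

```bash
mirpair all --demo --seed 11 --outdir demo_out
```

```
[demo] generating synthetic inputs
[de_mirna] n_called=30, input=300, prefilter=300, consensus=43, called=30
[de_mrna] n_called=40, input=400, prefilter=400, consensus=40, called=40
[targets_mlr] n_relations=457
[targets_merge] n_relations=885
[pairs] n_pairs=125, n_mirnas=30, n_mirnas_up=18, n_mirnas_down=12, n_genes=40, n_genes_up=17, n_genes_down=23
[enrichment] n_rows=200, n_sets=50
[survival] chi_square=2.1149, p_value=0.14587095598978522
```

Reading the log: of 300 simulated miRNAs, 43 pass the three-way FDR
consensus and 30 survive the expression gate and per-patient consistency
filters (the demo plants 10% DE features at |log2FC| ∈ [2, 3]); the called
set splits 18 up / 12 down in tumor. The merged target map holds 885
(miRNA, gene) relations from the regression scorer, a validated list and
four prediction programs; intersecting it with the 30 DE miRNAs and 40 DE
genes under the opposite-direction rule yields 125 anticorrelated pairs.
Outputs land in `demo_out/` as TSVs (`de_mirna.tsv`, `pairs.tsv`,
`enrichment.tsv`, `km_curves.tsv`, …) plus `run_manifest.json` with input
hashes and row counts; re-running with the same seed reproduces it exactly.

Individual stages run standalone, e.g. percentile-group survival on a
simulated 200-subject cohort with a planted hazard ratio of 3:

```bash
mirpair survive --table cohort.tsv --low-pct 0.25 --high-pct 0.25 --out km.tsv
# log-rank chi2=16.1431 p=5.87e-05
```

As a library:

```python
from mirpair import SimCountParams, simulate_paired_counts, select_de_features, DEConfig

counts, truth = simulate_paired_counts(SimCountParams(n_pairs=48, seed=1))
result = select_de_features(counts, DEConfig.mirna())
print(result.step_counts)          # features surviving each step
print(result.called[["feature_id", "avg_logfc", "direction"]].head())
```

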