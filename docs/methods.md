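# Methods

This note records the statistical models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate.

## Matched-pair count model

All differential-expression machinery assumes one tumor and one normal
sample per patient. The working model for a count of feature *i* in sample
*s* (patient *p*, condition *c* ∈ {0 = normal, 1 = tumor}) is negative
binomial with

    log μ_is = log(L_s · ρ_i) + a_p + c · λ_i · log 2,
    Var = μ + α μ²,

where `L_s` is the library size, `ρ_i` the relative abundance, `a_p` a
patient factor shared *exactly* by the patient's two samples, `λ_i` the
log2 fold change, and `α` the dispersion. The shared patient factor is what
makes per-patient fold changes informative: it cancels in
`d_p = logCPM_T(p) − logCPM_N(p)`, so the paired statistics and the
consistency filters see only the condition effect plus count noise. The
synthetic generator draws from exactly this model, which also defines its
limits (below).

## The three DE statistics

The consensus framework is test-agnostic; it ships three statistics
implemented from standard published formulas rather than wrapping the
R packages commonly used for this task. The contribution being exercised is
the consensus-plus-consistency construction, not any one test's internals.

1. **Moderated paired t.** Per-feature variances s² of the `d_p` (df
   d₁ = n−1) are modeled as scaled-χ² around a prior (s₀², d₀). The prior is
   estimated by moment matching on log s²: with z = log s²,
   E[z] and Var[z] involve digamma/trigamma terms of d₁/2 and d₀/2, so d₀
   solves a trigamma equation (Newton inversion) and s₀² follows from the
   mean. The posterior variance (d₀s₀² + d₁s²)/(d₀+d₁) feeds
   t = mean(d)·√n / s_post with d₀+d₁ df. When the observed spread of log s²
   is no larger than the χ² sampling noise, d₀ → ∞ and all features share
   s₀².
2. **Wilcoxon signed-rank** on the `d_p`: exact null for ≤ 25 evaluable
   pairs, otherwise the normal approximation with continuity correction.
   Zeros are dropped; an all-zero feature gets p = 1. This is the robust
   member of the trio — it answers sign-and-rank questions only.
3. **NB Wald.** With only an intercept, a condition effect and library-size
   offsets, the group rate estimate is closed-form: total group counts over
   total group library size (plus 0.5 as a continuity guard), and
   β₁ = log(r_T/r_N). Dispersion per feature solves the Pearson moment
   equation Σ (y−μ)²/(μ(1+αμ)) = S−2 (α = 0 if even Poisson is
   overdispersed relative to the data), and is then shrunk 50/50 toward a
   trend obtained by binning features on mean expression and averaging the
   raw estimates — a deliberately loess-free trend fit. The Wald variance is
   the delta-method variance of the log group-total rate,
   (Σμ + αΣμ²)/(Σμ)² per group. This matters: the group-total rate is a
   count-weighted ratio estimator, not the information-weighted MLE, and
   its variance exceeds the NB Fisher bound whenever library sizes vary
   across samples. Using the Fisher bound here produces a ~5–10%
   anti-conservative z under realistic library-size spread; the ratio
   variance restores null uniformity (measured as KS distance ~0.02 at
   2000 features × 48 pairs).

BH q-values are computed per statistic (statsmodels' step-up); the consensus
requires q ≤ `fdr_threshold` under all three.

### Consistency criteria and gates

With N evaluable pairs, a feature passes when (a) the majority direction
covers strictly more than `direction_frac·N` pairs, and (b) at least
`fold_frac·N` pairs show |d_p| ≥ log2(`fold_threshold`). The asymmetry
(strict > for (a), ≥ for (b)) mirrors the wording of the filtering rules the
defaults come from; both comparisons are configurable. A per-pair fold
change of exactly 0 counts against both criteria, and a tie between up and
down majorities fails (a) — these conventions make degenerate inputs
deterministic. Defaults: FDR 10⁻⁵; miRNA mode 0.80/0.70 with a mean-logCPM
≥ 3 gate; mRNA mode 0.70/0.60 with a |mean logFC| > 0.5 gate ("relaxed by
10" read as percentage points). The low-expression prefilter keeps features
with CPM > 1 in ≥ 25% of samples — a standard choice where only "initial
filtering" is specified.

### Where quantile normalization sits

`quantile_normalize` maps every column onto the mean-of-sorted-columns
reference; ties take the mean of the reference values their rank span
covers (deterministic). It is applied to logCPM. The pipeline emits the
quantile-normalized miRNA abundance matrix as the reported quantification,
but by default the tests and the consistency criteria run on plain logCPM,
for two reasons: the count-based tests consume counts or per-pair logCPM
differences by construction, and QN is structurally unable to express
upregulation of a feature already at the top abundance rank (its tumor and
normal values both map to the reference maximum, so the fold change
collapses — we observed planted log2FC of −2.4 reported as −1.1 on small
matrices). `DEConfig.quantile_norm = True` switches the DE path onto QN
values for users who want the alternative reading.

logCPM uses value = log2((count + 0.5)/(libsize + 1)·10⁶): the pseudocount
avoids log 0 and keeps the transform monotone within a sample.

## Seed sites and the repression regression

Site patterns (miRNA positions 5′→3′, 1-based): 7mer-m8 = reverse
complement of positions 2–8; 7mer-A1 = reverse complement of positions 2–7
followed by A (the A faces position 1 regardless of its identity); 8mer =
both. 6mer sites are excluded as weak-effect noise. One locus reports one
type (8mer > 7mer-m8 > 7mer-A1); a 7mer-m8 followed by A is the 8mer at the
same offset, a 7mer-A1 preceded by the position-8 complement is the tail of
the 8mer one base earlier. Coordinates are 0-based half-open on the UTR
plus strand; UTRs arrive already stranded. T is normalized to U on input.

Context features per site:

* **AU content** — fraction of A/U in the 30 nt flanks each side (truncated
  at UTR ends; denominator is bases actually present). 30 nt unweighted is
  the canonical local-AU convention; the window is configurable.
* **UTR length** — log₁₀ nt.
* **Target-site abundance** — log₁₀(1 + count of the miRNA's 7mer-m8 match
  over the whole UTR universe, overlaps included); the +1 guards empty
  universes.
* **Seed-pairing stability** — sum of RNA nearest-neighbor stacking free
  energies (kcal/mol, 37 °C, Turner-group Watson–Crick parameters bundled
  in `targets.NN_STACK_DG37`) over the six stacks of the 7-bp seed duplex,
  assuming perfect Watson–Crick pairing and not counting G:U. Always ≤ 0;
  more negative = stabler. Helix initiation is omitted — only relative
  stability across seeds matters to the regression.

The MLR score is intercept + coefficients·(AU, len, TA, SPS); site scores
sum to the mRNA level (configurable to `min`), and summed score < −0.3
calls a putative target. The shipped default coefficients
(−0.40, 0.05, 0.10, 0.02) are **synthetic-fit**: the regression this scorer
descends from does not publish its coefficients, so the defaults were fit
once on this package's own repression generator and are labeled as such.
Their signs encode the expected biology: AU-rich context means stronger
repression (more negative score); longer UTRs and higher TA dilute
repression; and since SPS is itself negative for stable seeds, its small
positive coefficient makes stabler seeds score more negative, i.e. more
repressive. `fit_mlr_coefficients` refits by OLS (statsmodels) and rejects
singular designs; ≥ 20 rows are required.

Knowledgebase merging keeps every validated relation, keeps predicted
relations supported by ≥ 3 programs, and imports scored (TargetScan-style)
lists at score > 0.2. That published cutoff is sign-inverted relative to
the usual context-score convention (more negative = stronger repression),
so the comparison direction is configurable (`ts_comparison`) rather than
silently resolved.

## Enrichment and survival

Over-representation is the upper-tail hypergeometric P(X ≥ k) with
population N = universe, successes K = set ∩ universe, draws n = query;
BH within one query direction. The default universe is the set of genes
passing the DE prefilter (expressed genes), the standard choice; depletion
is not tested. Up- and down-regulated queries, and their restrictions to
the gene side of the anticorrelated pairs, form four separate families.

Percentile grouping sorts by expression and takes the bottom
floor(low_pct·n) and top floor(high_pct·n) subjects; boundary ties break by
stable input order. KM is the product-limit estimator over distinct event
times with Greenwood variance S²·Σ d/(n(n−d)); times with only censorings
shrink the risk set silently. An event tied with a censoring at the same
time counts first (the censored subject stays in that risk set). The
log-rank p comes from the asymptotic χ²₁ (lifelines' two-group test); no
permutation option, matching common survival-portal practice.

## The synthetic generators — what they emulate and what they don't

Defaults are the study conditions the package is exercised under: 48
matched pairs, 2000 features after filtering, 5% planted DE at
|log2FC| ∈ [1.5, 3], NB dispersion 0.1, patient factor SD 0.3 (natural
log), library sizes uniform in 0.8–1.2 M, baseline abundance spanning 8
log2 units of relative weight. The demo uses 300 miRNA features — a
realistic post-filter mature-miRNA matrix; quantile normalization over far
fewer features compresses ranks so coarsely that planted fold changes are
destroyed, which is an artifact of tiny matrices rather than of any method.
The sequence generator plants exact site patterns into uniform-random UTRs
(flank bases adjusted so a planted 7mer is not accidentally an 8mer, and
planted spans never overlap); the survival generator draws exponential
times for two latent half-cohorts with hazard ratio HR and ties expression
to the latent group so percentile stratification can recover it.

What passing tests therefore show: the pipeline recovers truth planted
*under its own model assumptions*, its null behavior is calibrated, and its
set logic is exact. What they do not show: robustness to features real data
has and the generators omit — batch effects, isomiR structure, dispersion
that varies with biology rather than a trend, heavy-tailed abundance with a
few features taking most of the library, informative censoring, or
correlated miRNA–mRNA noise. Headline counts from any specific cohort
(numbers of DE features, pairs, enriched sets) depend on that cohort and on
external target databases, and are not reproduced here.

## Numerical conventions and problem sizes

* One `numpy.random.default_rng` per generator call, seeded by one integer;
  identical seeds give byte-identical outputs, including FASTA text.
* Trigamma inversion by Newton on the trigamma scale (50 iterations,
  relative tolerance 10⁻⁸); dispersion Newton solves run 40 vectorized
  iterations clipped to [10⁻¹⁰, 10⁴].
* Variances are floored at 10⁻¹² before logs; a feature with all-zero
  per-pair fold changes gets t = 0, p = 1.
* Quantile-normalization ties use cumulative sums of the reference, so tied
  spans are averaged exactly, and the transform is idempotent to 10⁻¹⁰.
* The acceptance script runs 2000 × 48 cohorts (≈ 1 s per pipeline pass),
  100 null replicates, and 1000 log-rank replicates at n = 200 — sizes
  chosen so the whole script completes in about two minutes on one CPU
  while keeping Monte-Carlo error well below the decision margins.

## Known limitations

* The NB test ignores the pairing (the paired information lives in the
  other two statistics and the consistency filters); a paired NB GLM would
  need per-patient nuisance parameters and is out of scope.
* Seed matching is exact Watson–Crick only: no G:U seeds, no 3′
  supplementary or compensatory sites, no ORF/5′UTR sites, no conservation
  or structural accessibility features.
* SPS uses stacking terms only; absolute free energies are therefore offset
  from duplex ΔG° values, by design.
* The Wilcoxon exact/approximate switch at n = 25 creates a small p-value
  discontinuity across cohort sizes near the switch.
* `assign_percentile_groups` uses floor sizing, so low_pct + high_pct = 1
  can still exclude up to two subjects.
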