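# Methods

## The analysis

The package implements a geneset-restricted, vote-counting meta-analysis of
COPD transcriptomics. The unit of evidence is a (gene, cohort) significance
call; cohort-level calls are then counted, never pooled: there is no effect
pooling, heterogeneity modelling, or covariate adjustment. Two tissue
compartments — whole lung tissue (4 cohorts) and small airway epithelial
cells, SAEC (3 cohorts) — are analysed separately and only combined by the
explicit cross-compartment rule.

### Geneset curation

Source lists are tuples (symbol, accession, name) under one of seven
provenance labels. The dedup key is the normalized symbol (whitespace-
stripped, uppercased), not the accession, because the sources mix identifier
systems while the analysis is keyed by gene symbol throughout. Symbol
synonyms are *not* resolved (no HGNC lookup): inputs are taken at face
value, keeping curation deterministic and offline. A gene is
ciliopathy-flagged iff at least one contributing source is in the
configurable ciliopathy-labelled set (default: the UniProt ciliopathy
query). When sources disagree on an accession the first seen wins and the
conflict is logged. The compartment geneset is the subset of the merged list
detected on at least one of the compartment's platforms.

### Differential expression

Tests run on log2 expression. Linear-scale matrices are transformed as
log2(x + pseudocount) with pseudocount 1 (configurable); scale is
auto-detected when unstated (matrix maximum > 50 ⇒ linear — log2 microarray
or log-CPM values essentially never exceed 50) and always overridable.
Duplicate gene rows (multiple probes per symbol) collapse to the
highest-mean probe, the common microarray convention. Missing cells are an
error, not imputed.

The test is an independent two-sample t-test per gene, Welch by default
(Student optional). The cohorts compare independent, unequal-size COPD and
non-COPD groups, so a paired design is not possible; Welch is the safer
default under group-variance differences. The statistic, Welch–Satterthwaite
degrees of freedom and the Benjamini–Hochberg step-up

  q_(i) = min_{j ≥ i} ( p_(j) · m / j ),  capped at 1,

are computed in-package (scipy supplies only the t CDF); tests cross-check
both against scipy/statsmodels as independent oracles. BH runs per cohort
over exactly the tested geneset genes (m = n_tested), since the analysis is
explicitly geneset-restricted — q-values would be incomparable across
cohorts if some used transcriptome-wide m.

Significance defaults to raw p < 0.05 with q reported alongside
(`sig_rule=fdr_q` gives the stricter reading); "deregulated" means
significant — no fold-change cutoff (reported candidate effects go as low as
|log2FC| ≈ 0.01) and no cross-dataset direction requirement, since
sign-discordant candidates are a real feature of this kind of data; a
`require_direction` switch implements the stricter variant by dropping
minority-sign cohorts from a gene's membership. Degenerate inputs follow
fixed conventions: two equal constant groups give (t=0, p=1); two unequal
constant groups give p=0 with a warning.

Two effect statistics are kept because they answer different questions:
log2FC (COPD minus non-COPD on log means) for tables, and the dot-plot
statistic log10(mean_lin non-COPD / mean_lin COPD) computed on *linear*
means (the retained pre-transform matrix, or 2^x back-transform). The two
deliberately have opposite orientation; for near-null genes their signs may
also disagree because one averages logs and the other logs averages.

### Concordance

Per compartment, a gene's membership is the exact set of cohorts calling it
significant. Venn regions are exact-subset counts (they partition the tier-1
genes); tier k counts genes with |membership| ≥ k. Percentages divide by the
compartment geneset size and round half-up (not banker's); whole-lung tiers
print at 0 decimals and the sparse SAEC ≥2 tier at 1 decimal, the formats
used for this analysis's published-style summaries. All gene lists are
emitted lexicographically sorted; Venn keys are sorted dataset-id tuples.

Cross-compartment hits require ≥ 2 lung and ≥ 1 SAEC cohorts (configurable).
The common-gene table takes genes at ≥ 3 of 4 lung or ≥ 2 of 3 SAEC cohorts,
one row per (gene, qualifying compartment), with per-cohort log2FC columns
blank where the gene was not significant or not tested; a gene significant
in every cohort of its compartment is flagged fully concordant.

### Single-cell annotation

Cell populations are taken as given (no clustering). "Expressing" means
value > 0 by default — no published cutoff exists — with a configurable
minimum. Bins: fraction < 25% ⇒ `+`, 25–50% inclusive ⇒ `++`, > 50% ⇒
`+++`; both boundaries belong to the middle bin (the closed interval between
open-ended neighbours). The principal-population rule is this package's own
construction, as no operational rule is published for that column: the top
population wins if its expressing fraction is ≥ 1.5 × the pooled expressing
fraction of all remaining cells, else the label is "All" (broad). The
dominance ratio 1.5 was fixed a priori as "clearly more than the rest
combined, short of absolute majority logic"; pooling weights populations by
cell count when sizes are known and equally otherwise (the signature also
accepts bare fraction maps). EC_other reports as "EC"; a dominant
non-epithelial signal reports as "All" because the output vocabulary is
fixed to {MCC, NDC, EC, All}.

## The synthetic study generator

`SimConfig` defaults encode the seven-cohort design: 4 lung cohorts whose
group sizes split 238 non-COPD / 391 COPD evenly (60/60/59/59 and
98/98/98/97 — the per-cohort breakdown is not published in text form), 3
SAEC cohorts at 100/39 each, and a 495-gene geneset built from a 447-gene
cilia list and a 189-gene ciliopathy list sharing 141 symbols, plus smaller
overlapping library lists for provenance realism. Per gene: log2 baseline
μ_g ~ N(6, 2²) and noise σ_g ~ U(0.3, 0.8) — typical log2-microarray
location and spread; a planted fraction frac_de = 0.3 of genes carries a
log2 shift δ = 1 in COPD samples with direction ±1 equiprobable (both up-
and down-regulated candidates occur); each planted gene is independently
active per cohort with concordance ρ = 0.6, and every gene drops out of each
cohort with platform probability 0.1. frac_de, δ and ρ are the package's own
choices of a realistic regime (a moderate shared signal detected by some but
not all cohorts); no published values exist for them. One master seed feeds
fixed per-stage generator streams (geneset / lung / SAEC / single cell), so
identical configs are bit-identical and adding draws to one stage never
shifts another.

Single-cell simulation is Bernoulli(expression probability) × (1 +
Poisson(1)) per cell×gene: a zero-inflated count with the planted
per-population expressing fraction exactly equal to the Bernoulli rate.

What the generator does **not** emulate: probe-level effects, batch
structure, library-size variation, correlated (platform-block) dropout —
with independent 10% dropout the compartment-geneset union across 4 cohorts
recovers nearly all 495 genes, unlike the real platforms' 350/399 subsets —
non-normal noise, gene–gene correlation, and clinical covariates. Passing
recovery tests therefore demonstrates correctness of the pipeline's
counting, testing and bookkeeping under the stated model, not robustness to
real-platform artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled-down high-power designs chosen so
conclusions are exact rather than approximate: 4 cohorts × 30/30 samples,
150 genes, δ = 2, σ = 0.25, giving a planted shift of ≈ 31 standard errors;
at α = 1e-6 significance then equals planted activity and tier recovery is
checked for exact equality against ground truth. Calibration checks (type-I
error at α = 0.05) use 200 genes over 20–50 independent cohorts and a
3-Monte-Carlo-standard-error band. Percent rounding uses decimal half-up
arithmetic to avoid binary-float ties. Report JSON serializes floats at 6
significant digits, sorts keys, and excludes the output path from the config
digest, so identical runs are byte-identical. Ties in the
principal-population rule break deterministically (fraction, then label).

## Known limitations

* Vote counting ignores effect sizes and cohort precision; a gene barely
  significant in two small cohorts outranks a large consistent effect in one.
* Raw p < 0.05 as the default call (with q alongside) mirrors the analysis
  this package operationalizes; switch to `fdr_q` for error-rate control.
* Per-dataset significant percentages use each cohort's tested-gene count as
  denominator; compartment-level percentages use the compartment geneset.
* No covariate adjustment (age, sex, smoking) — the public matrices this
  design targets lack harmonized clinical annotations.
* The principal-population rule and the expressing threshold are explicit
  conventions of this package; published single-cell labels produced by other
  conventions need not reproduce.
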