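# Methods

## Problem setting

The pipeline integrates two kinds of differential-expression (DE) evidence:
a *disease signature* — a per-gene summary table (logFC, p, FDR) from a
large case–control cohort, as published for post-mortem brain studies — and
*drug signatures* derived from small in-vitro drug-vs-vehicle RNA-seq
experiments (4–6 replicates per group). A gene "reversed" by a drug is
significant on both sides with strictly opposite log2 fold changes; genes
reversed by every drug form the common set that is then characterized by
over-representation analysis (ORA) and protein–protein-interaction (PPI)
clustering.

## The synthetic-data generator

Real inputs of this kind are not redistributable, so the package generates
all of them with planted ground truth. The generator defines the study
conditions; its defaults are fixed once and are not tuning knobs.

**Truth model.** Exactly `round(n_genes · frac_disease_de)` genes carry a
disease direction (±1 with equal probability). Conditional on a nonzero
disease direction, each drug independently opposes it with probability
`reversal_prob`, matches it with probability `concordant_prob`, and is
silent otherwise. Truly reversed ≡ nonzero disease direction and drug
direction equal to its negative. Two consequences worth keeping in mind:

- *No drug–drug correlation.* Real antipsychotics share receptor pharmacology,
  which inflates the commonly-reversed count relative to independence (a
  published four-drug study found ~25% of its union commonly reversed; under
  independence the analogous fraction is `reversal_prob⁴ / (1−(1−reversal_prob)⁴)`
  ≈ 15% at 0.6 before detection loss). The default run therefore shows a
  proportionally smaller common set than a real study would.
- *Drugs only perturb disease genes.* Disease-null genes have drug direction
  0, so the drug signatures contain no disease-irrelevant DE. This keeps the
  truth exactly scoreable but understates the multiple-testing burden a real
  drug signature carries.

**Key parameters** (defaults in parentheses):

| parameter | meaning |
|---|---|
| `n_genes` (20,000) | genes measured; full-scale default mirrors a mammalian transcriptome |
| `frac_disease_de` (0.05) | fraction with a true disease effect; yields an FDR<0.1 significant fraction in the 2–10% band seen in large cohort tables |
| `disease_effect_scale` (1.5) | mean of the disease |logFC| distribution: 0.25 + Gamma(shape 2), log2 units |
| `drug_effect_scale` (2.0) | mean drug |logFC|: 0.5 + Gamma(shape 2); in-vitro drug responses at therapeutic doses are typically ≥ 2-fold among responsive genes |
| `reversal_prob` (0.6), `concordant_prob` (0.1) | per-drug response probabilities given a disease gene; 0.6 mirrors per-drug reversed/disease-DEG ratios of published four-drug comparisons |
| `reps_per_group` (6), `nb_dispersion` (0.05) | replicate count and NB dispersion; 0.05 is a typical cell-line (technical-replicate) dispersion, well below post-mortem tissue values |
| `mean_log_expression` (5.0), `baseline_log_sd` (1.5) | natural-log baseline count model, exp(5) ≈ 150 median counts with a realistic dynamic range |
| `disease_noise_sd` (1.0), `disease_pseudo_n` (100) | the disease table's standard error is σ/√n = 0.1, mimicking the precision of a several-hundred-sample cohort |
| `n_ppi_modules` (2), `ppi_module_size` (14), `module_edge_prob` (0.6) | two dense modules planted among the commonly reversed genes, sized like the two clusters reported in comparable PPI analyses |
| `enrichment_factor` (1000) | sampling weight of truly common-reversed genes when drawing the planted gene set; at this weight the planted set is essentially "all common-reversed genes plus `planted_noise_frac` (0.2) noise", while factor 1 reduces it to a decoy |

**Count model.** Counts are gamma–Poisson: mean μ = exp(baseline) for
vehicle and μ·2^(direction·|effect|) for treated samples, variance
μ + `nb_dispersion`·μ². As dispersion → 0 this degenerates to Poisson,
which the tests verify.

**Disease table p-model.** logFC = direction·|effect| + ε with
ε ~ N(0, SE), SE = `disease_noise_sd`/√`disease_pseudo_n`; the p-value is
the two-sided normal tail of logFC/SE and q is BH. This is the cheapest
model that couples effect size and significance the way an inherited cohort
summary table does.

**Determinism.** Every stage draws from its own `numpy` SeedSequence stream
keyed on (`seed`, stage id), so identical parameters reproduce every output
file byte-identically and stages can be regenerated independently.

## Differential expression of the drug arms

- **Filtering.** Two documented rules: *fraction* mode keeps a gene with
  CPM > threshold in strictly more than a given fraction of samples (the
  ">1 CPM in >50%" convention of cohort tables); *smallest-group* mode
  (default) keeps genes at CPM ≥ 1 in at least n samples, n = smallest
  group size — the standard practice for small two-group designs.
- **TMM.** Pairwise against a reference (auto: sample whose 75th percentile
  of relative expression is closest to the mean), per-gene
  M = log2 ratio and A = mean log2 abundance over genes expressed in both,
  double trim (30% on M, 5% on A, rank-based with average ties), factor =
  2^(precision-weighted mean of surviving M) with binomial asymptotic
  variance weights, then rescaled to geometric mean 1. A test cross-checks
  the factors against Bioconductor edgeR's `calcNormFactors` to 1e-8.
- **Per-gene test.** Welch's unequal-variance t on log2-CPM with
  pseudocount 0.5, a deliberate substitute for a negative-binomial
  framework: with ≥ 4 replicates per group and moderately expressed genes
  its type-I error is within a percentage point of nominal (verified on
  10,000 null synthetic genes), and it keeps the pipeline free of
  dispersion estimation. `de_welch` is the single swap point if an NB test
  is ever wanted. Degenerate zero-variance genes get p = 1 (zero
  difference) or the smallest positive float (nonzero difference, logged).
- **BH.** Step-up q-values, authored and tested against an independent
  implementation to 1e-12.

## Reversal and intersection

"Opposite direction" is a strict sign product < 0; a logFC of exactly 0
never counts. Significance is required on both sides (disease q ≤ 0.1 —
the threshold published for the cohort table this emulates — and drug
q ≤ 0.05, configurable; both compared with ≤). Identifier matching is exact
string match after upper-casing and whitespace stripping; no alias or
ortholog resolution. Duplicate identifiers in a loaded table collapse to
the record with the smallest q (ties: largest |logFC|, then first
occurrence).

Intersections are exact per-gene memberships: each union gene belongs to
one exclusive region (the subset of drugs reversing it), so region counts
sum to the union and the per-drug inclusive totals are the row sums — both
invariants are tested against brute force.

## Over-representation analysis

Exact hypergeometric upper tail computed with integer binomial
coefficients (correct to float precision; verified against an independent
implementation over all argument tuples with N ≤ 60), BH within the tested
collection only, and size filters K ∈ [10, 500] applied *before* testing.
The default universe is the measured background — genes present in the
disease table and every drug analysis after filtering — rather than all
annotated genes, because the query can only ever be drawn from what was
measured. Results sort by p, ties by overlap descending then set id, making
the output order reproducible.

## PPI network

Edges are score-weighted undirected pairs; 0–1000 integer scales are
auto-detected and rescaled. The induced subgraph keeps edges with both
endpoints in the query at score ≥ 0.7 (inclusive, matching the
"high confidence" preset); isolated query genes stay in the data flagged
`isolated`. Clusters are connected components (the definition used when a
figure labels its "largest connected components" as clusters — no
modularity or MCL clustering), sorted by size then lexicographic smallest
member, with components below 3 nodes counted but not reported.

**Edge-enrichment null.** The analytic enrichment p-value of the STRING web
service is unpublished, so the package states its null explicitly: uniform
random same-size gene sets from the declared background, statistic = induced
edge count at the cutoff, p = (1 + #{null ≥ observed})/(n_perm + 1). The
pseudo-count avoids p = 0 and makes the minimum attainable p 1/(n_perm+1).
Uniform (rather than degree-preserving) sampling matches the question "is
this gene set unusually connected for its size"; the empirical p is
slightly conservative because the statistic is discrete. Calibration is
tested (KS < 0.05 against uniform under random queries) and exactness is
checked against full subset enumeration on a small background.

## Annotation

For genes reversed by all drugs, the drug logFC signs must agree (each
opposes the one disease sign) — asserted, not assumed: mixed signs raise an
error. Direction is up/down by that common sign, `mean_logfc` is the
unweighted arithmetic mean across drugs, and eQTL flags are exact matches
against a flat user-supplied list.

## Problem sizes used in tests

The acceptance tests run the recovery analyses at 2,000 genes,
30% disease-DE fraction, reversal probability 0.5, 6 replicates, averaged
over 20–50 seeds; the end-to-end determinism check runs the full default
(20,000 genes, 10,000 permutations) twice. These sizes keep the whole suite
near a minute while leaving every statistical check well-powered.

## Known limitations

- Independence of drug responses and disease-gene-only drug effects (above)
  make the common set smaller and the drug signatures cleaner than real
  data; passing recovery tests demonstrates correctness of the analysis
  logic, not robustness to correlated or off-target drug biology.
- No batch effects, gene–gene correlation, dose–response structure, or
  read-level simulation.
- The Welch substitute loses power versus NB tests at very low counts; the
  low-expression filter keeps it in its comfortable regime.
- Gene sets are flat: no ontology hierarchy, redundancy trimming, or
  semantic similarity.
- The permutation enrichment p is not comparable to the proprietary
  analytic p of the STRING service beyond order of magnitude.
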