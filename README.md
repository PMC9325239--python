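# revkit — disease–drug transcriptomic reversal analysis

`revkit` implements an integrative transcriptomic-reversal pipeline for
psychiatric drug-repurposing questions of the form: *which genes does a drug
push in the opposite direction to a disease signature?* The motivating use
case is antipsychotic drugs versus a schizophrenia post-mortem brain
signature: genes significantly dysregulated in the disease and regulated the
opposite way by every studied drug are candidate therapeutic-relevance
genes, which are then characterized by gene-set over-representation analysis
and protein–protein-interaction (PPI) clustering.

Because the cohort and cell-line datasets such a study rests on are not
publicly redistributable, all inputs here are synthetic with planted ground
truth (`revkit.synthetic`), so every stage of the pipeline is testable for
recovery of known signal.

## The method

1. **Drug differential expression** (`revkit.de`). Each drug-vs-vehicle
   count matrix is filtered (keep genes with ≥ 1 CPM in at least *n*
   samples, *n* = size of the smallest group), TMM-normalized (weighted
   trimmed mean of M-values, trims 0.30/0.05), tested per gene with a Welch
   test on log2-CPM (pseudocount 0.5), and BH-adjusted:
   q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j.
2. **Reversal detection** (`revkit.reversal`). Gene g is reversed by drug d
   iff q_disease(g) ≤ 0.1, q_d(g) ≤ 0.05, and
   logFC_disease(g) · logFC_d(g) < 0. Per-drug sets are combined into
   UpSet-style exclusive intersection regions, the union, and the common set
   (reversed by **all** drugs).
3. **Over-representation analysis** (`revkit.enrichment`). For each gene set
   with in-universe size K ∈ [10, 500], the exact hypergeometric upper tail
   P(X ≥ k) = Σᵢ₌ₖ C(K,i)·C(N−K,n−i)/C(N,n) of the common set's overlap k,
   BH-adjusted across tested sets. The universe is the set of genes measured
   in the disease table *and* every drug analysis.
4. **PPI clustering** (`revkit.network`). The common set's induced subgraph
   at combined score ≥ 0.7 (the STRING "high confidence" preset); clusters
   are connected components; connectivity enrichment is a permutation test
   against 10,000 uniform same-size gene sets,
   p = (1 + #{null ≥ observed}) / (n_perm + 1).
5. **Annotation** (`revkit.annotate`). Each common-reversed gene gets a
   consensus direction (its drug logFC signs necessarily agree), the mean
   drug logFC, and an eQTL-list membership flag, exported to GraphML.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default synthetic conditions (20,000 genes, 4 drugs, 6 replicates per
group, seed 1):

```sh
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_reversal.py
python analysis/04_enrichment.py
python analysis/05_network.py
```

`03_reversal.py` prints:

```
reversed genes per drug: {'amisulpride': 490, 'aripiprazole': 466, 'clozapine': 443, 'risperidone': 480}
reversed by at least one drug: 909
reversed by all four drugs:   52
```

i.e. each drug reverses 443–490 of the 1,000 planted disease genes that
survive both significance filters, 909 genes are reversed by at least one
drug, and 52 by all four (drug responses are independent given the disease
sign, so the common set is the small tail of four coincidences).
`04_enrichment.py` then ranks the planted gene set first
(k = 45 of its K = 133 in-universe members, q ≈ 6 × 10⁻⁹⁰; no decoy is
significant), and `05_network.py` reports the high-confidence subgraph on
the 52 common genes (7 edges, observed against a null mean of ~0, empirical
p = 0.0001 at 10,000 permutations) and its connected components.

The same run as a single command:

```sh
revkit all --out results/run --seed 1
```

writes `summary.json` with keys
`{per_drug_counts, union, common, ora_significant, components, enrichment_p, seed}`.
Subcommands `simulate`, `de`, `reverse`, `enrich`, `network` expose the
individual stages on files.

## Layout

- `src/revkit/` — library: `synthetic`, `de`, `reversal`, `enrichment`,
  `network`, `annotate`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing under `results/`.
- `tests/` — unit, property and acceptance tests (pytest + hypothesis).
- `docs/methods.md` — models, parameter choices, numerical details,
  limitations.
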