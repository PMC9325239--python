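#!/usr/bin/env python
"""Over-representation analysis of the commonly reversed genes.

Tests each gene set (hypergeometric upper tail, BH across tested sets)
against the measured universe: genes present in the disease table and in
every drug analysis after filtering. Writes results/ora_results.tsv.
"""

import logging
from pathlib import Path

from revkit.annotate import read_gene_list
from revkit.enrichment import ora, read_gmt, write_ora
from revkit.reversal import load_signature
from revkit.synthetic import DEFAULT_DRUGS

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

query = set(read_gene_list("results/reversal/common_set.txt"))
disease = load_signature("results/inputs/disease.tsv")
universe = set(disease.table.index)
for d in DEFAULT_DRUGS:
    universe &= set(load_signature(Path("results/de") / f"{d}.tsv").table.index)

collection = read_gmt("results/inputs/gene_sets.gmt")
df = ora(query, universe, collection, min_size=10, max_size=500, q_cut=0.05)
write_ora(df, "results/ora_results.tsv")

n_sig = int(df["significant"].sum())
print(f"query {len(query)} genes against {len(collection.sets)} sets, universe {len(universe)}")
print(f"significant sets at FDR <= 0.05: {n_sig}")
print(df.head(5)[["set_id", "k", "K", "pvalue", "qvalue"]].to_string(index=False))
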