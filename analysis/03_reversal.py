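#!/usr/bin/env python
"""Reversal detection: disease vs each drug, then intersection accounting.

A gene counts as reversed by a drug when it is FDR-significant on both sides
(disease q <= 0.1, drug q <= 0.05) with strictly opposite logFC signs.
Writes per-drug tables, the membership matrix, UpSet-style exclusive region
counts and the common set under results/reversal/.
"""

import logging
from pathlib import Path

from revkit.reversal import intersect_across_drugs, load_signature, reversed_genes, upset_counts, write_reversal
from revkit.synthetic import DEFAULT_DRUGS

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

disease = load_signature("results/inputs/disease.tsv", label="disease")
drug_sigs = {d: load_signature(Path("results/de") / f"{d}.tsv", label=d) for d in DEFAULT_DRUGS}

per_drug = {d: reversed_genes(disease, sig, q_disease=0.1, q_drug=0.05) for d, sig in drug_sigs.items()}
result = intersect_across_drugs(per_drug)
write_reversal(result, disease, drug_sigs, "results/reversal")

table, totals = upset_counts(result)
print("reversed genes per drug:", totals.astype(int).to_dict())
print(f"reversed by at least one drug: {len(result.union_set)}")
print(f"reversed by all four drugs:   {len(result.common_set)}")
print("largest exclusive regions:")
print(table.head(8).to_string(index=False))
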