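#!/usr/bin/env python
"""Generate the study's synthetic inputs with planted ground truth.

Emulates the data the reversal analysis consumes: a disease DE summary table
(~5% of 20,000 genes significant at FDR < 0.1), four drug-vs-vehicle count
matrices (6 replicates per group), a gene-set collection with one planted
enriched set, a STRING-style PPI edge list with two planted modules, and an
eQTL gene list. Writes everything under results/inputs/.
"""

import logging

from revkit.synthetic import SimulationParams, write_inputs

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

SEED = 1

params = SimulationParams(seed=SEED)
paths = write_inputs(params, "results/inputs")
truth = paths["truth"]

n_dis = int((truth.disease_direction != 0).sum())
print(f"simulated {params.n_genes} genes, {params.n_drugs} drugs, seed {SEED}")
print(f"planted disease-effect genes: {n_dis}")
for d, label in enumerate(params.drug_labels):
    print(f"  truly reversed by {label}: {len(truth.reversed_by_drug(d))}")
print(f"truly reversed by all drugs: {len(truth.reversed_by_all())}")
print(f"planted PPI modules: {[len(m) for m in truth.module_members]}")
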