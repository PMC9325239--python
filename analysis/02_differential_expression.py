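#!/usr/bin/env python
"""Per-drug differential expression from the simulated count matrices.

For each drug: low-expression filter (>= 1 CPM in at least the smallest
group's n samples), TMM normalization, Welch test on log2-CPM, BH
adjustment. Writes one signature TSV per drug under results/de/.
"""

import logging
from pathlib import Path

import yaml

from revkit.de import de_welch, filter_low_expression, read_counts, tmm_factors, write_signature
from revkit.synthetic import DEFAULT_DRUGS

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")

inputs = Path("results/inputs")
out = Path("results/de")
out.mkdir(parents=True, exist_ok=True)

summary = {}
for label in DEFAULT_DRUGS:
    cm = read_counts(inputs / f"counts_{label}.tsv", inputs / f"groups_{label}.tsv")
    n_raw = len(cm.gene_ids)
    cm = filter_low_expression(cm, min_cpm=1.0, mode="smallest_group")
    factors = tmm_factors(cm)
    sig = de_welch(cm, factors, label=label)
    write_signature(sig, out / f"{label}.tsv")
    summary[label] = {
        "genes_raw": n_raw,
        "genes_after_filter": len(sig.table),
        "significant_q05": len(sig.significant(0.05)),
    }
    print(
        f"{label}: {n_raw} -> {len(sig.table)} genes after CPM filter, "
        f"{summary[label]['significant_q05']} significant at q<=0.05"
    )

yaml.safe_dump(summary, (out / "de_summary.yaml").open("w"))
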