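"""Disease-drug reversal detection and multi-drug intersection accounting.

The core operation of the pipeline: a gene is "reversed" by a drug when it is
significant in both the disease and the drug signature and its log2 fold
changes have strictly opposite signs. Per-drug reversed sets are then
combined into UpSet-style exclusive intersection regions, the union
(reversed by at least one drug), and the common set (reversed by all drugs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from revkit.de import DESignature
from revkit.enrichment import normalize_gene_id

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {"gene": "gene", "logfc": "logFC", "pvalue": "pvalue", "qvalue": "fdr"}


@dataclass
class ReversalResult:
    """Per-drug reversed sets plus exclusive-intersection accounting."""

    drug_labels: list[str]
    reversed_sets: dict[str, set[str]]
    union_set: set[str]
    common_set: set[str]
    exclusive_regions: dict[tuple[str, ...], int]
    membership: pd.DataFrame  # genes x drugs, bool

    def per_drug_counts(self) -> dict[str, int]:
        return {d: len(self.reversed_sets[d]) for d in self.drug_labels}


def load_signature(path, column_map: dict | None = None, label: str = "") -> DESignature:
    """Load a signature TSV, normalizing and deduplicating gene ids.

    ``column_map`` maps the canonical fields {gene, logfc, qvalue} (and
    optionally pvalue) to the file's column names; by default the columns
    are gene/logFC/pvalue/fdr. Duplicate gene ids collapse to the record
    with the smallest q (ties: largest |logFC|, then first occurrence).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for canonical in ("gene", "logfc", "qvalue"):
        if cmap[canonical] not in df.columns:
            raise ValueError(f"{path}: missing required column {cmap[canonical]!r} (for {canonical})")
    has_p = cmap.get("pvalue") in df.columns
    n_raw = len(df)
    out = pd.DataFrame({"gene": df[cmap["gene"]].map(normalize_gene_id)})
    for canonical in ("logfc", "qvalue") + (("pvalue",) if has_p else ()):
        raw = df[cmap[canonical]]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            lineno = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}:{lineno}: unparsable numeric value {raw[bad.idxmax()]!r} in column {cmap[canonical]!r}")
        out[canonical] = numeric
    if not has_p:
        out["pvalue"] = out["qvalue"]
    if n_raw == 0:
        logger.warning("%s: empty signature file", path)
    # dedup: smallest q, then largest |logFC|, then first occurrence
    out["_order"] = np.arange(len(out))
    out["_abs"] = out["logfc"].abs()
    out = out.sort_values(["qvalue", "_abs", "_order"], ascending=[True, False, True], kind="stable")
    deduped = out.drop_duplicates("gene", keep="first").sort_values("_order")
    n_dup = n_raw - len(deduped)
    if n_dup:
        logger.info("%s: collapsed %d duplicate gene record(s)", path, n_dup)
    logger.info("%s: loaded %d gene record(s)", path, len(deduped))
    table = deduped.set_index("gene")[["logfc", "pvalue", "qvalue"]]
    return DESignature(label=label or Path(path).stem, table=table)


def reversed_genes(
    disease: DESignature,
    drug: DESignature,
    q_disease: float = 0.1,
    q_drug: float = 0.05,
) -> set[str]:
    """Genes significant in both signatures with opposite logFC signs.

    Inclusion requires presence in both tables, q <= q_disease on the
    disease side, q <= q_drug on the drug side, and a strictly negative
    logFC product (a zero logFC on either side never counts).
    """
    merged = disease.table.join(drug.table, how="inner", lsuffix="_dis", rsuffix="_drug")
    mask = (
        (merged["qvalue_dis"] <= q_disease)
        & (merged["qvalue_drug"] <= q_drug)
        & (merged["logfc_dis"] * merged["logfc_drug"] < 0)
    )
    return set(merged.index[mask])


def concordant_genes(
    disease: DESignature, drug: DESignature, q_disease: float = 0.1, q_drug: float = 0.05
) -> set[str]:
    """Doubly significant genes moved in the same direction (sign product > 0)."""
    merged = disease.table.join(drug.table, how="inner", lsuffix="_dis", rsuffix="_drug")
    mask = (
        (merged["qvalue_dis"] <= q_disease)
        & (merged["qvalue_drug"] <= q_drug)
        & (merged["logfc_dis"] * merged["logfc_drug"] > 0)
    )
    return set(merged.index[mask])


def intersect_across_drugs(per_drug: dict[str, set[str]]) -> ReversalResult:
    """Union, common set, per-gene membership and exclusive regions.

    Each gene in the union belongs to exactly one exclusive region: the
    subset of drugs whose reversed sets contain it.
    """
    if not per_drug:
        raise ValueError("at least one drug set is required")
    labels = list(per_drug)
    union = set().union(*per_drug.values())
    common = set.intersection(*per_drug.values()) if per_drug else set()
    genes = sorted(union)
    membership = pd.DataFrame(
        {d: [g in per_drug[d] for g in genes] for d in labels},
        index=pd.Index(genes, name="gene"),
        dtype=bool,
    )
    regions: dict[tuple[str, ...], int] = {}
    for g in genes:
        region = tuple(d for d in labels if g in per_drug[d])
        regions[region] = regions.get(region, 0) + 1
    return ReversalResult(
        drug_labels=labels,
        reversed_sets={d: set(per_drug[d]) for d in labels},
        union_set=union,
        common_set=common,
        exclusive_regions=regions,
        membership=membership,
    )


def upset_counts(result: ReversalResult) -> tuple[pd.DataFrame, pd.Series]:
    """Exclusive-region table (count descending) and per-drug inclusive totals."""
    rows = [
        {"drugs": "&".join(region), "n_drugs": len(region), "count": count}
        for region, count in result.exclusive_regions.items()
    ]
    table = pd.DataFrame(rows, columns=["drugs", "n_drugs", "count"])
    if len(table):
        table = table.sort_values(["count", "drugs"], ascending=[False, True], ignore_index=True)
    totals = pd.Series(result.per_drug_counts(), name="reversed_genes")
    return table, totals


def write_reversal(result: ReversalResult, disease: DESignature, drug_sigs: dict[str, DESignature], out_dir) -> None:
    """Write per-drug reversed tables, membership matrix, UpSet counts, common set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for drug, genes in result.reversed_sets.items():
        sig = drug_sigs[drug]
        genes_sorted = sorted(genes)
        df = pd.DataFrame(
            {
                "gene": genes_sorted,
                "disease_logFC": disease.table.loc[genes_sorted, "logfc"].to_numpy(),
                "drug_logFC": sig.table.loc[genes_sorted, "logfc"].to_numpy(),
                "disease_q": disease.table.loc[genes_sorted, "qvalue"].to_numpy(),
                "drug_q": sig.table.loc[genes_sorted, "qvalue"].to_numpy(),
            }
        )
        df.to_csv(out / f"reversed_genes_{drug}.tsv", sep="\t", index=False)
    result.membership.astype(int).to_csv(out / "membership.tsv", sep="\t")
    table, totals = upset_counts(result)
    table.to_csv(out / "upset_counts.tsv", sep="\t", index=False)
    totals.rename_axis("drug").to_csv(out / "per_drug_totals.tsv", sep="\t")
    (out / "common_set.txt").write_text("".join(f"{g}\n" for g in sorted(result.common_set)))
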