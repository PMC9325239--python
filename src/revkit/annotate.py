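"""Node annotations for the commonly reversed genes.

Each gene reversed by every drug moves in one consistent direction across
the drug signatures (it must oppose the single disease sign), so it can be
annotated with a consensus direction (up/down), the arithmetic mean of its
drug log2 fold changes, and membership in a user-supplied eQTL gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from revkit.de import DESignature
from revkit.enrichment import normalize_gene_id

logger = logging.getLogger(__name__)


@dataclass
class NodeAnnotation:
    gene_id: str
    direction: str  # "up" or "down"
    mean_logfc: float
    is_eqtl: bool = False


def consensus_direction(gene: str, drug_sigs: list[DESignature]) -> NodeAnnotation:
    """Consensus direction and mean drug logFC for one gene.

    Raises if the gene is missing from any signature or if the drug logFC
    signs disagree (which would violate the common-reversal contract).
    """
    gene = normalize_gene_id(gene)
    logfcs = []
    for sig in drug_sigs:
        if gene not in sig.table.index:
            raise KeyError(f"gene {gene!r} missing from signature {sig.label!r}")
        logfcs.append(float(sig.table.loc[gene, "logfc"]))
    if all(x > 0 for x in logfcs):
        direction = "up"
    elif all(x < 0 for x in logfcs):
        direction = "down"
    else:
        raise ValueError(f"gene {gene!r} has mixed drug logFC signs {logfcs}: not a consensus gene")
    return NodeAnnotation(gene_id=gene, direction=direction, mean_logfc=sum(logfcs) / len(logfcs))


def read_gene_list(path) -> list[str]:
    """One gene id per line, normalized, deduplicated, order-preserving."""
    seen: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        g = normalize_gene_id(line)
        if g:
            seen.setdefault(g, None)
    return list(seen)


def flag_eqtl(genes: list[str], eqtl_path) -> dict[str, bool]:
    """Exact-match eQTL flags for each gene after id normalization."""
    eqtl = set(read_gene_list(eqtl_path))
    if not eqtl:
        logger.warning("eQTL list %s is empty; all flags false", eqtl_path)
    flags = {normalize_gene_id(g): normalize_gene_id(g) in eqtl for g in genes}
    logger.info("flag_eqtl: %d of %d genes flagged", sum(flags.values()), len(flags))
    return flags


def annotate_genes(genes: list[str], drug_sigs: list[DESignature], eqtl_path=None) -> pd.DataFrame:
    """Annotation table (index gene; direction, mean_logfc, is_eqtl)."""
    annos = [consensus_direction(g, drug_sigs) for g in genes]
    flags = flag_eqtl([a.gene_id for a in annos], eqtl_path) if eqtl_path is not None else {}
    df = pd.DataFrame(
        {
            "direction": [a.direction for a in annos],
            "mean_logfc": [a.mean_logfc for a in annos],
            "is_eqtl": [flags.get(a.gene_id, False) for a in annos],
        },
        index=pd.Index([a.gene_id for a in annos], name="gene"),
    )
    return df.sort_index()


def write_annotations(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"mean_logfc": "mean_logFC"})
    out.to_csv(path, sep="\t", index_label="gene")
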