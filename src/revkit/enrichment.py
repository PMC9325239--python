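"""Over-representation analysis (ORA) of a gene set against a collection.

Exact hypergeometric upper-tail test per set, Benjamini-Hochberg adjustment
across the tested sets, with annotated-size filters applied before testing.
The tail probability is computed with exact integer binomial coefficients,
so it is correct to full float precision for any argument sizes that arise
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import pandas as pd

from revkit.de import bh_adjust

logger = logging.getLogger(__name__)


def normalize_gene_id(gene: str) -> str:
    return str(gene).strip().upper()


@dataclass
class GeneSetCollection:
    """Named gene sets keyed by a unique id."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for set_id, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {set_id!r} is empty")
        self.names = {sid: self.names.get(sid, sid) for sid in self.sets}


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name<TAB>description<TAB>genes..."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        set_id, desc = fields[0], fields[1]
        genes = {normalize_gene_id(g) for g in fields[2:] if g.strip()}
        if not genes:
            logger.warning("%s:%d: gene set %r has no genes, skipped", path, lineno, set_id)
            continue
        if set_id in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set id {set_id!r}")
        sets[set_id] = genes
        names[set_id] = desc
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets=sets, names=names, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id in collection.sets:
            genes = sorted(collection.sets[set_id])
            fh.write("\t".join([set_id, collection.names.get(set_id, set_id), *genes]) + "\n")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    X counts successes in a size-n draw without replacement from a
    population of N with K successes. Computed as an exact integer sum
    sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) over C(N,n).
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ValueError(f"inconsistent hypergeometric arguments K={K}, n={n}, N={N}")
    m = min(K, n)
    if not (0 <= k <= m):
        if k > m:
            return 0.0
        raise ValueError(f"k={k} out of range [0, {m}]")
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, m + 1))
    return numerator / comb(N, n)


def ora(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 500,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Every set is first intersected with the universe; sets whose in-universe
    size K falls outside [min_size, max_size] are excluded before testing.
    Returns a DataFrame sorted by p ascending (ties: overlap k descending,
    then set id) with columns set_id, name, k, K, n, N, pvalue, qvalue,
    overlap (';'-joined gene ids) and a boolean ``significant`` at ``q_cut``.
    """
    universe = {normalize_gene_id(g) for g in universe}
    if not universe:
        raise ValueError("ORA universe is empty")
    query = {normalize_gene_id(g) for g in query}
    outside = query - universe
    if outside:
        logger.warning("ORA: %d query gene(s) outside the universe dropped", len(outside))
        query = query & universe
    N, n = len(universe), len(query)
    rows = []
    for set_id, genes in collection.sets.items():
        in_universe = genes & universe
        K = len(in_universe)
        if not (min_size <= K <= max_size):
            continue
        overlap = sorted(in_universe & query)
        k = len(overlap)
        rows.append(
            {
                "set_id": set_id,
                "name": collection.names.get(set_id, set_id),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": hypergeom_tail(k, K, n, N),
                "overlap": ";".join(overlap),
            }
        )
    logger.info("ORA: tested %d of %d sets (size filter [%d, %d])", len(rows), len(collection.sets), min_size, max_size)
    if not rows:
        return pd.DataFrame(columns=["set_id", "name", "k", "K", "n", "N", "pvalue", "qvalue", "overlap", "significant"])
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df = df.sort_values(["pvalue", "k", "set_id"], ascending=[True, False, True], ignore_index=True)
    df["significant"] = df["qvalue"] <= q_cut
    return df[["set_id", "name", "k", "K", "n", "N", "pvalue", "qvalue", "overlap", "significant"]]


def write_ora(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"qvalue": "fdr"})
    out.to_csv(path, sep="\t", index=False)
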