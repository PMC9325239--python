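"""Protein-protein-interaction subgraph, clusters, and edge-enrichment null.

Builds the query-induced subgraph of a score-weighted interaction network at
a confidence cutoff (0.7 = the STRING "high confidence" preset), reports
connected components as clusters, and assesses whether the query set is more
densely connected than uniform random gene sets of the same size via a
permutation null with a +1 pseudo-count empirical p-value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from revkit.enrichment import normalize_gene_id

logger = logging.getLogger(__name__)


@dataclass
class ClusterReport:
    """Connected components sorted by size desc (ties: smallest member)."""

    components: list[list[str]]
    min_size: int
    n_below_min: int

    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    pvalue: float
    n_perm: int
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "observed": self.observed,
                    "expected": self.expected,
                    "pvalue": self.pvalue,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                },
                sort_keys=True,
                indent=2,
            )
        )


def read_edges(path, col1: str = "protein1", col2: str = "protein2", score_col: str = "combined_score") -> pd.DataFrame:
    """Read a STRING-style edge TSV into columns gene1, gene2, score in [0, 1].

    Integer 0-1000 score scales are auto-detected (any score > 1) and divided
    by 1000. Duplicate undirected pairs collapse to the maximum score;
    self-loops are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (col1, col2, score_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    score = pd.to_numeric(df[score_col], errors="coerce")
    bad = score.isna()
    if bad.any():
        lineno = int(bad.idxmax()) + 2
        raise ValueError(f"{path}:{lineno}: non-numeric score {df[score_col][bad.idxmax()]!r}")
    if (score > 1).any():
        score = score / 1000.0
    g1 = df[col1].map(normalize_gene_id)
    g2 = df[col2].map(normalize_gene_id)
    loops = g1 == g2
    if loops.any():
        logger.warning("%s: dropped %d self-loop(s)", path, int(loops.sum()))
    lo = np.minimum(g1, g2)
    hi = np.maximum(g1, g2)
    edges = pd.DataFrame({"gene1": lo, "gene2": hi, "score": score})[~loops]
    edges = edges.groupby(["gene1", "gene2"], as_index=False)["score"].max()
    return edges.sort_values(["gene1", "gene2"], ignore_index=True)


def induced_subgraph(edges: pd.DataFrame, query: set[str], min_score: float = 0.7) -> nx.Graph:
    """Subgraph on the query genes keeping edges with score >= min_score.

    Every query gene becomes a node; genes left without any surviving edge
    remain in the graph flagged ``isolated`` (kept in the data, typically
    excluded from drawing).
    """
    if not query:
        raise ValueError("query gene set is empty")
    query = {normalize_gene_id(g) for g in query}
    graph = nx.Graph()
    graph.add_nodes_from(sorted(query))
    kept = edges[(edges["score"] >= min_score) & edges["gene1"].isin(query) & edges["gene2"].isin(query)]
    graph.add_edges_from(zip(kept["gene1"], kept["gene2"], ({"score": s} for s in kept["score"])))
    for node in graph.nodes:
        graph.nodes[node]["isolated"] = graph.degree[node] == 0
    logger.info("induced_subgraph: %d nodes, %d edges at score >= %.2f", graph.number_of_nodes(), graph.number_of_edges(), min_score)
    return graph


def components(graph: nx.Graph, min_size: int = 3) -> ClusterReport:
    """Connected components of the edge-bearing subgraph.

    Isolated nodes are ignored; components below ``min_size`` are counted
    but omitted from the report.
    """
    connected = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    connected.sort(key=lambda c: (-len(c), c[0]))
    kept = [c for c in connected if len(c) >= min_size]
    n_small = len(connected) - len(kept)
    if n_small:
        logger.info("components: %d component(s) below min_size=%d omitted", n_small, min_size)
    return ClusterReport(components=kept, min_size=min_size, n_below_min=n_small)


def _induced_edge_count(u: np.ndarray, v: np.ndarray, member: np.ndarray) -> int:
    return int(np.count_nonzero(member[u] & member[v]))


def edge_enrichment_p(
    query: set[str],
    edges: pd.DataFrame,
    background_genes: set[str],
    min_score: float = 0.7,
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test: is the query set unusually connected?

    The observed statistic is the number of edges (score >= min_score) with
    both endpoints in the query. The null draws ``n_perm`` uniform random
    gene sets of the same size from ``background_genes`` and recomputes the
    count; p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    query = {normalize_gene_id(g) for g in query}
    background = sorted({normalize_gene_id(g) for g in background_genes})
    if not query <= set(background):
        missing = sorted(query - set(background))[:5]
        raise ValueError(f"query genes missing from background, e.g. {missing}")
    n_bg, n_q = len(background), len(query)
    index = {g: i for i, g in enumerate(background)}
    strong = edges[edges["score"] >= min_score]
    in_bg = strong["gene1"].isin(index) & strong["gene2"].isin(index)
    u = strong["gene1"][in_bg].map(index).to_numpy()
    v = strong["gene2"][in_bg].map(index).to_numpy()

    member = np.zeros(n_bg, dtype=bool)
    member[[index[g] for g in query]] = True
    observed = _induced_edge_count(u, v, member)

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=np.int64)
    batch = max(1, min(n_perm, int(2e7 // max(n_bg, 1))))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, n_bg))
        idx = np.argpartition(keys, n_q - 1, axis=1)[:, :n_q] if n_q < n_bg else np.tile(np.arange(n_bg), (b, 1))
        mem = np.zeros((b, n_bg), dtype=bool)
        mem[np.arange(b)[:, None], idx] = True
        null_counts[done : done + b] = (mem[:, u] & mem[:, v]).sum(axis=1)
        done += b
    pvalue = (1 + int((null_counts >= observed).sum())) / (n_perm + 1)
    return EnrichmentResult(
        observed=observed,
        expected=float(null_counts.mean()),
        pvalue=pvalue,
        n_perm=n_perm,
        seed=seed,
    )


def write_graphml(graph: nx.Graph, report: ClusterReport, annotations: pd.DataFrame | None, path) -> None:
    """GraphML export with node attributes direction/mean_logfc/is_eqtl/component_id."""
    g = graph.copy()
    comp_of = {gene: i + 1 for i, comp in enumerate(report.components) for gene in comp}
    for node in g.nodes:
        g.nodes[node]["component_id"] = comp_of.get(node, 0)
        if annotations is not None and node in annotations.index:
            row = annotations.loc[node]
            g.nodes[node]["direction"] = str(row["direction"])
            g.nodes[node]["mean_logfc"] = float(row["mean_logfc"])
            g.nodes[node]["is_eqtl"] = bool(row["is_eqtl"])
    nx.write_graphml(g, path)


def write_clusters(report: ClusterReport, path) -> None:
    rows = [
        {"component_id": i + 1, "size": len(comp), "genes": ";".join(comp)}
        for i, comp in enumerate(report.components)
    ]
    pd.DataFrame(rows, columns=["component_id", "size", "genes"]).to_csv(path, sep="\t", index=False)
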