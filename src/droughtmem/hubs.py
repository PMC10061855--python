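"""Hub-gene ranking on an interaction network.

Implements the two classic cytoHubba-family centralities:

* degree - number of neighbours;
* MCC (maximal clique centrality) - for node v,
  MCC(v) = sum over maximal cliques C containing v of (|C|-1)!.

Maximal cliques are enumerated exactly (Bron-Kerbosch with pivoting, via
networkx).  Isolated nodes score 0 under both metrics.  MCC enumeration is
refused above a configurable node bound because clique counts can grow
exponentially on dense graphs.
"""

from __future__ import annotations

import logging
from math import factorial
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DroughtMemError, LoadError

logger = logging.getLogger(__name__)


def load_edges(path: str | Path, min_score: float | None = None) -> nx.Graph:
    """Read an edge-list TSV (gene_a, gene_b[, score]) into a simple graph.

    Self-loops are dropped with a warning; parallel edges collapse
    naturally.  With ``min_score``, edges scoring below it are discarded.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise LoadError(f"{path}: need columns gene_a, gene_b[, score]")
    a, b = df.columns[:2]
    if min_score is not None:
        if df.shape[1] < 3:
            raise LoadError(f"{path}: min_score given but no score column present")
        df = df[df[df.columns[2]].astype(float) >= min_score]
    g = nx.Graph()
    n_loops = int((df[a] == df[b]).sum())
    if n_loops:
        logger.warning("%d self-loop(s) dropped", n_loops)
    df = df[df[a] != df[b]]
    g.add_edges_from(zip(df[a], df[b]))
    return g


def degree_score(net: nx.Graph) -> dict[str, int]:
    return {n: d for n, d in net.degree()}


def mcc_score(net: nx.Graph, node_bound: int = 5000) -> dict[str, int]:
    """Maximal clique centrality for every node.

    MCC(v) = sum of (|C|-1)! over maximal cliques C with v in C.
    """
    if nx.number_of_selfloops(net):
        raise DroughtMemError("graph must be simple (no self-loops)")
    if net.number_of_nodes() > node_bound:
        raise DroughtMemError(
            f"graph has {net.number_of_nodes()} nodes, above the bound of "
            f"{node_bound}; raise node_bound explicitly if clique "
            "enumeration is expected to be tractable"
        )
    scores = {n: 0 for n in net.nodes()}
    for clique in nx.find_cliques(net):
        if len(clique) == 1:
            continue  # isolated nodes score 0
        w = factorial(len(clique) - 1)
        for n in clique:
            scores[n] += w
    return scores


def top_hubs(scores: dict[str, int], k: int = 5) -> list[tuple[str, int]]:
    """Top-k nodes by descending score; ties break lexicographically."""
    if k < 1:
        raise DroughtMemError("k must be >= 1")
    if k > len(scores):
        logger.warning("k=%d exceeds node count %d; returning all", k, len(scores))
        k = len(scores)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def score_table(net: nx.Graph, node_bound: int = 5000) -> pd.DataFrame:
    """Degree and MCC with per-metric ranks, sorted by MCC."""
    deg = degree_score(net)
    mcc = mcc_score(net, node_bound=node_bound)
    df = pd.DataFrame(
        {"gene": list(net.nodes()), "degree": [deg[n] for n in net.nodes()],
         "mcc": [mcc[n] for n in net.nodes()]}
    )
    df["degree_rank"] = df["degree"].rank(method="min", ascending=False).astype(int)
    df["mcc_rank"] = df["mcc"].rank(method="min", ascending=False).astype(int)
    return df.sort_values(["mcc_rank", "gene"]).reset_index(drop=True)


def write_sif(net: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    """Export the network in Cytoscape SIF format."""
    with open(path, "w") as fh:
        for u, v in net.edges():
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in nx.isolates(net):
            fh.write(f"{n}\n")
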