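"""Degree/betweenness centrality and key-node selection on the ceRNA graph.

Conventions match CytoNCA's undirected defaults: degree is the incident
edge count, betweenness is the unnormalized Brandes accumulation with each
unordered node pair counted once; pairs in different components contribute
nothing.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd


def degree_centrality(graph: nx.Graph) -> dict[str, int]:
    """Undirected edge count per node."""
    return {n: int(d) for n, d in graph.degree()}


def betweenness_centrality(
    graph: nx.Graph, normalized: bool = False
) -> dict[str, float]:
    """Shortest-path betweenness (unweighted); unnormalized by default."""
    return nx.betweenness_centrality(graph, normalized=normalized)


def centrality_table(graph: nx.Graph, normalized: bool = False) -> pd.DataFrame:
    """Per-node degree and betweenness, with node attributes carried along."""
    deg = degree_centrality(graph)
    bc = betweenness_centrality(graph, normalized=normalized)
    rows = [
        {
            "node_id": n,
            "biotype": graph.nodes[n].get("biotype", "unknown"),
            "degree": deg[n],
            "betweenness": bc[n],
        }
        for n in sorted(graph.nodes)
    ]
    return pd.DataFrame(
        rows, columns=["node_id", "biotype", "degree", "betweenness"]
    )


def select_key_nodes(
    centrality: pd.DataFrame, biotype_filter: str = "lncRNA", k: int = 7
) -> pd.DataFrame:
    """Top-k nodes of one biotype by degree, ties broken by betweenness
    then node id (deterministic); adds a 1-based ``key_rank`` column.

    Asking for more nodes than exist returns all candidates with a warning;
    k = 0 returns an empty table.
    """
    cand = centrality[centrality["biotype"] == biotype_filter].copy()
    if k > len(cand):
        warnings.warn(
            f"requested k={k} but only {len(cand)} {biotype_filter} nodes",
            stacklevel=2,
        )
        k = len(cand)
    cand = cand.sort_values(
        by=["degree", "betweenness", "node_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).head(k)
    cand["key_rank"] = range(1, len(cand) + 1)
    return cand.reset_index(drop=True)
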