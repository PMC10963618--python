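"""Assembly of co-expression competing triplets and the tripartite network.

A (lncRNA, miRNA, mRNA) trio is a competing triplet when both the lncRNA and
the mRNA are targeted by, and negatively co-expressed with, the common
miRNA. By default the differential directions must be consistent with
sponge regulation: lncRNA and mRNA move together, the miRNA moves the
opposite way (up-lncRNA / down-miRNA / up-mRNA, or the converse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .coexpression import CorrelationEdge


@dataclass(frozen=True)
class CeRNATriplet:
    lncRNA_id: str
    mirna_id: str
    mrna_id: str
    r_lnc_mi: float
    r_mi_mrna: float
    lnc_direction: str
    mi_direction: str
    mrna_direction: str


def assemble_triplets(
    lnc_edges: Iterable[CorrelationEdge],
    mrna_edges: Iterable[CorrelationEdge],
    de_calls: Mapping[str, str],
    require_directions: bool = True,
) -> list[CeRNATriplet]:
    """Cross each miRNA's retained lncRNA partners with its mRNA partners.

    ``de_calls`` maps every participating feature to its DE call (up/down/
    not_significant); a missing feature is an error. With
    ``require_directions`` (default) a triplet is kept only when lncRNA and
    mRNA share a direction opposite to the miRNA's, and all three are
    significant. Output is deterministically sorted.
    """
    by_mi_lnc: dict[str, list[CorrelationEdge]] = {}
    for e in lnc_edges:
        by_mi_lnc.setdefault(e.source_id, []).append(e)
    by_mi_mrna: dict[str, list[CorrelationEdge]] = {}
    for e in mrna_edges:
        by_mi_mrna.setdefault(e.source_id, []).append(e)

    def call_of(fid: str) -> str:
        if fid not in de_calls:
            raise ValueError(f"feature {fid} has no DE call")
        return de_calls[fid]

    triplets = []
    for mi in sorted(set(by_mi_lnc) & set(by_mi_mrna)):
        mi_dir = call_of(mi)
        for le in by_mi_lnc[mi]:
            lnc_dir = call_of(le.target_id)
            for me in by_mi_mrna[mi]:
                mrna_dir = call_of(me.target_id)
                if require_directions:
                    ok = (
                        lnc_dir == mrna_dir
                        and {lnc_dir, mi_dir} == {"up", "down"}
                    )
                    if not ok:
                        continue
                triplets.append(
                    CeRNATriplet(
                        lncRNA_id=le.target_id,
                        mirna_id=mi,
                        mrna_id=me.target_id,
                        r_lnc_mi=le.pearson_r,
                        r_mi_mrna=me.pearson_r,
                        lnc_direction=lnc_dir,
                        mi_direction=mi_dir,
                        mrna_direction=mrna_dir,
                    )
                )
    triplets.sort(key=lambda t: (t.lncRNA_id, t.mirna_id, t.mrna_id))
    return triplets


def build_network(triplets: Iterable[CeRNATriplet]) -> nx.Graph:
    """Tripartite ceRNA graph: lncRNA-miRNA and miRNA-mRNA edges only.

    Nodes carry ``biotype`` and ``direction``; edges carry ``interaction``
    and the Pearson ``r``. Nodes/edges shared between triplets are
    de-duplicated. An empty triplet set produces an empty graph with a
    warning.
    """
    g = nx.Graph()
    triplets = list(triplets)
    if not triplets:
        warnings.warn("building an empty ceRNA network", stacklevel=2)
        return g
    for t in triplets:
        g.add_node(t.lncRNA_id, biotype="lncRNA", direction=t.lnc_direction)
        g.add_node(t.mirna_id, biotype="miRNA", direction=t.mi_direction)
        g.add_node(t.mrna_id, biotype="mRNA", direction=t.mrna_direction)
        g.add_edge(
            t.lncRNA_id, t.mirna_id, interaction="lncRNA-miRNA", r=t.r_lnc_mi
        )
        g.add_edge(
            t.mirna_id, t.mrna_id, interaction="miRNA-mRNA", r=t.r_mi_mrna
        )
    return g


def triplet_table(triplets: Iterable[CeRNATriplet]) -> pd.DataFrame:
    """Flat TSV-ready table of triplets (also Sankey-ready: first 3 cols)."""
    rows = [
        {
            "lncRNA": t.lncRNA_id,
            "miRNA": t.mirna_id,
            "mRNA": t.mrna_id,
            "r_lnc_mi": t.r_lnc_mi,
            "r_mi_mrna": t.r_mi_mrna,
            "lnc_direction": t.lnc_direction,
            "mi_direction": t.mi_direction,
            "mrna_direction": t.mrna_direction,
        }
        for t in triplets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lncRNA",
            "miRNA",
            "mRNA",
            "r_lnc_mi",
            "r_mi_mrna",
            "lnc_direction",
            "mi_direction",
            "mrna_direction",
        ],
    )
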