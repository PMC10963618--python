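#!/usr/bin/env python
"""Key-lncRNA selection: degree and betweenness centrality on each ceRNA
network, lncRNAs ranked by degree with betweenness tie-break, top-k
reported (the CytoNCA-style step).
"""

import argparse
from pathlib import Path

from cerna_sponge.graph_metrics import centrality_table, select_key_nodes
from cerna_sponge.io_model import read_network

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--results", type=Path, default=Path("results/analysis"))
ap.add_argument("--top-k", type=int, default=7)
args = ap.parse_args()

for tag in ("CON_vs_MOD", "MOD_vs_TRT"):
    network = read_network(args.results / f"network_{tag}.graphml")
    table = centrality_table(network)
    table.to_csv(args.results / f"centrality_{tag}.tsv", sep="\t", index=False)
    key = select_key_nodes(table, biotype_filter="lncRNA", k=args.top_k)
    key.to_csv(args.results / f"key_lncRNAs_{tag}.tsv", sep="\t", index=False)
    names = ", ".join(key["node_id"])
    print(f"{tag}: {len(key)} key lncRNAs by degree/betweenness: {names}")
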