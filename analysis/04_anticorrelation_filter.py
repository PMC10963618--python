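#!/usr/bin/env python
"""Anti-correlation filtering: Pearson r between each targeting-supported
(miRNA, lncRNA) and (miRNA, mRNA) pair over the contrast's samples; edges
retained at r < -0.85. Reports retention of the planted sponge pairs.
"""

import argparse
from pathlib import Path

import pandas as pd

from cerna_sponge.coexpression import anticorrelated_edges
from cerna_sponge.diffexpr import tpm_normalize
from cerna_sponge.io_model import read_counts, read_group_map
from cerna_sponge.synthetic_data import GroundTruth
from cerna_sponge.targets import TargetPair

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--results", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

sim = args.results / "sim"
groups = read_group_map(sim / "groups.tsv")
tpm = {
    bt: tpm_normalize(read_counts(sim / f"counts_{bt}.tsv", bt, sim / "groups.tsv"))
    for bt in ("lncRNA", "miRNA", "mRNA")
}
truth = GroundTruth.from_json(sim / "truth.json")
planted_pairs = truth.target_pair_ids()

for contrast in (("CON", "MOD"), ("MOD", "TRT")):
    tag = f"{contrast[0]}_vs_{contrast[1]}"
    cand = pd.read_csv(args.results / f"target_pairs_{tag}.tsv", sep="\t")
    pairs = [
        TargetPair(r.miRNA, r.transcript, r.biotype, r.n_sites, r.best_site_type)
        for r in cand.itertuples(index=False)
    ]
    samples = [s for s, g in groups.items() if g in contrast]
    rows = []
    kept_planted = 0
    for biotype in ("lncRNA", "mRNA"):
        edges = anticorrelated_edges(
            tpm["miRNA"],
            tpm[biotype],
            [p for p in pairs if p.transcript_biotype == biotype],
            r_cut=-0.85,
            samples=samples,
        )
        for e in edges:
            rows.append((e.source_id, e.target_id, biotype, e.pearson_r, e.n_samples))
            kept_planted += (e.source_id, e.target_id) in planted_pairs
    pd.DataFrame(
        rows, columns=["miRNA", "target", "biotype", "pearson_r", "n_samples"]
    ).to_csv(args.results / f"anticorrelation_edges_{tag}.tsv", sep="\t", index=False)
    print(f"{tag}: {len(rows)} edges at r < -0.85 over {len(samples)} samples; "
          f"{kept_planted}/{len(planted_pairs)} planted sponge pairs retained")
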