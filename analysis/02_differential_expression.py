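#!/usr/bin/env python
"""Differential expression for both contrasts (CON vs MOD, MOD vs TRT) on
each biotype: exact NB test, BH correction, |log2FC| > 1 & padj < 0.05
calls, and the cross-contrast overlap of DE features.
"""

import argparse
from pathlib import Path

from cerna_sponge.diffexpr import de_contrast, de_feature_sets, overlap_de_sets
from cerna_sponge.io_model import read_counts

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--results", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

sim = args.results / "sim"
contrasts = [("CON", "MOD"), ("MOD", "TRT")]
de_sets: dict[str, list[set]] = {}
for biotype in ("lncRNA", "miRNA", "mRNA"):
    em = read_counts(sim / f"counts_{biotype}.tsv", biotype, sim / "groups.tsv")
    de_sets[biotype] = []
    for contrast in contrasts:
        table = de_contrast(em, contrast)
        tag = f"{contrast[0]}_vs_{contrast[1]}"
        out = args.results / f"de_{biotype}_{tag}.tsv"
        table.to_csv(out, sep="\t", index_label="feature_id")
        sets = de_feature_sets(table)
        de_sets[biotype].append(sets["de"])
        print(f"{biotype} {tag}: {len(sets['up'])} up, {len(sets['down'])} down")
    common = overlap_de_sets(*de_sets[biotype])
    (args.results / f"common_de_{biotype}.txt").write_text(
        "\n".join(common) + ("\n" if common else "")
    )
    print(f"{biotype}: {len(common)} DE features shared by both contrasts")
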