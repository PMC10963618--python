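#!/usr/bin/env python
"""Target prediction: seed-match miRNA targets among the DE features of
each contrast, and lncRNA target genes by the cis 10/100 kb windows and
the trans co-expression rule.
"""

import argparse
from pathlib import Path

import pandas as pd

from cerna_sponge.diffexpr import tpm_normalize
from cerna_sponge.io_model import read_annotation, read_counts, read_fasta
from cerna_sponge.targets import cis_targets, predict_targets, trans_targets

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--results", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

sim = args.results / "sim"
sequences = {r.id: r for r in read_fasta(sim / "mirna.fa")}
sequences.update({r.id: r for r in read_fasta(sim / "transcripts.fa")})

for contrast in (("CON", "MOD"), ("MOD", "TRT")):
    tag = f"{contrast[0]}_vs_{contrast[1]}"
    de_ids = {}
    for biotype in ("lncRNA", "miRNA", "mRNA"):
        de = pd.read_csv(args.results / f"de_{biotype}_{tag}.tsv", sep="\t",
                         index_col=0)
        de_ids[biotype] = sorted(de.index[de["call"] != "not_significant"])
    mirnas = [sequences[m] for m in de_ids["miRNA"]]
    transcripts = [sequences[t] for t in de_ids["lncRNA"] + de_ids["mRNA"]]
    biotype_of = {t: "lncRNA" for t in de_ids["lncRNA"]}
    biotype_of.update({t: "mRNA" for t in de_ids["mRNA"]})
    pairs = predict_targets(mirnas, transcripts, biotype_of)
    pd.DataFrame(
        [(p.mirna_id, p.transcript_id, p.transcript_biotype, p.n_sites,
          p.best_site_type) for p in pairs],
        columns=["miRNA", "transcript", "biotype", "n_sites", "best_site_type"],
    ).to_csv(args.results / f"target_pairs_{tag}.tsv", sep="\t", index=False)
    by_bt = {"lncRNA": 0, "mRNA": 0}
    for p in pairs:
        by_bt[p.transcript_biotype] += 1
    print(f"{tag}: {by_bt['lncRNA']} miRNA-lncRNA and {by_bt['mRNA']} "
          f"miRNA-mRNA seed-match pairs among DE features")

annotations = read_annotation(sim / "annotation.gtf")
lncs = [a for a in annotations if a.biotype == "lncRNA"]
genes = [a for a in annotations if a.biotype == "mRNA"]
for window in (10_000, 100_000):
    pairs = cis_targets(lncs, genes, window_bp=window)
    pd.DataFrame(
        [(p.lncRNA_id, p.gene_id, p.distance_bp) for p in pairs],
        columns=["lncRNA", "gene", "distance_bp"],
    ).to_csv(args.results / f"cis_pairs_{window // 1000}kb.tsv", sep="\t",
             index=False)
    print(f"cis window {window // 1000} kb: {len(pairs)} lncRNA-gene pairs")

lnc_tpm = tpm_normalize(
    read_counts(sim / "counts_lncRNA.tsv", "lncRNA", sim / "groups.tsv"))
mrna_tpm = tpm_normalize(
    read_counts(sim / "counts_mRNA.tsv", "mRNA", sim / "groups.tsv"))
trans = trans_targets(lnc_tpm, mrna_tpm, r_cut=0.9, min_expressed=5)
pd.DataFrame(
    [(p.lncRNA_id, p.gene_id, p.pearson_r, p.n_expressed_samples) for p in trans],
    columns=["lncRNA", "gene", "pearson_r", "n_expressed_samples"],
).to_csv(args.results / "trans_pairs.tsv", sep="\t", index=False)
print(f"trans rule (|r| >= 0.9, > 5 expressed samples): {len(trans)} pairs")
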