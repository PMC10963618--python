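#!/usr/bin/env python
"""Over-representation analysis of the DE mRNAs of each contrast against
the simulated annotation terms (hypergeometric test, BH correction,
significance at adjusted p < 0.05).
"""

import argparse
from pathlib import Path

import pandas as pd

from cerna_sponge.enrichment import hypergeom_ora
from cerna_sponge.io_model import read_gmt
from cerna_sponge.synthetic_data import GroundTruth

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--results", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

sim = args.results / "sim"
terms = read_gmt(sim / "terms.gmt")
truth = GroundTruth.from_json(sim / "truth.json")
background = truth.feature_ids["mRNA"]

for tag in ("CON_vs_MOD", "MOD_vs_TRT"):
    de = pd.read_csv(args.results / f"de_mRNA_{tag}.tsv", sep="\t", index_col=0)
    study = sorted(de.index[de["call"] != "not_significant"])
    res = hypergeom_ora(study, background, terms)
    res.to_csv(args.results / f"enrichment_{tag}.tsv", sep="\t", index=False)
    sig = res[res["significant"]]
    planted_hits = set(sig["term_id"]) & set(truth.enriched_term_ids)
    print(f"{tag}: {len(study)} DE mRNAs; {len(sig)} significant terms "
          f"(adj p < 0.05), including {len(planted_hits)}/"
          f"{len(truth.enriched_term_ids)} planted perturbation-responsive sets")
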