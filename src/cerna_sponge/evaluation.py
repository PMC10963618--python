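"""Scoring of pipeline output against the simulator's planted ground truth.

Used by the acceptance checks and the reproduction script: runs the full
analysis in memory on one simulated replicate and scores

* planted-DE recovery (sensitivity and empirical FDR over all biotypes and
  contrasts),
* retention of planted anti-correlation edges through the r < -0.85 filter,
* precision/recall/F1 of the recovered competing triplets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import cerna, coexpression, diffexpr, targets
from .synthetic_data import SimulationConfig, simulate_all


@dataclass
class ReplicateScore:
    de_sensitivity: float
    de_fdr: float
    edge_retention: float
    triplet_precision: float
    triplet_recall: float
    triplet_f1: float
    n_triplets_recovered: int


def score_replicate(
    seed: int,
    config: SimulationConfig | None = None,
    r_cut: float = -0.85,
    min_site_type: str = "7mer-A1",
) -> ReplicateScore:
    """Simulate one dataset, run DE -> targeting -> correlation -> triplet
    assembly per contrast, and score everything against the ground truth."""
    if config is None:
        config = SimulationConfig()
    config = dataclasses.replace(config, rng_seed=seed)
    ds = simulate_all(config)
    truth = ds.truth
    tpm = {bt: diffexpr.tpm_normalize(em) for bt, em in ds.matrices.items()}
    groups = next(iter(ds.matrices.values())).groups

    de_tp = de_fp = de_planted = 0
    edge_kept = edge_total = 0
    trip_tp = trip_fp = trip_fn = 0

    for contrast in config.contrasts:
        calls: dict[str, str] = {}
        de_ids: dict[str, set[str]] = {}
        for bt, em in ds.matrices.items():
            table = diffexpr.de_contrast(em, contrast)
            calls.update(table["call"].to_dict())
            de_ids[bt] = diffexpr.de_feature_sets(table)["de"]
            planted = truth.de_directions(bt, contrast)
            de_planted += len(planted)
            de_tp += sum(1 for f in de_ids[bt] if f in planted)
            de_fp += sum(1 for f in de_ids[bt] if f not in planted)

        # targeting on DE-called features, as in the pipeline
        mirnas = [ds.sequences[m] for m in sorted(de_ids["miRNA"])]
        transcripts = [
            ds.sequences[t]
            for t in sorted(de_ids["lncRNA"]) + sorted(de_ids["mRNA"])
        ]
        biotype_of = {t: "lncRNA" for t in de_ids["lncRNA"]}
        biotype_of.update({t: "mRNA" for t in de_ids["mRNA"]})
        pairs = targets.predict_targets(
            mirnas, transcripts, biotype_of, min_site_type=min_site_type
        )
        contrast_samples = [s for s in groups if groups[s] in contrast]
        lnc_edges = coexpression.anticorrelated_edges(
            tpm["miRNA"],
            tpm["lncRNA"],
            [p for p in pairs if p.transcript_biotype == "lncRNA"],
            r_cut=r_cut,
            samples=contrast_samples,
        )
        mrna_edges = coexpression.anticorrelated_edges(
            tpm["miRNA"],
            tpm["mRNA"],
            [p for p in pairs if p.transcript_biotype == "mRNA"],
            r_cut=r_cut,
            samples=contrast_samples,
        )
        triplets = cerna.assemble_triplets(lnc_edges, mrna_edges, calls)
        got = {(t.lncRNA_id, t.mirna_id, t.mrna_id) for t in triplets}
        planted_trips = truth.triplet_ids()
        trip_tp += len(got & planted_trips)
        trip_fp += len(got - planted_trips)
        trip_fn += len(planted_trips - got)

        # planted anti-correlation pairs through the filter, measured on the
        # truth's own candidate list (isolates the correlation stage)
        lnc_cand = [
            targets.TargetPair(t.mirna_id, t.lncRNA_id, "lncRNA", 1, "8mer")
            for t in truth.triplets
        ]
        mrna_cand = [
            targets.TargetPair(t.mirna_id, t.mrna_id, "mRNA", 1, "8mer")
            for t in truth.triplets
        ]
        kept = coexpression.anticorrelated_edges(
            tpm["miRNA"], tpm["lncRNA"], lnc_cand, r_cut=r_cut,
            samples=contrast_samples,
        ) + coexpression.anticorrelated_edges(
            tpm["miRNA"], tpm["mRNA"], mrna_cand, r_cut=r_cut,
            samples=contrast_samples,
        )
        edge_kept += len(kept)
        edge_total += len(lnc_cand) + len(mrna_cand)

    n_called = de_tp + de_fp
    prec = trip_tp / (trip_tp + trip_fp) if trip_tp + trip_fp else 0.0
    rec = trip_tp / (trip_tp + trip_fn) if trip_tp + trip_fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return ReplicateScore(
        de_sensitivity=de_tp / de_planted if de_planted else 0.0,
        de_fdr=de_fp / n_called if n_called else 0.0,
        edge_retention=edge_kept / edge_total if edge_total else 0.0,
        triplet_precision=prec,
        triplet_recall=rec,
        triplet_f1=f1,
        n_triplets_recovered=trip_tp,
    )


def average_scores(scores: list[ReplicateScore]) -> dict[str, float]:
    """Mean of every metric across replicates."""
    fields = [f.name for f in dataclasses.fields(ReplicateScore)]
    return {
        f: float(np.mean([getattr(s, f) for s in scores])) for f in fields
    }
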