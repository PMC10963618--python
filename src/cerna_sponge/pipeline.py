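"""End-to-end orchestration: simulate/load -> TPM -> DE -> targeting ->
anti-correlation -> triplets -> centrality -> enrichment, with a manifest.

Each stage writes plain-text tables under the output directory and records
them (with SHA-256 hashes, parameters and the seed) in ``manifest.json``;
rerunning with an identical config and seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cerna, coexpression, diffexpr, enrichment, graph_metrics, targets
from .io_model import (
    ConfigurationError,
    ExpressionMatrix,
    read_annotation,
    read_counts,
    read_fasta,
    read_gmt,
    write_network,
)
from .synthetic_data import SimulationConfig, simulate_all, write_simulation


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative run configuration; simulated or file-based inputs.

    When ``simulate`` is set, inputs are generated; otherwise the
    ``counts_*``/``groups``/``*_fasta``/``annotation``/``terms`` paths must
    all be provided. Thresholds default to the analysis' standard values:
    |log2FC| > 1, adjusted p < 0.05 (q < 0.01 without replicates),
    anti-correlation r < -0.85, cis window 100 kb, trans |r| >= 0.9 in > 5
    expressed samples.
    """

    out_dir: str = "results/run"
    simulate: SimulationConfig | None = None
    counts_lncRNA: str | None = None
    counts_miRNA: str | None = None
    counts_mRNA: str | None = None
    groups_file: str | None = None
    mirna_fasta: str | None = None
    transcript_fasta: str | None = None
    annotation: str | None = None
    terms: str | None = None
    contrasts: list[tuple[str, str]] | None = None
    lfc_cut: float = 1.0
    alpha: float = 0.05
    q_cut: float = 0.01
    r_cut: float = -0.85
    cis_window: int = 100_000
    trans_r_cut: float = 0.9
    min_expressed_samples: int = 5
    expression_floor: float = 0.1
    min_site_type: str = "7mer-A1"
    top_k: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.q_cut < 1:
            raise ConfigurationError(f"q_cut must be in (0,1), got {self.q_cut}")
        if self.lfc_cut < 0:
            raise ConfigurationError("lfc_cut must be non-negative")
        if not -1.0 <= self.r_cut <= 0.0:
            raise ConfigurationError("r_cut must lie in [-1, 0]")
        if not 0.0 <= self.trans_r_cut <= 1.0:
            raise ConfigurationError("trans_r_cut must lie in [0, 1]")
        if self.cis_window <= 0:
            raise ConfigurationError("cis_window must be positive")
        if self.min_site_type not in targets.SITE_TYPES:
            raise ConfigurationError(f"unknown site type {self.min_site_type!r}")
        if self.top_k < 0:
            raise ConfigurationError("top_k must be non-negative")
        if self.simulate is None:
            needed = [
                self.counts_lncRNA,
                self.counts_miRNA,
                self.counts_mRNA,
                self.groups_file,
            ]
            if any(p is None for p in needed):
                raise ConfigurationError(
                    "either a simulate block or all counts/groups paths required"
                )


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config; the ``simulate`` block maps onto
    SimulationConfig fields."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = doc.pop("simulate", None)
    if sim is not None:
        sim = SimulationConfig(**{k: _tuplify(v) for k, v in sim.items()})
    if "contrasts" in doc and doc["contrasts"] is not None:
        doc["contrasts"] = [tuple(c) for c in doc["contrasts"]]
    return PipelineConfig(simulate=sim, **doc)


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        # ------------------------------------------------------------- input
        stage = "input"
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, rng_seed=config.rng_seed)
            dataset = simulate_all(sim_cfg)
            sim_paths = write_simulation(dataset, out / "sim")
            artifacts.update({f"sim/{k}": v for k, v in sim_paths.items()})
            matrices = dataset.matrices
            sequences = dataset.sequences
            annotations = dataset.annotations
            terms = dataset.terms
        else:
            matrices = {
                bt: read_counts(path, bt, config.groups_file)
                for bt, path in (
                    ("lncRNA", config.counts_lncRNA),
                    ("miRNA", config.counts_miRNA),
                    ("mRNA", config.counts_mRNA),
                )
            }
            sequences = {}
            for path, alphabet in (
                (config.mirna_fasta, "RNA"),
                (config.transcript_fasta, "RNA"),
            ):
                if path:
                    for rec in read_fasta(path):
                        sequences[rec.id] = rec
            annotations = read_annotation(config.annotation) if config.annotation else []
            terms = read_gmt(config.terms) if config.terms else []

        groups = next(iter(matrices.values())).groups
        declared = sorted(set(groups.values()))
        if config.contrasts is not None:
            contrasts = [tuple(c) for c in config.contrasts]
        elif config.simulate is not None:
            contrasts = config.simulate.contrasts
        else:
            contrasts = [
                (declared[i], declared[i + 1]) for i in range(len(declared) - 1)
            ]
        for c in contrasts:
            bad = [g for g in c if g not in declared]
            if bad:
                raise ConfigurationError(f"contrast {c} uses unknown group(s) {bad}")

        # --------------------------------------------------------------- TPM
        stage = "tpm"
        tpm: dict[str, ExpressionMatrix] = {}
        for bt, em in matrices.items():
            tpm[bt] = diffexpr.tpm_normalize(em)
            p = out / f"tpm_{bt}.tsv"
            _write_tsv(tpm[bt].values, p, index_label="feature_id")
            artifacts[f"tpm_{bt}"] = p

        # ---------------------------------------------------------------- DE
        stage = "differential_expression"
        de_tables: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
        for contrast in contrasts:
            de_tables[contrast] = {}
            for bt, em in matrices.items():
                table = diffexpr.de_contrast(
                    em,
                    contrast,
                    lfc_cut=config.lfc_cut,
                    padj_cut=config.alpha,
                    q_cut=config.q_cut,
                )
                de_tables[contrast][bt] = table
                p = out / f"de_{bt}_{contrast[0]}_vs_{contrast[1]}.tsv"
                _write_tsv(table, p, index_label="feature_id")
                artifacts[f"de_{bt}_{contrast[0]}_vs_{contrast[1]}"] = p
        if len(contrasts) >= 2:
            for bt in matrices:
                sets = [
                    diffexpr.de_feature_sets(de_tables[c][bt])["de"]
                    for c in contrasts[:2]
                ]
                common = diffexpr.overlap_de_sets(*sets)
                p = out / f"common_de_{bt}.txt"
                p.write_text("\n".join(common) + ("\n" if common else ""))
                artifacts[f"common_de_{bt}"] = p

        # ----------------------------------------------------- lncRNA targets
        stage = "cis_trans_targets"
        lnc_ann = [a for a in annotations if a.biotype == "lncRNA"]
        mrna_ann = [a for a in annotations if a.biotype == "mRNA"]
        if lnc_ann and mrna_ann:
            cis = targets.cis_targets(lnc_ann, mrna_ann, window_bp=config.cis_window)
            df = pd.DataFrame(
                [(c.lncRNA_id, c.gene_id, c.distance_bp) for c in cis],
                columns=["lncRNA", "gene", "distance_bp"],
            ).sort_values(["lncRNA", "gene"])
            p = out / "cis_pairs.tsv"
            _write_tsv(df, p)
            artifacts["cis_pairs"] = p
        trans = targets.trans_targets(
            tpm["lncRNA"],
            tpm["mRNA"],
            r_cut=config.trans_r_cut,
            min_expressed=config.min_expressed_samples,
            expression_floor=config.expression_floor,
        )
        df = pd.DataFrame(
            [
                (t.lncRNA_id, t.gene_id, t.pearson_r, t.n_expressed_samples)
                for t in trans
            ],
            columns=["lncRNA", "gene", "pearson_r", "n_expressed_samples"],
        ).sort_values(["lncRNA", "gene"])
        p = out / "trans_pairs.tsv"
        _write_tsv(df, p)
        artifacts["trans_pairs"] = p

        # ------------------------------------------- per-contrast ceRNA stages
        summary_rows = []
        for contrast in contrasts:
            tag = f"{contrast[0]}_vs_{contrast[1]}"
            stage = f"targets[{tag}]"
            calls: dict[str, str] = {}
            de_ids: dict[str, set[str]] = {}
            for bt in matrices:
                table = de_tables[contrast][bt]
                calls.update(table["call"].to_dict())
                de_ids[bt] = diffexpr.de_feature_sets(table)["de"]
            mirna_seqs = [
                sequences[m] for m in sorted(de_ids["miRNA"]) if m in sequences
            ]
            transcript_ids = sorted(de_ids["lncRNA"]) + sorted(de_ids["mRNA"])
            transcript_seqs = [
                sequences[t] for t in transcript_ids if t in sequences
            ]
            biotype_of = {t: "lncRNA" for t in de_ids["lncRNA"]}
            biotype_of.update({t: "mRNA" for t in de_ids["mRNA"]})
            pairs = targets.predict_targets(
                mirna_seqs,
                transcript_seqs,
                biotype_of,
                min_site_type=config.min_site_type,
            )
            df = pd.DataFrame(
                [
                    (
                        q.mirna_id,
                        q.transcript_id,
                        q.transcript_biotype,
                        q.n_sites,
                        q.best_site_type,
                    )
                    for q in pairs
                ],
                columns=[
                    "miRNA",
                    "transcript",
                    "biotype",
                    "n_sites",
                    "best_site_type",
                ],
            ).sort_values(["miRNA", "transcript"])
            p = out / f"target_pairs_{tag}.tsv"
            _write_tsv(df, p)
            artifacts[f"target_pairs_{tag}"] = p

            stage = f"correlate[{tag}]"
            contrast_samples = [s for s in groups if groups[s] in contrast]
            lnc_pairs = [q for q in pairs if q.transcript_biotype == "lncRNA"]
            mrna_pairs = [q for q in pairs if q.transcript_biotype == "mRNA"]
            lnc_edges = coexpression.anticorrelated_edges(
                tpm["miRNA"],
                tpm["lncRNA"],
                lnc_pairs,
                r_cut=config.r_cut,
                samples=contrast_samples,
            )
            mrna_edges = coexpression.anticorrelated_edges(
                tpm["miRNA"],
                tpm["mRNA"],
                mrna_pairs,
                r_cut=config.r_cut,
                samples=contrast_samples,
            )
            edges_df = pd.DataFrame(
                [
                    (e.source_id, e.target_id, kind, e.pearson_r, e.n_samples)
                    for kind, edges in (
                        ("lncRNA-miRNA", lnc_edges),
                        ("miRNA-mRNA", mrna_edges),
                    )
                    for e in edges
                ],
                columns=["miRNA", "target", "interaction", "pearson_r", "n_samples"],
            ).sort_values(["miRNA", "target"])
            p = out / f"anticorrelation_edges_{tag}.tsv"
            _write_tsv(edges_df, p)
            artifacts[f"anticorrelation_edges_{tag}"] = p

            stage = f"cerna[{tag}]"
            triplets = cerna.assemble_triplets(lnc_edges, mrna_edges, calls)
            tdf = cerna.triplet_table(triplets)
            p = out / f"triplets_{tag}.tsv"
            _write_tsv(tdf, p)
            artifacts[f"triplets_{tag}"] = p
            network = cerna.build_network(triplets)
            if network.number_of_nodes() > 0:
                for fmt, ext in (("SIF", "sif"), ("GraphML", "graphml")):
                    p = out / f"network_{tag}.{ext}"
                    write_network(network, fmt, p)
                    artifacts[f"network_{tag}_{ext}"] = p
            p = out / f"sankey_{tag}.tsv"
            _write_tsv(tdf[["lncRNA", "miRNA", "mRNA"]], p)
            artifacts[f"sankey_{tag}"] = p

            stage = f"rank[{tag}]"
            table = graph_metrics.centrality_table(network)
            key = graph_metrics.select_key_nodes(
                table, biotype_filter="lncRNA", k=config.top_k
            )
            p = out / f"centrality_{tag}.tsv"
            _write_tsv(table, p)
            artifacts[f"centrality_{tag}"] = p
            p = out / f"key_lncRNAs_{tag}.tsv"
            _write_tsv(key, p)
            artifacts[f"key_lncRNAs_{tag}"] = p

            stage = f"enrich[{tag}]"
            if terms:
                background = set(matrices["mRNA"].feature_ids)
                study = de_ids["mRNA"] & background
                ora = enrichment.hypergeom_ora(
                    study, background, terms, alpha=config.alpha
                )
                p = out / f"enrichment_{tag}.tsv"
                _write_tsv(ora, p)
                artifacts[f"enrichment_{tag}"] = p

            summary_rows.append(
                {
                    "contrast": tag,
                    "de_lncRNA": len(de_ids["lncRNA"]),
                    "de_miRNA": len(de_ids["miRNA"]),
                    "de_mRNA": len(de_ids["mRNA"]),
                    "target_pairs": len(pairs),
                    "anticorrelation_edges": len(lnc_edges) + len(mrna_edges),
                    "triplets": len(triplets),
                    "network_nodes": network.number_of_nodes(),
                    "network_edges": network.number_of_edges(),
                    "key_lncRNAs": len(key),
                }
            )

        stage = "manifest"
        summary = pd.DataFrame(summary_rows)
        p = out / "summary.tsv"
        _write_tsv(summary, p)
        artifacts["summary"] = p
        manifest = {
            "seed": config.rng_seed,
            "parameters": {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("simulate",)
            },
            "simulate": (
                dataclasses.asdict(config.simulate)
                if config.simulate is not None
                else None
            ),
            "artifacts": {
                name: {"path": str(path), "sha256": _sha256(path)}
                for name, path in sorted(artifacts.items())
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=list))
        return manifest
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
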