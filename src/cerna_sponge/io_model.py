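"""Domain types and typed readers/writers for the pipeline's external formats.

All genomic coordinates are held internally in the GTF convention: 1-based,
closed intervals. BED input (0-based, half-open) is converted at the boundary
and converted back on write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

BIOTYPES = ("lncRNA", "miRNA", "mRNA")

#: edge labels used in SIF / GraphML output, keyed by the non-miRNA endpoint
EDGE_INTERACTIONS = ("lncRNA-miRNA", "miRNA-mRNA")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad coordinates, non-numeric cells)."""


class ConfigurationError(ValueError):
    """Inconsistent run configuration (missing group labels, unknown dialect...)."""


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix for one RNA biotype.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
        Raw counts (non-negative integers) or TPM (non-negative floats),
        declared by ``units``.
    biotype
        One of ``lncRNA``, ``miRNA``, ``mRNA``.
    groups
        Mapping sample id -> group label; every sample column must appear.
    units
        ``"counts"`` or ``"TPM"``.
    """

    values: pd.DataFrame
    biotype: str
    groups: dict[str, str]
    units: str = "counts"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ConfigurationError(f"unknown biotype {self.biotype!r}")
        if self.units not in ("counts", "TPM"):
            raise ConfigurationError(f"unknown units {self.units!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric cell in expression matrix")
        if np.isnan(arr).any():
            raise FormatError("NaN cell in expression matrix")
        if (arr < 0).any():
            raise FormatError("negative cell in expression matrix")
        if self.units == "counts" and not np.allclose(arr, np.round(arr)):
            raise FormatError("counts matrix contains non-integer values")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ConfigurationError(f"samples missing from group map: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, *group_labels: str) -> list[str]:
        """Sample ids belonging to the given group labels, in column order."""
        want = set(group_labels)
        return [s for s in self.values.columns if self.groups[s] in want]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[list(samples)],
            biotype=self.biotype,
            groups={s: self.groups[s] for s in samples},
            units=self.units,
        )


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic location of one feature, 1-based closed coordinates."""

    feature_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    length: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"{self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise FormatError(f"{self.feature_id}: bad strand {self.strand!r}")
        if (
            self.biotype == "lncRNA"
            and self.length is not None
            and self.length <= 200
        ):
            raise FormatError(
                f"{self.feature_id}: lncRNA length must exceed 200 nt "
                f"(got {self.length})"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with a declared alphabet (RNA or DNA)."""

    id: str
    residues: str
    alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"{self.id}: empty sequence")
        if self.alphabet not in ("RNA", "DNA"):
            raise FormatError(f"{self.id}: bad alphabet {self.alphabet!r}")
        valid = set("ACGUN") if self.alphabet == "RNA" else set("ACGTN")
        bad = set(self.residues.upper()) - valid
        if bad:
            raise FormatError(f"{self.id}: invalid residues {sorted(bad)}")


@dataclass(frozen=True)
class TermAnnotation:
    """One annotation term (GO/KEGG-style) with its member gene set."""

    term_id: str
    term_name: str
    member_gene_ids: frozenset[str]
    namespace: str = "pathway"

    def __post_init__(self) -> None:
        if not self.member_gene_ids:
            raise FormatError(f"{self.term_id}: empty member set")


# ---------------------------------------------------------------------------
# counts / groups
# ---------------------------------------------------------------------------

def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise FormatError(
            f"{path}: group map needs columns sample_id, group "
            f"(found {list(df.columns)})"
        )
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    return dict(zip(df["sample_id"], df["group"]))


def read_counts(
    path: str | Path, biotype: str, group_map_path: str | Path
) -> ExpressionMatrix:
    """Read a feature x sample raw-count TSV plus its sample->group map.

    The first column holds feature ids; every remaining column is a sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-integer count cell ({exc})") from exc
    groups = read_group_map(group_map_path)
    return ExpressionMatrix(values=df, biotype=biotype, groups=groups)


def write_counts(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="feature_id")


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation (GTF / GFF3 / BED)
# ---------------------------------------------------------------------------

_GTF_EXT = {".gtf", ".gff", ".gff3"}


def _annotation_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("gtf", "bed"):
            raise ConfigurationError(f"unknown annotation dialect {dialect!r}")
        return dialect
    ext = path.suffix.lower()
    if ext in _GTF_EXT:
        return "gtf"
    if ext == ".bed":
        return "bed"
    raise ConfigurationError(
        f"{path}: cannot infer annotation dialect from extension {ext!r}; "
        "pass dialect='gtf' or 'bed'"
    )


def read_annotation(
    path: str | Path, dialect: str | None = None
) -> list[FeatureAnnotation]:
    """Read GTF/GFF3 (1-based closed) or BED (0-based half-open) annotation.

    BED starts are shifted by +1 to the internal 1-based closed convention.
    """
    path = Path(path)
    if _annotation_dialect(path, dialect) == "bed":
        return _read_bed(path)
    return _read_gtf(path)


def _read_bed(path: Path) -> list[FeatureAnnotation]:
    names = ["chrom", "start", "end", "name", "score", "strand", "biotype"]
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    out = []
    for row in df.itertuples(index=False):
        start = int(row.start) + 1  # BED is 0-based half-open
        end = int(row.end)
        strand = getattr(row, "strand", ".")
        out.append(
            FeatureAnnotation(
                feature_id=str(getattr(row, "name", f"{row.chrom}:{start}-{end}")),
                biotype=str(getattr(row, "biotype", "mRNA")),
                chrom=str(row.chrom),
                start=start,
                end=end,
                strand=strand if strand in ("+", "-") else "unknown",
                length=end - start + 1,
            )
        )
    return out


def _read_gtf(path: Path) -> list[FeatureAnnotation]:
    import gffutils

    out = []
    for feat in gffutils.DataIterator(str(path)):
        attrs = feat.attributes
        fid = None
        for key in ("feature_id", "transcript_id", "gene_id", "ID", "Name"):
            if key in attrs:
                fid = attrs[key][0]
                break
        if fid is None:
            raise FormatError(f"{path}: record without an id attribute: {feat}")
        biotype = "mRNA"
        for key in ("biotype", "transcript_biotype", "gene_biotype"):
            if key in attrs:
                biotype = attrs[key][0]
                break
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        out.append(
            FeatureAnnotation(
                feature_id=fid,
                biotype=biotype,
                chrom=feat.seqid,
                start=int(feat.start),
                end=int(feat.end),
                strand=strand,
                length=int(feat.end) - int(feat.start) + 1,
            )
        )
    return out


def write_annotation_gtf(
    annotations: Iterable[FeatureAnnotation], path: str | Path, source: str = "sim"
) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            strand = a.strand if a.strand in ("+", "-") else "."
            attrs = f'gene_id "{a.feature_id}"; gene_biotype "{a.biotype}";'
            fh.write(
                f"{a.chrom}\t{source}\ttranscript\t{a.start}\t{a.end}\t."
                f"\t{strand}\t.\t{attrs}\n"
            )


def write_annotation_bed(
    annotations: Iterable[FeatureAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            strand = a.strand if a.strand in ("+", "-") else "."
            fh.write(
                f"{a.chrom}\t{a.start - 1}\t{a.end}\t{a.feature_id}\t0\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# sequences (FASTA)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "RNA") -> list[SequenceRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), alphabet=alphabet)
        )
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# term sets (GMT-style)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, namespace: str = "pathway") -> list[TermAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line with <3 fields: {line!r}")
            out.append(
                TermAnnotation(
                    term_id=fields[0],
                    term_name=fields[1],
                    member_gene_ids=frozenset(fields[2:]),
                    namespace=namespace,
                )
            )
    return out


def write_gmt(terms: Iterable[TermAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            members = "\t".join(sorted(t.member_gene_ids))
            fh.write(f"{t.term_id}\t{t.term_name}\t{members}\n")


# ---------------------------------------------------------------------------
# networks (SIF / GraphML)
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Export a ceRNA network for Cytoscape (SIF or GraphML).

    SIF rows are ``source<TAB>interaction<TAB>target`` with the interaction
    label taken from the edge's ``interaction`` attribute. GraphML carries the
    node attributes ``biotype``, ``degree``, ``betweenness`` and ``key_rank``
    when present.
    """
    if fmt not in ("SIF", "GraphML"):
        raise ConfigurationError(f"unknown network format {fmt!r}")
    if graph.number_of_edges() == 0:
        warnings.warn("writing an empty network", stacklevel=2)
    if fmt == "SIF":
        with open(path, "w") as fh:
            fh.write("source\tinteraction\ttarget\n")
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{data.get('interaction', 'pp')}\t{v}\n")
    else:
        # GraphML writer requires attribute values to be scalars
        g = nx.Graph()
        for n, data in sorted(graph.nodes(data=True)):
            g.add_node(n, **{k: v for k, v in data.items() if v is not None})
        for u, v, data in sorted(graph.edges(data=True)):
            g.add_edge(u, v, **{k: w for k, w in data.items() if w is not None})
        nx.write_graphml(g, str(path))


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    path = Path(path)
    if fmt is None:
        fmt = "SIF" if path.suffix.lower() == ".sif" else "GraphML"
    if fmt == "SIF":
        g = nx.Graph()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("source"):
                raise FormatError(f"{path}: missing SIF header")
            for line in fh:
                if not line.strip():
                    continue
                src, inter, tgt = line.rstrip("\n").split("\t")
                g.add_edge(src, tgt, interaction=inter)
        return g
    return nx.read_graphml(str(path))
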