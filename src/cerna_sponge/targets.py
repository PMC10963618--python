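"""miRNA target prediction by canonical seed matching, and lncRNA target
prediction via the cis genomic-window and trans co-expression rules.

Seed sites follow the canonical taxonomy. Writing the target 5'->3', a site is
built around an exact Watson-Crick match to the miRNA seed (positions 2-7,
the "core"); an additional match to miRNA position 8 immediately 5' of the
core and/or an adenosine immediately 3' of it upgrade the class:

    8mer      comp(m8) + core-match + A
    7mer-m8   comp(m8) + core-match
    7mer-A1   core-match + A
    6mer      core-match alone

G:U wobble pairs are not counted as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_model import ExpressionMatrix, FeatureAnnotation, SequenceRecord

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str) -> str:
    """Upper-case and convert T->U."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return normalize_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


def seed_core(mirna_seq: str) -> str:
    """The 6-nt target match to miRNA positions 2-7, written 5'->3'."""
    s = normalize_rna(mirna_seq)
    if len(s) < 8:
        raise ValueError(f"miRNA shorter than 8 nt: {s!r}")
    return reverse_complement(s[1:7])


def m8_match(mirna_seq: str) -> str:
    """The single target nucleotide complementary to miRNA position 8."""
    s = normalize_rna(mirna_seq)
    if len(s) < 8:
        raise ValueError(f"miRNA shorter than 8 nt: {s!r}")
    return s[7].translate(_RNA_COMPLEMENT)


@dataclass(frozen=True)
class SeedSite:
    """One seed-match locus on a transcript (1-based, closed coordinates)."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        length = self.site_end - self.site_start + 1
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if length != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, got {length}"
            )


@dataclass(frozen=True)
class TargetPair:
    """A predicted miRNA -> transcript interaction."""

    mirna_id: str
    transcript_id: str
    transcript_biotype: str
    n_sites: int
    best_site_type: str

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("TargetPair needs at least one site")


@dataclass(frozen=True)
class CisPair:
    """A lncRNA / coding-gene pair within a genomic window."""

    lncRNA_id: str
    gene_id: str
    distance_bp: int


@dataclass(frozen=True)
class TransPair:
    """A lncRNA / coding-gene pair linked by expression correlation."""

    lncRNA_id: str
    gene_id: str
    pearson_r: float
    n_expressed_samples: int


def classify_locus(transcript_seq: str, core_pos: int, m8c: str) -> tuple[str, int, int]:
    """Classify the site whose 6-nt core starts at ``core_pos`` (0-based).

    Returns (site_type, start, end) with 1-based closed coordinates of the
    span the class covers. Exactly one (the strongest) class is assigned.
    """
    t = transcript_seq
    has_m8 = core_pos > 0 and t[core_pos - 1] == m8c
    has_a1 = core_pos + 6 < len(t) and t[core_pos + 6] == "A"
    if has_m8 and has_a1:
        return "8mer", core_pos, core_pos + 7
    if has_m8:
        return "7mer-m8", core_pos, core_pos + 6
    if has_a1:
        return "7mer-A1", core_pos + 1, core_pos + 7
    return "6mer", core_pos + 1, core_pos + 6


def find_seed_sites(
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    allowed_types: Sequence[str] = SITE_TYPES,
) -> list[SeedSite]:
    """All seed-match sites of ``mirna`` on ``transcript``.

    Every occurrence of the seed core is reported (overlaps included), each
    with the strongest class it supports; ``allowed_types`` filters the
    output. Raises ValueError for miRNAs shorter than 8 nt.
    """
    mseq = normalize_rna(mirna.residues)
    if len(mseq) < 8:
        raise ValueError(f"{mirna.id}: miRNA shorter than 8 nt")
    tseq = normalize_rna(transcript.residues)
    core = seed_core(mseq)
    m8c = m8_match(mseq)
    allowed = set(allowed_types)
    sites = []
    pos = tseq.find(core)
    while pos != -1:
        site_type, start, end = classify_locus(tseq, pos, m8c)
        if site_type in allowed:
            sites.append(
                SeedSite(
                    mirna_id=mirna.id,
                    transcript_id=transcript.id,
                    site_start=start,
                    site_end=end,
                    site_type=site_type,
                )
            )
        pos = tseq.find(core, pos + 1)
    return sites


def predict_targets(
    mirnas: Iterable[SequenceRecord],
    transcripts: Iterable[SequenceRecord],
    transcript_biotypes: Mapping[str, str],
    min_site_type: str = "7mer-A1",
) -> list[TargetPair]:
    """One TargetPair per (miRNA, transcript) with >=1 site at or above
    ``min_site_type`` in the class hierarchy 8mer > 7mer-m8 > 7mer-A1 > 6mer.

    Applied identically to mRNA and lncRNA transcripts.
    """
    min_rank = SITE_RANK[min_site_type]
    allowed = [t for t in SITE_TYPES if SITE_RANK[t] >= min_rank]
    transcripts = list(transcripts)
    pairs = []
    for mi in mirnas:
        for tr in transcripts:
            sites = find_seed_sites(mi, tr, allowed_types=allowed)
            if sites:
                best = max(sites, key=lambda s: SITE_RANK[s.site_type])
                pairs.append(
                    TargetPair(
                        mirna_id=mi.id,
                        transcript_id=tr.id,
                        transcript_biotype=transcript_biotypes.get(tr.id, "mRNA"),
                        n_sites=len(sites),
                        best_site_type=best.site_type,
                    )
                )
    return pairs


def interval_gap(a: FeatureAnnotation, b: FeatureAnnotation) -> int | None:
    """Gap in bp between two features; 0 if they overlap, None if on
    different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start <= b.end and b.start <= a.end:
        return 0
    return max(a.start - b.end, b.start - a.end)


def cis_targets(
    lncrnas: Sequence[FeatureAnnotation],
    genes: Sequence[FeatureAnnotation],
    window_bp: int = 100_000,
) -> list[CisPair]:
    """Coding genes within ``window_bp`` of a lncRNA locus (strand-agnostic).

    The distance is the boundary gap; overlapping loci have distance 0.
    """
    pairs = []
    by_chrom: dict[str, list[FeatureAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lnc in lncrnas:
        for g in by_chrom.get(lnc.chrom, ()):
            gap = interval_gap(lnc, g)
            if gap is not None and gap <= window_bp:
                pairs.append(CisPair(lnc.feature_id, g.feature_id, gap))
    return pairs


def trans_targets(
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    r_cut: float = 0.9,
    min_expressed: int = 5,
    expression_floor: float = 0.1,
) -> list[TransPair]:
    """lncRNA/mRNA pairs with |Pearson r| >= ``r_cut`` over shared samples.

    A pair is only a candidate when both features are expressed (TPM above
    ``expression_floor``) in strictly more than ``min_expressed`` shared
    samples; the correlation itself is computed over all shared samples.
    """
    shared = [s for s in lnc_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples for correlation")
    L = lnc_expr.values[shared].to_numpy(float)
    M = mrna_expr.values[shared].to_numpy(float)
    Lz = L - L.mean(axis=1, keepdims=True)
    Mz = M - M.mean(axis=1, keepdims=True)
    Lsd = np.sqrt((Lz**2).sum(axis=1))
    Msd = np.sqrt((Mz**2).sum(axis=1))
    expressed_L = L > expression_floor
    expressed_M = M > expression_floor
    pairs = []
    for i, lnc_id in enumerate(lnc_expr.feature_ids):
        if Lsd[i] == 0:
            continue
        n_expr = (expressed_L[i][None, :] & expressed_M).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Mz @ Lz[i]) / (Msd * Lsd[i])
        keep = (n_expr > min_expressed) & (Msd > 0) & (np.abs(r) >= r_cut)
        for j in np.flatnonzero(keep):
            pairs.append(
                TransPair(
                    lncRNA_id=lnc_id,
                    gene_id=mrna_expr.feature_ids[j],
                    pearson_r=float(r[j]),
                    n_expressed_samples=int(n_expr[j]),
                )
            )
    return pairs
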