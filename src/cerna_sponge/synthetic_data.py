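"""Synthetic data with planted, machine-readable ground truth.

The generator emulates the data structure the sponge-network analysis
assumes: negative-binomial counts for three biotypes over three groups
(control / disease model / treatment), planted differential features, planted
lncRNA-miRNA-mRNA sponge circuits with strong expression anti-correlation,
transcript sequences carrying complementary seed sites, genomic coordinates
with planted cis neighbours, and annotation term sets.

The perturbed group sits between two baseline groups (the treatment arm
returns features to baseline), so every planted feature is differential in
both consecutive-group contrasts, with opposite directions.

Sponge circuits are driven by a shared latent factor with opposite linear
loadings on the miRNA and on its two targets, plus multiplicative log-normal
residual noise whose scale is calibrated in closed form so that the expected
Pearson correlation on the count/TPM scale equals the configured strength.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    ConfigurationError,
    ExpressionMatrix,
    FeatureAnnotation,
    SequenceRecord,
    TermAnnotation,
    write_annotation_gtf,
    write_counts,
    write_fasta,
    write_gmt,
    write_group_map,
)
from .targets import SITE_RANK, SITE_TYPES, m8_match, seed_core

_RNA_BASES = "ACGU"


class SimulationError(RuntimeError):
    """The generator could not satisfy its constraints within bounded retries."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    ``n_features`` applies per biotype; ``n_samples_per_group`` per group.
    Planted differential features change by ``de_log2fc`` (must exceed the
    |log2FC| > 1 calling threshold) in the perturbed group. Planted triplets
    target a count-scale Pearson correlation of ``triplet_anticorr`` between
    the miRNA and each of its two targets.
    """

    n_features: int = 500
    n_samples_per_group: int = 8
    groups: tuple[str, ...] = ("CON", "MOD", "TRT")
    perturbed_group: str = "MOD"
    mean_log_mu: float = math.log(200.0)
    mean_log_sigma: float = 1.0
    dispersion: float = 0.1
    n_de: int = 40
    de_log2fc: float = 1.5
    n_triplets: int = 10
    triplet_anticorr: float = -0.95
    triplet_jitter_sd: float = 0.1
    triplet_min_mean: float = 300.0
    residual_cv: float | None = None
    seed_site_type: str = "8mer"
    screen_min_type: str = "7mer-A1"
    mirna_length: int = 22
    lnc_length: int = 600
    mrna_length: int = 1000
    n_cis_per_class: int = 5
    cis_distances: tuple[int, ...] = (5_000, 50_000, 250_000)
    n_terms: int = 20
    term_size_range: tuple[int, int] = (10, 50)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 3:
            raise ConfigurationError(
                "need at least 3 samples per group (correlation degenerates)"
            )
        if abs(self.de_log2fc) <= 1:
            raise ConfigurationError("planted |log2FC| must exceed 1")
        if not -1.0 <= self.triplet_anticorr <= -0.85:
            raise ConfigurationError("triplet anti-correlation must be <= -0.85")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.seed_site_type not in SITE_TYPES:
            raise ConfigurationError(f"unknown site type {self.seed_site_type!r}")
        if self.screen_min_type not in SITE_TYPES:
            raise ConfigurationError(f"unknown site type {self.screen_min_type!r}")
        if self.perturbed_group not in self.groups:
            raise ConfigurationError(
                f"perturbed group {self.perturbed_group!r} not in groups"
            )
        if self.n_triplets + self.n_de > self.n_features:
            raise ConfigurationError("n_triplets + n_de exceeds n_features")
        if self.n_cis_per_class * len(self.cis_distances) > self.n_features // 4:
            raise ConfigurationError("too many planted cis pairs for n_features")
        if self.mirna_length < 8:
            raise ConfigurationError("miRNAs must be at least 8 nt")
        if self.lnc_length <= 200:
            raise ConfigurationError("lncRNA transcripts must exceed 200 nt")

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        """Consecutive group contrasts, (A, B) with log2FC = log2(B/A)."""
        return [
            (self.groups[i], self.groups[i + 1]) for i in range(len(self.groups) - 1)
        ]


@dataclass(frozen=True)
class PlantedDE:
    feature_id: str
    biotype: str
    contrast: tuple[str, str]
    direction: str  # "up"/"down" of group B relative to group A


@dataclass(frozen=True)
class PlantedTriplet:
    lncRNA_id: str
    mirna_id: str
    mrna_id: str
    mirna_direction: str  # direction of the miRNA in the perturbed group


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based closed
    site_end: int
    site_type: str


@dataclass(frozen=True)
class PlantedCisPair:
    lncRNA_id: str
    gene_id: str
    distance_bp: int


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    feature_ids: dict[str, list[str]] = field(default_factory=dict)
    de_features: list[PlantedDE] = field(default_factory=list)
    triplets: list[PlantedTriplet] = field(default_factory=list)
    seed_sites: list[PlantedSite] = field(default_factory=list)
    cis_pairs: list[PlantedCisPair] = field(default_factory=list)
    enriched_term_ids: list[str] = field(default_factory=list)

    def de_directions(
        self, biotype: str, contrast: tuple[str, str]
    ) -> dict[str, str]:
        """feature_id -> planted direction for one biotype and contrast."""
        return {
            d.feature_id: d.direction
            for d in self.de_features
            if d.biotype == biotype and tuple(d.contrast) == tuple(contrast)
        }

    def triplet_ids(self) -> set[tuple[str, str, str]]:
        return {(t.lncRNA_id, t.mirna_id, t.mrna_id) for t in self.triplets}

    def target_pair_ids(self) -> set[tuple[str, str]]:
        """All planted (miRNA, transcript) targeting pairs."""
        out = set()
        for t in self.triplets:
            out.add((t.mirna_id, t.lncRNA_id))
            out.add((t.mirna_id, t.mrna_id))
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_ids": self.feature_ids,
            "de_features": [
                {**asdict(d), "contrast": list(d.contrast)} for d in self.de_features
            ],
            "triplets": [asdict(t) for t in self.triplets],
            "seed_sites": [asdict(s) for s in self.seed_sites],
            "cis_pairs": [asdict(c) for c in self.cis_pairs],
            "enriched_term_ids": self.enriched_term_ids,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            feature_ids=doc["feature_ids"],
            de_features=[
                PlantedDE(
                    d["feature_id"], d["biotype"], tuple(d["contrast"]), d["direction"]
                )
                for d in doc["de_features"]
            ],
            triplets=[PlantedTriplet(**t) for t in doc["triplets"]],
            seed_sites=[PlantedSite(**s) for s in doc["seed_sites"]],
            cis_pairs=[PlantedCisPair(**c) for c in doc["cis_pairs"]],
            enriched_term_ids=doc["enriched_term_ids"],
        )


_PREFIX = {"lncRNA": "lnc", "miRNA": "mir", "mRNA": "mrna"}


def _feature_ids(biotype: str, n: int) -> list[str]:
    return [f"{_PREFIX[biotype]}_{i:04d}" for i in range(n)]


def _fold_amplitude(log2fc: float) -> float:
    """Linear loading a with (1+a)/(1-a) = 2^log2fc between the two poles."""
    fold = 2.0**log2fc
    return (fold - 1.0) / (fold + 1.0)


def _residual_cv(config: SimulationConfig, mu: float, var_g: float) -> float:
    """Log-normal residual CV giving expected Pearson r = triplet_anticorr.

    A planted count series is X = mu * F * N + Poisson noise with
    F = 1 +/- a*u (shared latent u = g + jitter, g = +/-1 by group) and N a
    unit-mean log-normal with CV c. Then Var(X)/mu^2 = S + c^2(1+S) + 1/mu
    with signal S = a^2(var_g + sigma_u^2), while Cov between two planted
    partners is -S*mu1*mu2, so r = -S/(S + c^2(1+S) + 1/mu). Solving for c
    at the configured |r| gives the calibration; var_g is the variance of
    the +/-1 group pattern over all samples.
    """
    if config.residual_cv is not None:
        return config.residual_cv
    rho = abs(config.triplet_anticorr)
    a = _fold_amplitude(abs(config.de_log2fc))
    signal = a**2 * (var_g + config.triplet_jitter_sd**2)
    c2 = (signal * (1.0 / rho - 1.0) - 1.0 / mu) / (1.0 + signal)
    return math.sqrt(max(1e-6, c2))


def simulate_counts(
    config: SimulationConfig,
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Generate the three count matrices and the ground truth.

    Background features are i.i.d. NB(mean, dispersion) across samples with
    log-normal baseline means. Planted differential features have the
    perturbed group's mean scaled by 2**(+/-de_log2fc). Planted triplet
    members follow the shared-latent-factor model described in the module
    docstring. All counts are floored at 1.
    """
    rng = np.random.default_rng([config.rng_seed, 0])
    n_per = config.n_samples_per_group
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for g in config.groups:
        for k in range(n_per):
            sid = f"{g}_{k + 1}"
            sample_ids.append(sid)
            groups[sid] = g
    n_samples = len(sample_ids)
    perturbed = np.array([groups[s] == config.perturbed_group for s in sample_ids])
    g_vec = np.where(perturbed, 1.0, -1.0)

    phi = config.dispersion
    r_nb = 1.0 / phi
    a = _fold_amplitude(abs(config.de_log2fc))

    truth = GroundTruth()
    matrices: dict[str, ExpressionMatrix] = {}
    baselines: dict[str, np.ndarray] = {}

    for biotype in ("lncRNA", "miRNA", "mRNA"):
        ids = _feature_ids(biotype, config.n_features)
        truth.feature_ids[biotype] = ids
        mu = rng.lognormal(config.mean_log_mu, config.mean_log_sigma, config.n_features)
        mu[: config.n_triplets] = np.maximum(
            mu[: config.n_triplets], config.triplet_min_mean
        )
        baselines[biotype] = mu
        # background: NB i.i.d. across samples
        p_nb = r_nb / (r_nb + mu)
        counts = rng.negative_binomial(
            r_nb, p_nb[:, None], size=(config.n_features, n_samples)
        ).astype(np.int64)
        matrices[biotype] = counts  # placeholder; wrapped below

    # plain planted DE features (rows n_triplets .. n_triplets+n_de-1)
    for biotype in ("lncRNA", "miRNA", "mRNA"):
        counts = matrices[biotype]
        mu = baselines[biotype]
        ids = truth.feature_ids[biotype]
        for j in range(config.n_de):
            row = config.n_triplets + j
            direction = "up" if j % 2 == 0 else "down"
            lfc = config.de_log2fc if direction == "up" else -config.de_log2fc
            mu_pert = mu[row] * 2.0**lfc
            p_pert = r_nb / (r_nb + mu_pert)
            counts[row, perturbed] = rng.negative_binomial(
                r_nb, p_pert, size=int(perturbed.sum())
            )
            _record_de(truth, ids[row], biotype, direction, config)

    # planted sponge triplets (rows 0 .. n_triplets-1 in each biotype)
    var_g = float(g_vec.var())
    for t in range(config.n_triplets):
        mi_dir = "up" if t % 2 == 0 else "down"
        sign_mi = 1.0 if mi_dir == "up" else -1.0
        u = g_vec + rng.normal(0.0, config.triplet_jitter_sd, n_samples)
        for biotype, sign in (
            ("miRNA", sign_mi),
            ("lncRNA", -sign_mi),
            ("mRNA", -sign_mi),
        ):
            mu_t = baselines[biotype][t]
            cv = _residual_cv(config, mu_t, var_g)
            sigma_ln = math.sqrt(math.log1p(cv**2))
            noise = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, n_samples)
            factor = np.clip(1.0 + sign * a * u, 0.02, None)
            matrices[biotype][t, :] = rng.poisson(mu_t * factor * noise)
            direction = mi_dir if biotype == "miRNA" else _flip(mi_dir)
            _record_de(truth, truth.feature_ids[biotype][t], biotype, direction, config)
        truth.triplets.append(
            PlantedTriplet(
                lncRNA_id=truth.feature_ids["lncRNA"][t],
                mirna_id=truth.feature_ids["miRNA"][t],
                mrna_id=truth.feature_ids["mRNA"][t],
                mirna_direction=mi_dir,
            )
        )

    out = {}
    for biotype in ("lncRNA", "miRNA", "mRNA"):
        counts = np.maximum(matrices[biotype], 1)
        df = pd.DataFrame(counts, index=truth.feature_ids[biotype], columns=sample_ids)
        out[biotype] = ExpressionMatrix(
            values=df, biotype=biotype, groups=dict(groups), units="counts"
        )
    return out, truth


def _flip(direction: str) -> str:
    return "down" if direction == "up" else "up"


def _record_de(
    truth: GroundTruth,
    feature_id: str,
    biotype: str,
    direction_in_perturbed: str,
    config: SimulationConfig,
) -> None:
    """The perturbed group is B in the first contrast and A in the second."""
    for (ga, gb) in config.contrasts:
        if gb == config.perturbed_group:
            d = direction_in_perturbed
        elif ga == config.perturbed_group:
            d = _flip(direction_in_perturbed)
        else:
            continue
        truth.de_features.append(PlantedDE(feature_id, biotype, (ga, gb), d))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _site_string(mirna_seq: str, site_type: str) -> str:
    core = seed_core(mirna_seq)
    m8c = m8_match(mirna_seq)
    return {
        "8mer": m8c + core + "A",
        "7mer-m8": m8c + core,
        "7mer-A1": core + "A",
        "6mer": core,
    }[site_type]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return "".join(_RNA_BASES[i] for i in idx)


def simulate_sequences(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, SequenceRecord]:
    """Generate miRNA and transcript sequences consistent with the truth.

    Every miRNA gets a random RNA sequence (default 22 nt) with a seed core
    unique among the simulated miRNAs. Each transcript in a planted targeting
    pair carries one embedded site of ``config.seed_site_type`` exactly
    complementary to its miRNA's seed; embedded positions are appended to
    ``truth.seed_sites``. All transcripts are then screened so that, outside
    the planted sites, no site of class >= ``config.screen_min_type`` remains
    for any simulated miRNA (offending sites are destroyed by point
    mutation; bounded retries, else SimulationError).
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    sequences: dict[str, SequenceRecord] = {}

    # miRNAs with pairwise-distinct seed cores; additionally no miRNA's
    # embedded site string may contain another miRNA's core as a substring
    # (otherwise a planted site would carry an unremovable foreign site)
    core_to_mirna: dict[str, str] = {}
    mirna_seq: dict[str, str] = {}
    blocked_windows: set[str] = set()
    for mid in truth.feature_ids["miRNA"]:
        for _ in range(500):
            seq = _random_seq(rng, config.mirna_length)
            core = seed_core(seq)
            site = _site_string(seq, config.seed_site_type)
            windows = {site[i : i + 6] for i in range(len(site) - 5)}
            if core not in blocked_windows and not (
                windows & set(core_to_mirna)
            ):
                core_to_mirna[core] = mid
                mirna_seq[mid] = seq
                blocked_windows |= windows
                break
        else:
            raise SimulationError("could not draw a compatible seed core")
        sequences[mid] = SequenceRecord(id=mid, residues=mirna_seq[mid])

    m8c_of = {mid: m8_match(seq) for mid, seq in mirna_seq.items()}

    # planted targeting pairs per transcript
    partners: dict[str, list[str]] = {}
    for mi_id, tr_id in sorted(truth.target_pair_ids()):
        partners.setdefault(tr_id, []).append(mi_id)

    lengths = {"lncRNA": config.lnc_length, "mRNA": config.mrna_length}
    screen_rank = SITE_RANK[config.screen_min_type]

    for biotype in ("lncRNA", "mRNA"):
        for tr_id in truth.feature_ids[biotype]:
            length = lengths[biotype]
            seq = list(_random_seq(rng, length))
            protected: list[tuple[int, int]] = []  # 0-based closed site spans
            planted_loci: set[tuple[str, int]] = set()  # (miRNA, core pos)
            flank_forbidden: dict[int, str] = {}  # pos -> base that must not appear
            for mi_id in partners.get(tr_id, ()):
                site = _site_string(mirna_seq[mi_id], config.seed_site_type)
                span = len(site) + 2  # one flank each side
                for _ in range(100):
                    pos = int(rng.integers(1, length - span))
                    ok = all(
                        pos + span - 1 < s or pos > e + span for s, e in protected
                    )
                    if ok:
                        break
                else:
                    raise SimulationError(f"cannot place site on {tr_id}")
                seq[pos : pos + len(site)] = list(site)
                # flanks that would upgrade the planted class are forced off
                if config.seed_site_type in ("7mer-A1", "6mer"):
                    flank_forbidden[pos - 1] = m8c_of[mi_id]
                    if seq[pos - 1] == m8c_of[mi_id]:
                        seq[pos - 1] = _other_base(rng, m8c_of[mi_id])
                if config.seed_site_type in ("7mer-m8", "6mer"):
                    after = pos + len(site)
                    if after < length:
                        flank_forbidden[after] = "A"
                        if seq[after] == "A":
                            seq[after] = _other_base(rng, "A")
                protected.append((pos, pos + len(site) - 1))
                core_offset = 1 if config.seed_site_type in ("8mer", "7mer-m8") else 0
                planted_loci.add((mi_id, pos + core_offset))
                truth.seed_sites.append(
                    PlantedSite(
                        mirna_id=mi_id,
                        transcript_id=tr_id,
                        site_start=pos + 1,
                        site_end=pos + len(site),
                        site_type=config.seed_site_type,
                    )
                )
            _screen_transcript(
                seq,
                core_to_mirna,
                m8c_of,
                protected,
                planted_loci,
                flank_forbidden,
                screen_rank,
                rng,
                tr_id,
            )
            sequences[tr_id] = SequenceRecord(id=tr_id, residues="".join(seq))
    return sequences


def _other_base(
    rng: np.random.Generator, base: str, also_not: str | None = None
) -> str:
    choices = [b for b in _RNA_BASES if b != base and b != also_not]
    return choices[int(rng.integers(len(choices)))]


def _screen_transcript(
    seq: list[str],
    core_to_mirna: dict[str, str],
    m8c_of: dict[str, str],
    protected: list[tuple[int, int]],
    planted_loci: set[tuple[str, int]],
    flank_forbidden: dict[int, str],
    screen_rank: int,
    rng: np.random.Generator,
    tr_id: str,
    max_passes: int = 60,
) -> None:
    """Destroy every unplanted seed site of class >= screen_rank in place.

    Planted site spans are never touched; flank positions whose base is
    constrained (to keep the planted class from upgrading) keep that
    constraint when mutated.
    """
    from .targets import classify_locus

    def in_protected(i: int) -> bool:
        return any(s <= i <= e for s, e in protected)

    length = len(seq)
    for _ in range(max_passes):
        text = "".join(seq)
        dirty = False
        for pos in range(length - 5):
            mi = core_to_mirna.get(text[pos : pos + 6])
            if mi is None:
                continue
            if (mi, pos) in planted_loci:
                continue
            site_type, _, _ = classify_locus(text, pos, m8c_of[mi])
            if SITE_RANK[site_type] < screen_rank:
                continue
            mutable = [i for i in range(pos, pos + 6) if not in_protected(i)]
            if not mutable:
                # cannot happen when miRNA site strings are core-disjoint
                raise SimulationError(
                    f"{tr_id}: cannot screen site overlapping a planted span"
                )
            i = mutable[int(rng.integers(len(mutable)))]
            seq[i] = _other_base(rng, seq[i], also_not=flank_forbidden.get(i))
            dirty = True
        if not dirty:
            return
    raise SimulationError(f"{tr_id}: screening did not converge")


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def simulate_coordinates(
    truth: GroundTruth, config: SimulationConfig
) -> list[FeatureAnnotation]:
    """Genomic coordinates with planted cis lncRNA/mRNA pairs.

    Planted pairs sit on a dedicated chromosome at the configured boundary
    gaps (below, inside and beyond the 10/100 kb windows); all other
    features live on per-biotype chromosomes, so the planted pairs are the
    only lncRNA/mRNA pairs within any window. Distances are appended to
    ``truth.cis_pairs``.
    """
    lengths = {
        "lncRNA": config.lnc_length,
        "miRNA": config.mirna_length,
        "mRNA": config.mrna_length,
    }
    n_cis = config.n_cis_per_class * len(config.cis_distances)
    # planted pairs use the tail of the feature lists (disjoint from
    # triplet/DE head rows)
    cis_lnc = truth.feature_ids["lncRNA"][-n_cis:]
    cis_mrna = truth.feature_ids["mRNA"][-n_cis:]
    placed: dict[str, FeatureAnnotation] = {}
    offset = 1
    k = 0
    for dist in config.cis_distances:
        for _ in range(config.n_cis_per_class):
            lnc_id, gene_id = cis_lnc[k], cis_mrna[k]
            lnc_start = offset
            lnc_end = lnc_start + lengths["lncRNA"] - 1
            gene_start = lnc_end + dist
            gene_end = gene_start + lengths["mRNA"] - 1
            placed[lnc_id] = FeatureAnnotation(
                lnc_id, "lncRNA", "chr_cis", lnc_start, lnc_end, "+",
                lengths["lncRNA"],
            )
            placed[gene_id] = FeatureAnnotation(
                gene_id, "mRNA", "chr_cis", gene_start, gene_end, "+",
                lengths["mRNA"],
            )
            truth.cis_pairs.append(PlantedCisPair(lnc_id, gene_id, dist))
            offset = gene_end + 2_000_000
            k += 1

    annotations: list[FeatureAnnotation] = []
    for biotype, chrom in (
        ("lncRNA", "chr_lnc"),
        ("miRNA", "chr_mir"),
        ("mRNA", "chr_mrna"),
    ):
        pos = 1
        for fid in truth.feature_ids[biotype]:
            if fid in placed:
                annotations.append(placed[fid])
                continue
            end = pos + lengths[biotype] - 1
            annotations.append(
                FeatureAnnotation(fid, biotype, chrom, pos, end, "+", lengths[biotype])
            )
            pos = end + 1_000_000
    return annotations


# ---------------------------------------------------------------------------
# term sets
# ---------------------------------------------------------------------------

def simulate_terms(
    truth: GroundTruth, config: SimulationConfig
) -> list[TermAnnotation]:
    """Random annotation terms over the mRNA universe, plus two terms
    concentrated in planted differential mRNAs (recorded as enriched)."""
    rng = np.random.default_rng([config.rng_seed, 2])
    universe = truth.feature_ids["mRNA"]
    lo, hi = config.term_size_range
    terms = []
    for i in range(config.n_terms):
        size = min(int(rng.integers(lo, hi + 1)), len(universe))
        members = rng.choice(universe, size=size, replace=False)
        terms.append(
            TermAnnotation(
                term_id=f"TERM:{i:04d}",
                term_name=f"random pathway {i}",
                member_gene_ids=frozenset(members.tolist()),
            )
        )
    de_mrnas = sorted({d.feature_id for d in truth.de_features if d.biotype == "mRNA"})
    for j in range(2):
        if len(de_mrnas) < 8:
            break
        hit = rng.choice(de_mrnas, size=8, replace=False).tolist()
        pad = rng.choice(universe, size=7, replace=False).tolist()
        tid = f"TERM:DE{j}"
        terms.append(
            TermAnnotation(
                term_id=tid,
                term_name=f"perturbation-responsive set {j}",
                member_gene_ids=frozenset(hit + pad),
            )
        )
        truth.enriched_term_ids.append(tid)
    return terms


# ---------------------------------------------------------------------------
# one-call dataset + writers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    matrices: dict[str, ExpressionMatrix]
    truth: GroundTruth
    sequences: dict[str, SequenceRecord]
    annotations: list[FeatureAnnotation]
    terms: list[TermAnnotation]


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage from one config (fixed seed => identical)."""
    matrices, truth = simulate_counts(config)
    sequences = simulate_sequences(truth, config)
    annotations = simulate_coordinates(truth, config)
    terms = simulate_terms(truth, config)
    return SimulatedDataset(config, matrices, truth, sequences, annotations, terms)


def write_simulation(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the same dialects io_model reads; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    any_em = next(iter(dataset.matrices.values()))
    paths["groups"] = outdir / "groups.tsv"
    write_group_map(any_em.groups, paths["groups"])
    for biotype, em in dataset.matrices.items():
        key = f"counts_{biotype}"
        paths[key] = outdir / f"counts_{biotype}.tsv"
        write_counts(em, paths[key])
    mirna_ids = set(dataset.truth.feature_ids["miRNA"])
    paths["mirna_fasta"] = outdir / "mirna.fa"
    write_fasta(
        [dataset.sequences[i] for i in sorted(mirna_ids)], paths["mirna_fasta"]
    )
    paths["transcript_fasta"] = outdir / "transcripts.fa"
    write_fasta(
        [dataset.sequences[i] for i in sorted(dataset.sequences) if i not in mirna_ids],
        paths["transcript_fasta"],
    )
    paths["annotation"] = outdir / "annotation.gtf"
    write_annotation_gtf(dataset.annotations, paths["annotation"])
    paths["terms"] = outdir / "terms.gmt"
    write_gmt(dataset.terms, paths["terms"])
    paths["truth"] = outdir / "truth.json"
    dataset.truth.to_json(paths["truth"])
    return paths
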