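import itertools

import numpy as np
import pandas as pd
import pytest

from cerna_sponge.io_model import ExpressionMatrix, FeatureAnnotation, SequenceRecord
from cerna_sponge.targets import (
    SITE_RANK,
    cis_targets,
    find_seed_sites,
    interval_gap,
    predict_targets,
    reverse_complement,
    trans_targets,
)

from _oracles import seed_sites_bruteforce

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def _rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


class TestFindSeedSites:
    def test_canonical_8mer(self):
        # reverse complement of let-7 positions 2-8 (GAGGUAG) is CUACCUC;
        # with the A anchor the site reads CUACCUCA
        mirna = SequenceRecord("let7", LET7)
        transcript = SequenceRecord("t", "GGGG" + "CUACCUCA" + "GGGG")
        (site,) = find_seed_sites(mirna, transcript)
        assert site.site_type == "8mer"
        assert (site.site_start, site.site_end) == (5, 12)

    def test_no_core_match_is_empty(self):
        mirna = SequenceRecord("let7", LET7)
        transcript = SequenceRecord("t", "A" * 40)
        assert find_seed_sites(mirna, transcript) == []

    def test_full_reverse_complement_is_8mer(self):
        mirna = SequenceRecord("let7", LET7)
        transcript = SequenceRecord("t", reverse_complement(LET7))
        sites = find_seed_sites(mirna, transcript)
        assert sites
        assert any(s.site_type == "8mer" for s in sites)

    def test_each_weaker_class(self):
        mirna = SequenceRecord("let7", LET7)
        core = reverse_complement(LET7[1:7])  # UACCUC
        m8c = reverse_complement(LET7[7])  # C
        cases = {
            "7mer-m8": "GG" + m8c + core + "G" + "GG",
            "7mer-A1": "GG" + "G" + core + "A" + "GG",
            "6mer": "GG" + "G" + core + "G" + "GG",
        }
        for expected, seq in cases.items():
            (site,) = find_seed_sites(mirna, SequenceRecord("t", seq))
            assert site.site_type == expected, expected

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites(SequenceRecord("m", "ACGUACG"), SequenceRecord("t", "ACGU"))

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        """All-substring complementarity oracle agreement, 200 random pairs."""
        rng = np.random.default_rng(123)
        for _ in range(200):
            m = SequenceRecord("m", _rna(rng, 22))
            # short transcripts seeded with the core to raise hit rates
            t_seq = _rna(rng, 60) + reverse_complement(m.residues[1:7]) + _rna(rng, 60)
            t = SequenceRecord("t", t_seq)
            got = {
                (s.site_start, s.site_end, s.site_type)
                for s in find_seed_sites(m, t)
            }
            assert got == seed_sites_bruteforce(m.residues, t.residues)

    def test_every_site_has_exactly_one_type(self):
        rng = np.random.default_rng(9)
        m = SequenceRecord("m", _rna(rng, 22))
        t = SequenceRecord(
            "t", (reverse_complement(m.residues[1:8]) + "A") * 3
        )
        sites = find_seed_sites(m, t)
        assert sites
        for s in sites:
            assert s.site_type in SITE_RANK


class TestPredictTargets:
    def test_planted_pairs_fully_recovered(self, small_dataset):
        truth, seqs = small_dataset.truth, small_dataset.sequences
        mirnas = [seqs[m] for m in truth.feature_ids["miRNA"]]
        transcripts = [
            seqs[t]
            for t in truth.feature_ids["lncRNA"] + truth.feature_ids["mRNA"]
        ]
        biotypes = {t: "lncRNA" for t in truth.feature_ids["lncRNA"]}
        biotypes.update({t: "mRNA" for t in truth.feature_ids["mRNA"]})
        pairs = predict_targets(mirnas, transcripts, biotypes)
        got = {(p.mirna_id, p.transcript_id) for p in pairs}
        planted = truth.target_pair_ids()
        recall = len(got & planted) / len(planted)
        precision = len(got & planted) / len(got)
        assert recall == 1.0
        assert precision >= 0.95

    def test_empty_mirna_set(self):
        assert predict_targets([], [SequenceRecord("t", "ACGU")], {}) == []

    def test_min_site_type_filters(self):
        mirna = SequenceRecord("let7", LET7)
        core_only = SequenceRecord(
            "t", "GG" + "G" + reverse_complement(LET7[1:7]) + "G" + "GG"
        )
        assert predict_targets([mirna], [core_only], {}, min_site_type="7mer-A1") == []
        (pair,) = predict_targets([mirna], [core_only], {}, min_site_type="6mer")
        assert pair.best_site_type == "6mer"


def _ann(fid, chrom, start, end, biotype="mRNA"):
    return FeatureAnnotation(fid, biotype, chrom, start, end, "+", end - start + 1)


class TestCisTargets:
    def test_window_semantics(self):
        lnc = _ann("L", "chr1", 100_000, 101_000, "lncRNA")
        gene = _ann("G", "chr1", 150_000, 152_000)
        assert cis_targets([lnc], [gene], window_bp=100_000) != []
        (pair,) = cis_targets([lnc], [gene], window_bp=100_000)
        assert pair.distance_bp == 49_000
        assert cis_targets([lnc], [gene], window_bp=10_000) == []

    def test_overlap_distance_zero(self):
        lnc = _ann("L", "chr1", 1000, 5000, "lncRNA")
        gene = _ann("G", "chr1", 4000, 9000)
        (pair,) = cis_targets([lnc], [gene], window_bp=1)
        assert pair.distance_bp == 0

    def test_different_chromosomes_never_pair(self):
        lnc = _ann("L", "chr1", 1, 1000, "lncRNA")
        gene = _ann("G", "chr2", 1, 1000)
        assert cis_targets([lnc], [gene], window_bp=10**9) == []

    def test_matches_all_pairs_check(self):
        rng = np.random.default_rng(4)
        lncs, genes = [], []
        for i in range(50):
            c = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(1, 500_000))
            lncs.append(_ann(f"L{i}", c, s, s + 500, "lncRNA"))
            c = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(1, 500_000))
            genes.append(_ann(f"G{i}", c, s, s + 1000))
        got = {(p.lncRNA_id, p.gene_id, p.distance_bp)
               for p in cis_targets(lncs, genes, window_bp=50_000)}
        expected = set()
        for lnc, gene in itertools.product(lncs, genes):
            gap = interval_gap(lnc, gene)
            if gap is not None and gap <= 50_000:
                expected.add((lnc.feature_id, gene.feature_id, gap))
        assert got == expected

    def test_planted_cis_pairs_recovered_by_window(self, small_dataset):
        lncs = [a for a in small_dataset.annotations if a.biotype == "lncRNA"]
        genes = [a for a in small_dataset.annotations if a.biotype == "mRNA"]
        w100 = {(p.lncRNA_id, p.gene_id): p.distance_bp
                for p in cis_targets(lncs, genes, window_bp=100_000)}
        w10 = {(p.lncRNA_id, p.gene_id)
               for p in cis_targets(lncs, genes, window_bp=10_000)}
        planted = {(c.lncRNA_id, c.gene_id): c.distance_bp
                   for c in small_dataset.truth.cis_pairs}
        assert set(w100) == {k for k, d in planted.items() if d <= 100_000}
        assert w10 == {k for k, d in planted.items() if d <= 10_000}
        for k in w100:
            assert w100[k] == planted[k]


def _expr(rows, samples, biotype):
    df = pd.DataFrame(rows, columns=samples)
    df.index = [f"{biotype}{i}" for i in range(len(df))]
    return ExpressionMatrix(df, biotype, {s: "A" for s in samples}, units="TPM")


class TestTransTargets:
    def test_perfect_correlation_retained(self):
        samples = [f"s{i}" for i in range(8)]
        x = list(range(1, 9))
        lnc = _expr([x], samples, "lncRNA")
        mrna = _expr([[2 * v for v in x]], samples, "mRNA")
        (pair,) = trans_targets(lnc, mrna, r_cut=0.9)
        assert pair.pearson_r == pytest.approx(1.0)
        assert pair.n_expressed_samples == 8

    def test_expressed_in_too_few_samples_excluded(self):
        samples = [f"s{i}" for i in range(8)]
        # both expressed (>0.1) in only 4 shared samples, perfectly correlated
        x = [5, 6, 7, 8, 0.0, 0.0, 0.0, 0.0]
        lnc = _expr([x], samples, "lncRNA")
        mrna = _expr([x], samples, "mRNA")
        assert trans_targets(lnc, mrna, r_cut=0.9, min_expressed=5) == []

    def test_planted_coexpression_recovered(self):
        from cerna_sponge.diffexpr import tpm_normalize
        from cerna_sponge.synthetic_data import SimulationConfig, simulate_counts

        got, planted = set(), set()
        for seed in range(5):
            cfg = SimulationConfig(n_features=100, n_de=10, n_triplets=5,
                                   n_cis_per_class=0, rng_seed=seed)
            mats, truth = simulate_counts(cfg)
            lnc = tpm_normalize(mats["lncRNA"])
            mrna = tpm_normalize(mats["mRNA"])
            pairs = trans_targets(lnc, mrna, r_cut=0.9)
            got |= {(seed, p.lncRNA_id, p.gene_id) for p in pairs}
            # lncRNA and mRNA of one triplet co-move (both anti-miRNA)
            planted |= {(seed, t.lncRNA_id, t.mrna_id) for t in truth.triplets}
        recall = len(got & planted) / len(planted)
        assert recall >= 0.9
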