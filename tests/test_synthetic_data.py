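import numpy as np
import pytest

from cerna_sponge.io_model import ConfigurationError
from cerna_sponge.synthetic_data import (
    GroundTruth,
    SimulationConfig,
    simulate_all,
    simulate_coordinates,
    simulate_counts,
    simulate_sequences,
)
from cerna_sponge.targets import SITE_RANK, find_seed_sites, reverse_complement


def _cfg(**kw):
    base = dict(
        n_features=24,
        n_samples_per_group=8,
        n_de=6,
        n_triplets=4,
        n_cis_per_class=1,
        n_terms=4,
        rng_seed=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(n_samples_per_group=2)

    def test_subthreshold_log2fc_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(de_log2fc=0.8)

    def test_weak_anticorrelation_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(triplet_anticorr=-0.5)


class TestSimulateCounts:
    def test_shape_and_fixed_seed_reproducibility(self):
        cfg = SimulationConfig(rng_seed=7)
        mats, _ = simulate_counts(cfg)
        assert all(m.values.shape == (500, 24) for m in mats.values())
        mats2, _ = simulate_counts(SimulationConfig(rng_seed=7))
        for bt in mats:
            assert mats[bt].values.equals(mats2[bt].values)
        mats3, _ = simulate_counts(SimulationConfig(rng_seed=8))
        assert not mats["mRNA"].values.equals(mats3["mRNA"].values)

    def test_counts_floored_at_one(self, small_dataset):
        for em in small_dataset.matrices.values():
            assert int(em.values.to_numpy().min()) >= 1

    def test_zero_triplets_gives_empty_truth(self):
        _, truth = simulate_counts(_cfg(n_triplets=0))
        assert truth.triplets == []

    def test_planted_anticorrelation_realized(self):
        """r(miRNA, lncRNA) < -0.85 for planted triplets in >=95% of seeds."""
        hits = total = 0
        for seed in range(100):
            mats, truth = simulate_counts(_cfg(rng_seed=seed, n_features=8,
                                               n_de=2, n_triplets=2,
                                               n_cis_per_class=0))
            mi = mats["miRNA"].values
            ln = mats["lncRNA"].values
            for t in truth.triplets:
                r = np.corrcoef(mi.loc[t.mirna_id], ln.loc[t.lncRNA_id])[0, 1]
                total += 1
                hits += r < -0.85
        assert hits / total >= 0.95

    def test_background_nb_moments(self):
        """Marginal mean/variance of background counts match the config."""
        cfg = _cfg(n_features=24, n_de=0, n_triplets=0, n_cis_per_class=0,
                   mean_log_sigma=0.0, mean_log_mu=np.log(200.0),
                   n_samples_per_group=200, groups=("CON", "MOD"),
                   rng_seed=2)
        # 24 features x 400 samples ~ 10,000 background draws
        mats, _ = simulate_counts(cfg)
        x = mats["mRNA"].values.to_numpy().ravel().astype(float)
        mu, phi = 200.0, cfg.dispersion
        assert abs(x.mean() - mu) / mu < 0.05
        expected_var = mu + phi * mu**2
        assert abs(x.var() - expected_var) / expected_var < 0.15

    def test_planted_log2fc_recovered_within_tolerance(self):
        """Empirical log2FC of planted DE features within +/-0.3 of the
        configured 1.5, averaged over 50 replicates at n=8 per group."""
        errs = []
        for seed in range(50):
            cfg = _cfg(rng_seed=seed, n_features=12, n_de=4, n_triplets=0,
                       n_cis_per_class=0)
            mats, truth = simulate_counts(cfg)
            em = mats["mRNA"]
            con = em.samples_of("CON")
            mod = em.samples_of("MOD")
            for fid, direction in truth.de_directions("mRNA", ("CON", "MOD")).items():
                lfc = np.log2(
                    em.values.loc[fid, mod].mean() / em.values.loc[fid, con].mean()
                )
                target = cfg.de_log2fc if direction == "up" else -cfg.de_log2fc
                errs.append(lfc - target)
        assert abs(np.mean(errs)) < 0.3

    def test_truth_references_existing_features(self, small_dataset):
        truth, mats = small_dataset.truth, small_dataset.matrices
        for t in truth.triplets:
            assert t.lncRNA_id in mats["lncRNA"].values.index
            assert t.mirna_id in mats["miRNA"].values.index
            assert t.mrna_id in mats["mRNA"].values.index


class TestSimulateSequences:
    def test_mirna_lengths(self, small_dataset):
        for mid in small_dataset.truth.feature_ids["miRNA"]:
            assert len(small_dataset.sequences[mid].residues) == 22

    def test_planted_site_is_reverse_complement_of_seed(self, small_dataset):
        truth, seqs = small_dataset.truth, small_dataset.sequences
        for site in truth.seed_sites:
            m = seqs[site.mirna_id].residues
            t = seqs[site.transcript_id].residues
            embedded = t[site.site_start - 1 : site.site_end]
            # 8mer: reverse complement of miRNA positions 2-8, then A
            assert embedded == reverse_complement(m[1:8]) + "A"
            assert site.site_type == "8mer"

    def test_nontargets_carry_no_screened_sites(self, small_dataset):
        truth, seqs = small_dataset.truth, small_dataset.sequences
        planted = truth.target_pair_ids()
        screen_rank = SITE_RANK[small_dataset.config.screen_min_type]
        mirnas = [seqs[m] for m in truth.feature_ids["miRNA"]]
        transcripts = truth.feature_ids["lncRNA"] + truth.feature_ids["mRNA"]
        for tid in transcripts:
            for mi in mirnas:
                if (mi.id, tid) in planted:
                    continue
                sites = find_seed_sites(mi, seqs[tid])
                assert all(SITE_RANK[s.site_type] < screen_rank for s in sites), (
                    mi.id,
                    tid,
                )

    def test_fixed_seed_sequences_identical(self, small_config):
        a = simulate_all(small_config)
        b = simulate_all(small_config)
        assert {k: v.residues for k, v in a.sequences.items()} == {
            k: v.residues for k, v in b.sequences.items()
        }


class TestSimulateCoordinates:
    def test_planted_distances_by_window(self):
        cfg = _cfg()
        _, truth = simulate_counts(cfg)
        anns = {a.feature_id: a for a in simulate_coordinates(truth, cfg)}
        dists = sorted(c.distance_bp for c in truth.cis_pairs)
        assert dists == [5_000, 50_000, 250_000]
        for pair in truth.cis_pairs:
            lnc, gene = anns[pair.lncRNA_id], anns[pair.gene_id]
            assert lnc.chrom == gene.chrom
            assert gene.start - lnc.end == pair.distance_bp

    def test_non_planted_features_on_separate_chromosomes(self, small_dataset):
        planted = {c.lncRNA_id for c in small_dataset.truth.cis_pairs} | {
            c.gene_id for c in small_dataset.truth.cis_pairs
        }
        lnc = {a.chrom for a in small_dataset.annotations
               if a.biotype == "lncRNA" and a.feature_id not in planted}
        mrna = {a.chrom for a in small_dataset.annotations
                if a.biotype == "mRNA" and a.feature_id not in planted}
        assert lnc.isdisjoint(mrna)


class TestTruthSerialization:
    def test_json_roundtrip(self, small_dataset, tmp_path):
        p = tmp_path / "truth.json"
        small_dataset.truth.to_json(p)
        back = GroundTruth.from_json(p)
        assert back.triplet_ids() == small_dataset.truth.triplet_ids()
        assert back.de_features == small_dataset.truth.de_features
        assert back.cis_pairs == small_dataset.truth.cis_pairs
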