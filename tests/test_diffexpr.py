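import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerna_sponge.diffexpr import (
    bh_adjust,
    binomial_test_noreplicate,
    call_de,
    de_contrast,
    nb_exact_test,
    overlap_de_sets,
    qvalue_noreplicate,
    tpm_normalize,
)
from cerna_sponge.io_model import ExpressionMatrix

from _oracles import bh_stepup, conditional_nb_pvalue_enum


def _em(rows, samples, groups, biotype="mRNA"):
    df = pd.DataFrame(rows, columns=samples)
    df.index = [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(df, biotype, groups)


class TestTpmNormalize:
    def test_printed_formula(self):
        em = _em([[50], [999_950]], ["s1"], {"s1": "A"})
        tpm = tpm_normalize(em)
        assert tpm.values.loc["g0", "s1"] == pytest.approx(50.0)

    def test_column_proportions(self):
        em = _em([[2], [3], [5]], ["s1"], {"s1": "A"})
        tpm = tpm_normalize(em)
        assert tpm.values["s1"].tolist() == pytest.approx([200000, 300000, 500000])

    def test_columns_sum_to_one_million(self, small_dataset):
        tpm = tpm_normalize(small_dataset.matrices["mRNA"])
        sums = tpm.values.sum(axis=0)
        assert np.allclose(sums, 1e6)
        assert tpm.units == "TPM"

    def test_all_zero_column_names_sample(self):
        em = _em([[0, 1], [0, 2]], ["bad", "ok"], {"bad": "A", "ok": "B"})
        with pytest.raises(ValueError, match="bad"):
            tpm_normalize(em)

    def test_external_totals(self):
        em = _em([[50]], ["s1"], {"s1": "A"})
        tpm = tpm_normalize(em, totals={"s1": 1_000_000})
        assert tpm.values.loc["g0", "s1"] == pytest.approx(50.0)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_computed_cases(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_stepup_oracle_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(bh_stepup(p))
        assert np.all(np.asarray(adj) >= np.asarray(p) - 1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = bh_adjust(p)
        adj_perm = bh_adjust([p[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])


class TestNbExactTest:
    def test_identical_counts_are_null(self):
        # balancing row keeps library sizes equal
        em = _em(
            [[10, 10, 10, 10], [90, 90, 90, 90]],
            ["a1", "a2", "b1", "b2"],
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = nb_exact_test(em, ["a1", "a2"], ["b1", "b2"])
        assert res.loc["g0", "p_value"] == pytest.approx(1.0)
        assert res.loc["g0", "log2FC"] == pytest.approx(0.0)

    def test_strong_shift_matches_enumeration_oracle(self):
        # equal library sizes by construction (columns all sum to 200)
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        groups = {s: s[0].upper() for s in samples}
        rows = [
            [5, 6, 4, 50, 60, 40],
            [195, 194, 196, 150, 140, 160],
        ]
        em = _em(rows, samples, groups)
        res = nb_exact_test(em, samples[:3], samples[3:])
        assert res.loc["g0", "p_value"] < 0.05
        assert res.loc["g0", "log2FC"] == pytest.approx(3.3, abs=0.2)
        # windowed implementation vs full-support enumeration at the same
        # fitted dispersion
        from cerna_sponge.diffexpr import estimate_common_dispersion

        mat = em.values[samples].to_numpy(float)
        phi = estimate_common_dispersion(mat, [np.arange(3), np.arange(3, 6)])
        sa, s = 15, 165
        expected = conditional_nb_pvalue_enum(sa, s, 3 / phi, 3 / phi)
        assert res.loc["g0", "p_value"] == pytest.approx(expected, rel=1e-6)

    def test_single_sample_group_directs_to_noreplicate_path(self):
        em = _em([[1, 2, 3]], ["a1", "b1", "b2"], {"a1": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError, match="noreplicate"):
            nb_exact_test(em, ["a1"], ["b1", "b2"])


class TestNoReplicatePath:
    def test_identical_single_samples_null(self):
        em = _em([[10, 10], [90, 90]], ["a", "b"], {"a": "A", "b": "B"})
        res = binomial_test_noreplicate(em, "a", "b")
        assert res.loc["g0", "p_value"] == pytest.approx(1.0)
        q = qvalue_noreplicate(res["p_value"].to_numpy())
        assert q == pytest.approx([1.0, 1.0])

    def test_qvalue_stepup_example(self):
        assert qvalue_noreplicate([1e-6, 0.5, 0.9]) == pytest.approx(
            [3e-6, 0.75, 0.9]
        )

    def test_fold_change_gate_overrides_tiny_q(self):
        df = pd.DataFrame(
            {"log2FC": [0.8], "p_value": [1e-9], "adj_p": [1e-9]}, index=["g0"]
        )
        out = call_de(df, lfc_cut=1.0, padj_cut=0.01)
        assert out.loc["g0", "call"] == "not_significant"


class TestCallDe:
    @pytest.mark.parametrize(
        "lfc, padj, expected",
        [
            (1.2, 0.01, "up"),
            (-1.5, 0.04, "down"),
            (1.0, 0.001, "not_significant"),  # strict > 1
            (-1.0, 0.001, "not_significant"),
            (2.0, 0.05, "not_significant"),  # strict < 0.05
        ],
    )
    def test_threshold_semantics(self, lfc, padj, expected):
        df = pd.DataFrame(
            {"log2FC": [lfc], "p_value": [padj], "adj_p": [padj]}, index=["g0"]
        )
        assert call_de(df).loc["g0", "call"] == expected


class TestOverlap:
    def test_intersection_and_disjoint(self):
        assert overlap_de_sets({"a", "b", "c"}, {"b", "c", "d"}) == ["b", "c"]
        assert overlap_de_sets({"a"}, {"b"}) == []


class TestDeContrastOnPlantedData:
    def test_recovers_planted_directions(self, small_dataset):
        em = small_dataset.matrices["mRNA"]
        table = de_contrast(em, ("CON", "MOD"))
        planted = small_dataset.truth.de_directions("mRNA", ("CON", "MOD"))
        called = table[table["call"] != "not_significant"]
        hits = [f for f in planted if f in called.index]
        assert len(hits) / len(planted) >= 0.8
        for f in hits:
            assert table.loc[f, "call"] == planted[f]
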