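"""Jaccard/MLST distance structure and category decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cghpan import (
    ValidationError,
    cog_divergence,
    content_vs_phylogeny,
    decompose_divergence,
    jaccard_matrix,
    mlst_identity_matrix,
)
from _oracles import naive_jaccard, naive_symdiff, spearman_manual
from conftest import pa_from_array


class TestJaccard:
    def test_small_cases(self):
        # A={g1,g2,g3}, B={g2,g3,g4} -> 1 - 2/4 = 0.5
        arr = np.array([[1, 0], [1, 1], [1, 1], [0, 1]], dtype=bool)
        d = jaccard_matrix(pa_from_array(arr))
        assert d.iloc[0, 1] == pytest.approx(0.5)
        assert d.iloc[0, 0] == 0.0
        # identical and disjoint strains
        arr2 = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=bool)
        d2 = jaccard_matrix(pa_from_array(arr2))
        assert d2.iloc[0, 1] == 0.0
        assert d2.iloc[0, 2] == 1.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        arr = rng.random((40, 7)) < 0.6
        arr[0] = True  # no empty strain
        d = jaccard_matrix(pa_from_array(arr))
        assert np.allclose(d.to_numpy(), naive_jaccard(arr))

    def test_empty_strain_is_an_error(self):
        arr = np.zeros((4, 2), dtype=bool)
        arr[:, 0] = True
        with pytest.raises(ValidationError):
            jaccard_matrix(pa_from_array(arr))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.random((15, 6)) < rng.uniform(0.2, 0.9)
        arr[0] = True
        d = jaccard_matrix(pa_from_array(arr)).to_numpy()
        lhs = d[:, :, None]
        assert (lhs <= d[:, None, :] + d[None, :, :] + 1e-12).all()


class TestMlstIdentity:
    def test_identity_values(self):
        seqs = {"a": "ACGT" * 25, "b": "ACGT" * 25, "c": "TGCA" * 25}
        ident = mlst_identity_matrix(seqs)
        assert ident.loc["a", "b"] == 1.0
        assert ident.loc["a", "c"] == 0.0
        seqs2 = {"a": "A" * 100, "b": "A" * 97 + "CCC"}
        assert mlst_identity_matrix(seqs2).loc["a", "b"] == pytest.approx(0.97)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            mlst_identity_matrix({"a": "ACGT", "b": "ACG"})


class TestContentVsPhylogeny:
    def test_monotone_transform_gives_perfect_correlation(self):
        rng = np.random.default_rng(1)
        arr = rng.random((60, 6)) < 0.6
        arr[:10] = True
        jac = jaccard_matrix(pa_from_array(arr))
        sim = 1.0 - jac.to_numpy()
        ident = pd.DataFrame(sim**3, index=jac.index, columns=jac.columns)
        np.fill_diagonal(ident.values, 1.0)
        _, mantel = content_vs_phylogeny(jac, ident, n_permutations=49, seed=0)
        assert mantel.statistic == pytest.approx(1.0)

    def test_constant_identity_is_undefined(self):
        rng = np.random.default_rng(2)
        arr = rng.random((30, 5)) < 0.6
        arr[0] = True
        jac = jaccard_matrix(pa_from_array(arr))
        ident = pd.DataFrame(0.9, index=jac.index, columns=jac.columns)
        np.fill_diagonal(ident.values, 1.0)
        # off-diagonal identity constant across pairs
        pairs, mantel = content_vs_phylogeny(jac, ident, n_permutations=9, seed=0)
        assert np.isnan(mantel.statistic)
        assert len(pairs) == 10

    def test_correlation_matches_manual_rank_computation(self):
        rng = np.random.default_rng(3)
        arr = rng.random((40, 5)) < 0.6
        arr[0] = True
        jac = jaccard_matrix(pa_from_array(arr))
        ident_arr = rng.uniform(0.9, 1.0, (5, 5))
        ident_arr = (ident_arr + ident_arr.T) / 2
        np.fill_diagonal(ident_arr, 1.0)
        ident = pd.DataFrame(ident_arr, index=jac.index, columns=jac.columns)
        pairs, mantel = content_vs_phylogeny(jac, ident, n_permutations=9, seed=0)
        expected = spearman_manual(
            pairs["genomic_similarity"], pairs["mlst_identity"]
        )
        assert mantel.statistic == pytest.approx(expected)

    def test_too_few_strains_rejected(self):
        jac = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError):
            content_vs_phylogeny(jac, jac)


def ann_with_categories(genes, categories, cogs=None):
    return pd.DataFrame(
        {
            "order_index": range(len(genes)),
            "gc": 0.5,
            "category": categories,
            "cog": cogs if cogs is not None else [None] * len(genes),
        },
        index=genes,
    )


class TestDecompose:
    def test_pure_and_mixed_pairs(self):
        genes = [f"g{i}" for i in range(10)]
        cats = ["MGE"] * 5 + ["functional"] * 5
        # pair (s0,s1) differs in MGE genes only; (s0,s2) in 5 MGE + 5 functional
        arr = np.zeros((10, 3), dtype=bool)
        arr[:, 0] = True
        arr[5:, 1] = True
        ident = pd.DataFrame(
            np.ones((3, 3)), index=["s0", "s1", "s2"], columns=["s0", "s1", "s2"]
        )
        pa = pa_from_array(arr, genes=genes, strains=["s0", "s1", "s2"])
        pairs, _ = decompose_divergence(pa, ann_with_categories(genes, cats), ident)
        assert pairs.loc[("s0", "s1"), "frac_hypo_mge"] == 1.0
        assert pairs.loc[("s0", "s2"), "frac_hypo_mge"] == 0.5
        assert pairs.loc[("s0", "s2"), "frac_functional"] == 0.5

    def test_counts_match_naive_double_loop_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(50)]
        cats = rng.choice(["functional", "hypothetical", "MGE"], size=50)
        arr = rng.random((50, 6)) < 0.6
        arr[0] = True
        strains = [f"s{j}" for j in range(6)]
        ident_arr = rng.uniform(0.9, 1.0, (6, 6))
        ident_arr = (ident_arr + ident_arr.T) / 2
        np.fill_diagonal(ident_arr, 1.0)
        ident = pd.DataFrame(ident_arr, index=strains, columns=strains)
        pa = pa_from_array(arr, genes=genes, strains=strains)
        pairs, _ = decompose_divergence(pa, ann_with_categories(genes, cats), ident)

        total = naive_symdiff(arr)
        hm = naive_symdiff(arr[(cats == "hypothetical") | (cats == "MGE")])
        iu = np.triu_indices(6, 1)
        assert (pairs["n_diff_total"].to_numpy() == total[iu]).all()
        assert (pairs["n_diff_hypo_mge"].to_numpy() == hm[iu]).all()
        nonzero = pairs["n_diff_total"] > 0
        sums = pairs.loc[nonzero, "frac_hypo_mge"] + pairs.loc[nonzero, "frac_functional"]
        assert np.allclose(sums, 1.0)
        assert (
            pairs["n_diff_hypo_mge"] + pairs["n_diff_functional"]
            == pairs["n_diff_total"]
        ).all()

    def test_uncategorized_gene_is_an_error(self):
        genes = ["g0", "g1"]
        ann = ann_with_categories(genes, ["functional", None])
        pa = pa_from_array(np.ones((2, 3)), genes=genes)
        ident = pd.DataFrame(np.ones((3, 3)), index=["s0", "s1", "s2"], columns=["s0", "s1", "s2"])
        with pytest.raises(ValidationError):
            decompose_divergence(pa, ann, ident)


class TestCogDivergence:
    def test_identical_strains_give_zero_counts(self):
        genes = ["g0", "g1"]
        ann = ann_with_categories(genes, ["functional"] * 2, cogs=["M", "K"])
        arr = np.ones((2, 3), dtype=bool)
        strains = ["s0", "s1", "s2"]
        ident = pd.DataFrame(np.ones((3, 3)), index=strains, columns=strains)
        pairs, _ = cog_divergence(pa_from_array(arr, genes=genes, strains=strains), ann, ident)
        assert (pairs[["K", "M"]].to_numpy() == 0).all()

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        cogs = rng.choice(["M", "T", "K", None], size=30)
        ann = ann_with_categories(genes, ["functional"] * 30, cogs=cogs)
        arr = rng.random((30, 5)) < 0.5
        strains = [f"s{j}" for j in range(5)]
        ident = pd.DataFrame(np.ones((5, 5)), index=strains, columns=strains)
        pairs, summary = cog_divergence(
            pa_from_array(arr, genes=genes, strains=strains), ann, ident
        )
        iu = np.triu_indices(5, 1)
        for letter in "MTK":
            expect = naive_symdiff(arr[cogs == letter])[iu]
            assert (pairs[letter].to_numpy() == expect).all()
        assert set(summary["cog"]) <= {"M", "T", "K"}
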