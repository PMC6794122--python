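"""Island detection along the reference order and island statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cghpan import (
    GenomicIsland,
    PresenceAbsenceMatrix,
    detect_islands,
    island_congruence,
    island_gc_contrast,
    island_stats,
    soft_core,
    variable_flags,
)
from cghpan.islands import round_half_away
from _oracles import islands_by_splitting, kendall_tau_b
from conftest import pa_from_array


def ann_table(genes, gc=0.5, category="functional", order=None):
    n = len(genes)
    return pd.DataFrame(
        {
            "order_index": order if order is not None else range(n),
            "gc": gc if np.iterable(gc) else [gc] * n,
            "category": category if not isinstance(category, str) else [category] * n,
            "cog": [None] * n,
        },
        index=genes,
    )


def flags_series(bits):
    return pd.Series(
        [bool(b) for b in bits], index=[f"g{i}" for i in range(len(bits))]
    )


class TestVariableFlags:
    def test_all_core_means_no_variable_genes(self):
        pa = pa_from_array(np.ones((5, 4)))
        ann = ann_table([f"g{i}" for i in range(5)])
        core, _ = soft_core(pa, 0.5)
        flags = variable_flags(pa, core, ann)
        assert not flags.any()

    def test_flags_follow_prevalence_and_annotation_order(self):
        rng = np.random.default_rng(0)
        arr = rng.random((30, 10)) < 0.8
        genes = [f"g{i}" for i in range(30)]
        order = rng.permutation(30)
        pa = pa_from_array(arr, genes=genes)
        ann = ann_table(genes, order=order)
        core, _ = soft_core(pa, 0.90)
        flags = variable_flags(pa, core, ann)
        # brute recomputation from prevalence, reordered by order_index
        for g in genes:
            prev = arr[genes.index(g)].mean()
            assert flags[g] == (prev <= 0.90)
        assert list(flags.index) == [genes[i] for i in np.argsort(order)]

    def test_missing_order_index_is_an_error(self):
        pa = pa_from_array(np.ones((2, 2)), genes=["g0", "gX"])
        ann = ann_table(["g0", "g1"])
        with pytest.raises(Exception):
            variable_flags(pa, pd.Index([]), ann)


class TestDetectIslands:
    def test_single_run_of_twelve(self):
        flags = flags_series([0] * 5 + [1] * 12 + [0] * 5)
        islands = detect_islands(flags)
        assert len(islands) == 1
        assert islands[0].size == 12

    def test_run_of_ten_is_below_the_over_ten_threshold(self):
        flags = flags_series([0] * 5 + [1] * 10 + [0] * 5)
        assert detect_islands(flags, min_run=11) == []
        assert len(detect_islands(flags, min_run=10)) == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        bits=st.lists(st.booleans(), min_size=1, max_size=200),
        max_gap=st.sampled_from([0, 2]),
        min_run=st.sampled_from([3, 11]),
    )
    def test_matches_string_splitting_oracle(self, bits, max_gap, min_run):
        flags = flags_series(bits)
        got = [
            [flags.index.get_loc(g) for g in isl.member_genes]
            for isl in detect_islands(flags, min_run=min_run, max_gap=max_gap)
        ]
        assert got == islands_by_splitting(bits, min_run, max_gap)

    def test_islands_disjoint_sorted_and_gap_merging_monotone(self):
        rng = np.random.default_rng(8)
        bits = rng.random(300) < 0.5
        flags = flags_series(bits)
        for gap in (0, 1, 3):
            islands = detect_islands(flags, min_run=3, max_gap=gap)
            spans = [
                (flags.index.get_loc(i.start_locus), flags.index.get_loc(i.end_locus))
                for i in islands
            ]
            assert spans == sorted(spans)
            assert all(a1 < b0 for (_, a1), (b0, _) in zip(spans, spans[1:]))
        small = detect_islands(flags, min_run=3, max_gap=0)
        large = detect_islands(flags, min_run=3, max_gap=3)
        # every gap-0 island lies inside some gap-3 island span
        for isl in small:
            s0 = flags.index.get_loc(isl.start_locus)
            e0 = flags.index.get_loc(isl.end_locus)
            assert any(
                flags.index.get_loc(big.start_locus) <= s0
                and e0 <= flags.index.get_loc(big.end_locus)
                for big in large
            )


class TestIslandStats:
    def test_uniform_gc_gives_zero_sd(self):
        genes = [f"g{i}" for i in range(12)]
        isl = GenomicIsland(1, genes[0], genes[-1], genes)
        out = island_stats(isl, ann_table(genes, gc=0.40))
        assert out.gc_mean == pytest.approx(0.40)
        assert out.gc_sd == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "n_hypo,n_mge,size,expected",
        [(27, 10, 46, 80), (14, 5, 19, 100), (24, 12, 40, 90), (0, 0, 11, 0), (16, 4, 32, 63)],
    )
    def test_hypo_mge_percent_rounding(self, n_hypo, n_mge, size, expected):
        genes = [f"g{i}" for i in range(size)]
        cats = (
            ["hypothetical"] * n_hypo
            + ["MGE"] * n_mge
            + ["functional"] * (size - n_hypo - n_mge)
        )
        out = island_stats(
            GenomicIsland(1, genes[0], genes[-1], genes), ann_table(genes, category=cats)
        )
        assert (out.n_hypothetical, out.n_mge) == (n_hypo, n_mge)
        assert out.hypo_mge_pct == expected

    def test_round_half_away_from_zero(self):
        assert round_half_away(62.5) == 63
        assert round_half_away(62.4) == 62
        assert round_half_away(-0.5) == -1


class TestGcContrast:
    def test_shifted_island_detected_identical_island_not(self):
        rng = np.random.default_rng(12)
        core_genes = [f"c{i}" for i in range(200)]
        shift_genes = [f"s{i}" for i in range(15)]
        same_genes = [f"m{i}" for i in range(15)]
        gc = np.concatenate(
            [
                rng.normal(0.47, 0.02, 200),
                rng.normal(0.42, 0.02, 15),
                rng.normal(0.47, 0.02, 15),
            ]
        )
        ann = ann_table(core_genes + shift_genes + same_genes, gc=gc)
        islands = [
            GenomicIsland(1, shift_genes[0], shift_genes[-1], shift_genes),
            GenomicIsland(2, same_genes[0], same_genes[-1], same_genes),
        ]
        out = island_gc_contrast(islands, pd.Index(core_genes), ann)
        assert out.loc[0, "gc_diff"] < -0.03
        assert out.loc[0, "p_value"] < 0.01
        assert abs(out.loc[1, "gc_diff"]) < 0.02
        assert out.loc[1, "p_value"] > 0.05

    def test_tiny_island_skips_test_but_reports_difference(self):
        genes = ["a", "b"]
        ann = ann_table(genes + ["c0", "c1", "c2"], gc=[0.4, 0.4, 0.5, 0.5, 0.5])
        out = island_gc_contrast(
            [GenomicIsland(1, "a", "b", genes)], pd.Index(["c0", "c1", "c2"]), ann
        )
        assert out.loc[0, "gc_diff"] == pytest.approx(-0.1)
        assert np.isnan(out.loc[0, "p_value"])


class TestCongruence:
    def test_island_equal_to_all_auxiliary_gives_tau_one(self):
        rng = np.random.default_rng(3)
        arr = rng.random((20, 8)) < 0.5
        pa = pa_from_array(arr)
        isl = GenomicIsland(1, "g0", "g19", list(pa.values.index))
        tau, p = island_congruence(isl, pa, n_permutations=49, seed=0)
        assert tau == pytest.approx(1.0)

    def test_constant_pattern_is_undefined(self):
        arr = np.ones((10, 6), dtype=bool)
        arr[5:, :] = False  # all strains identical -> zero-variance distances
        pa = pa_from_array(arr)
        isl = GenomicIsland(1, "g0", "g4", [f"g{i}" for i in range(5)])
        tau, p = island_congruence(isl, pa, n_permutations=9, seed=0)
        assert np.isnan(tau) and np.isnan(p)

    def test_tau_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        arr = rng.random((24, 6)) < 0.5
        pa = pa_from_array(arr)
        members = [f"g{i}" for i in range(8)]
        isl = GenomicIsland(1, members[0], members[-1], members)
        tau, _ = island_congruence(isl, pa, n_permutations=9, seed=0)
        from cghpan.divergence import jaccard_condensed

        d_isl = jaccard_condensed(arr[:8])
        d_all = jaccard_condensed(arr)
        mask = ~(np.isnan(d_isl) | np.isnan(d_all))
        assert tau == pytest.approx(kendall_tau_b(d_isl[mask], d_all[mask]))
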