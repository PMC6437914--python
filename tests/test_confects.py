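"""Nested-BH selection, confect values, ordering, and FCR validity."""

import itertools

import numpy as np
import pytest

from confects.core import ConfectParams, bh_largest_set, confect_scan
from confects.model import ConfectModel, compute_confects
from confects.treat import treat_pvalue

from conftest import random_gene_stats


def brute_force_largest_set(pvals, q):
    """Largest set S with p_i <= |S| q / n for all members, by enumeration."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    best = ()
    for r in range(n, 0, -1):
        for combo in itertools.combinations(range(n), r):
            if all(p[i] <= r * q / n for i in combo):
                best = combo
                break
        if best:
            break
    return set(best)


def oracle_confects(stats, grid, q):
    """Independent oracle: run BH separately at every grid value and take
    each gene's largest qualifying threshold (no use of nesting)."""
    n = len(stats)
    mag = np.full(n, np.nan)
    for e in grid:
        p = treat_pvalue(stats.effect, stats.se, stats.df, e)
        sel = bh_largest_set(p, q, n)
        mag[sel] = e
    return mag


class TestBHLargestSet:
    def test_all_ones_selects_nothing(self):
        assert not bh_largest_set([1.0] * 5, 0.05).any()

    def test_single_small_p_selected(self):
        assert bh_largest_set([0.01], 0.05).all()

    def test_worked_example(self):
        # k = 3 fails (0.04 > 3 * 0.05/4 = 0.0375), k = 2 passes
        # (0.02 <= 2 * 0.05/4 = 0.025)
        mask = bh_largest_set([0.001, 0.02, 0.04, 0.9], 0.05)
        assert list(mask) == [True, True, False, False]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            n = rng.integers(1, 13)
            p = np.round(rng.uniform(0, 1, n) ** 2, 3)
            q = rng.choice([0.05, 0.2, 0.5])
            sel = set(np.flatnonzero(bh_largest_set(p, q)))
            ref = brute_force_largest_set(p, q)
            assert len(sel) == len(ref)
            # step-up picks the smallest p's; with ties any maximal set has
            # the same multiset of p-values
            assert sorted(p[list(sel)]) == pytest.approx(sorted(p[list(ref)]))

    def test_universe_larger_than_pvals(self):
        # BH denominator is the full gene universe even on a subset
        p = [0.0001, 0.0008]
        assert bh_largest_set(p, 0.05, n_gene=100).all()
        # the same p-values fail once the universe grows (0.0001 > 0.05/1000)
        assert not bh_largest_set(p, 0.05, n_gene=1000).any()

    def test_invalid_pvalues_raise(self):
        with pytest.raises(ValueError):
            bh_largest_set([0.5, 1.2], 0.05)


class TestNestedSetsFixture:
    """A nine-gene instance with selections of sizes 7, 6, 3, 1, 0 on a
    grid of step 0.5, whose confect magnitudes must come out
    1.5, 1, 1, 0.5, 0.5, 0.5, 0 with the last two genes unvalued."""

    def test_confect_magnitudes(self, nested_sets_model):
        res = nested_sets_model.fit(fdr=0.05, step=0.5)
        mags = np.abs(res.table["confect"].to_numpy())
        assert mags[:7] == pytest.approx([1.5, 1.0, 1.0, 0.5, 0.5, 0.5, 0.0])
        assert np.isnan(mags[7:]).all()
        assert res.n_with_confect == 7

    def test_signs_follow_effects(self, nested_sets_model):
        res = nested_sets_model.fit(fdr=0.05, step=0.5)
        row = res.table.set_index("gene_id")
        assert row.loc["g3", "confect"] == -1.0
        assert row.loc["g1", "confect"] == 1.5

    def test_set_sizes_along_grid(self, nested_sets_model):
        res = nested_sets_model.fit(fdr=0.05, step=0.5)
        assert list(res.scan.set_sizes) == [7, 6, 3, 1, 0]
        assert len(res.selected_set_at(0.0)) == 7
        assert len(res.selected_set_at(1.0)) == 3
        assert len(res.selected_set_at(5.0)) == 0

    def test_unvalued_genes_ordered_by_p_zero(self, nested_sets_model):
        res = nested_sets_model.fit(fdr=0.05, step=0.5)
        assert list(res.table["gene_id"].tail(2)) == ["g8", "g9"]


class TestComputeConfects:
    def test_matches_per_threshold_oracle(self):
        rng = np.random.default_rng(1)
        q = 0.05
        grid = np.arange(0, 3.01, 0.1)
        for _ in range(20):
            stats = random_gene_stats(rng, int(rng.integers(5, 51)))
            res = compute_confects(stats, fdr=q, step=0.1, max_e=3.0)
            ref = oracle_confects(stats, grid, q)
            got = res.scan.confect_mag
            assert np.allclose(np.isnan(got), np.isnan(ref))
            ok = ~np.isnan(ref)
            assert np.allclose(got[ok], ref[ok])

    def test_sets_nest(self):
        rng = np.random.default_rng(2)
        stats = random_gene_stats(rng, 120)
        res = compute_confects(stats, fdr=0.1, step=0.05)
        sizes = res.scan.set_sizes
        assert np.all(np.diff(sizes) <= 0)
        prev = None
        for e in res.scan.grid[::4]:
            cur = set(res.selected_set_at(e))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_equals_treat_then_bh_at_each_threshold(self):
        # selecting down to |confect| = e reproduces TREAT+BH at threshold e
        rng = np.random.default_rng(3)
        stats = random_gene_stats(rng, 150)
        res = compute_confects(stats, fdr=0.05, step=0.25, max_e=5.0)
        for e in (0.0, 0.5, 1.0, 2.0):
            p = treat_pvalue(stats.effect, stats.se, stats.df, e)
            direct = set(stats.gene_id[bh_largest_set(p, 0.05, len(stats))])
            assert set(res.selected_set_at(e)) == direct

    def test_grid_refinement_preserves_shared_memberships(self):
        rng = np.random.default_rng(4)
        stats = random_gene_stats(rng, 80)
        coarse = compute_confects(stats, fdr=0.05, step=0.2)
        fine = compute_confects(stats, fdr=0.05, step=0.05)
        for e in coarse.scan.grid:
            assert set(coarse.selected_set_at(e)) == set(fine.selected_set_at(e))

    def test_all_null_genes_rank_by_p_zero(self):
        rng = np.random.default_rng(5)
        stats = random_gene_stats(rng, 30, effect_scale=0.01, se=(1.0, 2.0))
        res = compute_confects(stats, fdr=0.05)
        assert res.n_with_confect == 0
        p0 = res.table["p_zero"].to_numpy()
        assert np.all(np.diff(p0) >= 0)

    def test_confect_magnitude_bounded_by_effect(self):
        rng = np.random.default_rng(6)
        stats = random_gene_stats(rng, 200)
        res = compute_confects(stats, fdr=0.05, step=0.02)
        has = ~np.isnan(res.confect)
        assert np.all(np.abs(res.confect[has]) <= np.abs(stats.effect[has]))

    def test_order_is_strict_total_and_magnitudes_nonincreasing(self):
        rng = np.random.default_rng(7)
        stats = random_gene_stats(rng, 100)
        res = compute_confects(stats, fdr=0.2, step=0.05)
        assert sorted(res.table["rank"]) == list(range(1, 101))
        mags = np.abs(res.table["confect"].to_numpy()[: res.n_with_confect])
        assert np.all(np.diff(mags) <= 1e-12)

    def test_order_stable_under_gene_relabeling(self):
        rng = np.random.default_rng(8)
        stats = random_gene_stats(rng, 60)
        res1 = compute_confects(stats, fdr=0.1)
        stats2 = random_gene_stats(rng := np.random.default_rng(8), 60)
        stats2.gene_id = np.array([f"x{i:03d}" for i in range(60)], dtype=object)
        res2 = compute_confects(stats2, fdr=0.1)
        assert np.array_equal(res1.order, res2.order)

    def test_max_e_truncation_warns(self):
        rng = np.random.default_rng(9)
        stats = random_gene_stats(rng, 20, effect_scale=10.0, se=(0.01, 0.02))
        with pytest.warns(RuntimeWarning, match="max_e"):
            res = compute_confects(stats, fdr=0.05, step=0.5, max_e=2.0)
        assert res.scan.truncated
        assert res.n_with_confect > 0

    def test_empty_input_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ConfectModel(pd.DataFrame(columns=["gene_id", "effect", "se", "df"]))


class TestFcrInequality:
    def test_random_sweep_has_no_violations(self):
        rng = np.random.default_rng(10)
        stats = random_gene_stats(rng, 200)
        for q in (0.01, 0.05, 0.2):
            res = compute_confects(stats, fdr=q, step=0.05)
            check = res.check_fcr_inequality()
            assert bool(check)
            assert check.max_slack <= 0
            assert len(check.violations) == 0

    def test_single_significant_gene(self):
        from confects.moderation import GeneStats

        stats = GeneStats(np.array(["g0"], dtype=object), [8.0], [0.2], 10.0)
        res = compute_confects(stats, fdr=0.05, step=0.05)
        assert res.n_with_confect == 1
        b = abs(res.confect[0])
        p = treat_pvalue(stats.effect[0], stats.se[0], stats.df[0], b)
        assert p <= 0.05
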