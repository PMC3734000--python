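"""TagSNP selectors: hand-traced examples, covering property, brute-force
set-cover comparison and determinism."""

import numpy as np
import pytest

from tagimpute import (
    HaplotypePanel,
    MarkerMap,
    compute_maf,
    ia_overall,
    impute,
    ld_matrix,
    select_even_spacing,
    select_predictive,
    select_statistical,
    select_weighted_spacing,
)
from tagimpute.ld import LDMatrix
from tagimpute.select import statistical_tags_for_panel

from _oracles import minimal_cover_bruteforce
from conftest import random_panel


class TestEvenSpacing:
    def test_hand_traced_two_segments(self):
        mm = MarkerMap.from_positions([10, 30, 50, 70, 90])
        res = select_even_spacing(mm, 2, chromosome_length={"1": 100})
        assert list(mm.position_bp[res.tags.marker_indices]) == [30, 70]

    def test_empty_segment_yields_fewer_tags(self):
        mm = MarkerMap.from_positions([10, 20])
        res = select_even_spacing(mm, 2, chromosome_length={"1": 100})
        assert len(res) == 1
        assert mm.position_bp[res.tags.marker_indices[0]] == 20  # nearest to 25

    def test_k_one_picks_snp_nearest_midpoint(self):
        mm = MarkerMap.from_positions([10, 40, 90])
        res = select_even_spacing(mm, 1, chromosome_length={"1": 100})
        assert mm.position_bp[res.tags.marker_indices[0]] == 40

    def test_default_length_is_max_position(self):
        mm = MarkerMap.from_positions([10, 30, 50, 70, 90])
        res = select_even_spacing(mm, 2)  # L = 90, centers 22.5 and 67.5
        assert list(mm.position_bp[res.tags.marker_indices]) == [30, 70]

    def test_tag_count_never_exceeds_k(self, sim_panel):
        for k in (3, 10, 40):
            res = select_even_spacing(sim_panel.markers, k)
            assert len(res) <= k


def _ld_from_matrix(vals, positions=None):
    m = len(vals)
    pos = positions if positions is not None else np.arange(1, m + 1) * 1000
    return LDMatrix(
        np.asarray(vals, dtype=float),
        MarkerMap.from_positions(pos),
        segregating=np.ones(m, dtype=bool),
    )


class TestStatisticalSelection:
    def test_complete_ld_needs_one_tag(self):
        ld = _ld_from_matrix(np.ones((5, 5)))
        res = select_statistical(ld, 0.5)
        assert len(res) == 1
        assert res.diagnostics["coverage"] == 1.0

    def test_no_ld_needs_all_tags(self):
        ld = _ld_from_matrix(np.eye(6))
        res = select_statistical(ld, 0.3)
        assert len(res) == 6

    def test_covering_property_on_simulated_panels(self, sim_panel):
        ld = ld_matrix(sim_panel)
        maf = compute_maf(sim_panel)
        for rt2 in (0.2, 0.5, 0.8):
            res = select_statistical(ld, rt2, maf=maf)
            tags = res.tags.marker_indices
            non_tags = np.setdiff1d(np.flatnonzero(ld.segregating), tags)
            best = np.nanmax(ld.values[np.ix_(non_tags, tags)], axis=1)
            assert np.all(best >= rt2)

    def test_greedy_between_optimum_and_log_bound(self, rng):
        """Greedy cover size >= brute-force optimum, <= optimum*(1+ln M)."""
        for _ in range(25):
            m = int(rng.integers(4, 11))
            panel = random_panel(rng, n_hap=12, n_markers=m)
            ld = ld_matrix(panel)
            rt2 = float(rng.uniform(0.1, 0.9))
            res = select_statistical(ld, rt2, maf=compute_maf(panel))
            with np.errstate(invalid="ignore"):
                cover = (ld.values >= rt2)
            np.fill_diagonal(cover, True)
            sets = [set(np.flatnonzero(cover[i])) for i in range(m)]
            opt = minimal_cover_bruteforce(sets)
            assert opt <= len(res) <= max(opt * (1 + np.log(m)), opt)

    def test_tag_count_non_decreasing_in_threshold(self, sim_panel):
        ld = ld_matrix(sim_panel)
        maf = compute_maf(sim_panel)
        counts = [len(select_statistical(ld, t, maf=maf)) for t in np.arange(0.1, 1.0, 0.1)]
        assert counts == sorted(counts)

    def test_deterministic(self, sim_panel):
        ld = ld_matrix(sim_panel)
        maf = compute_maf(sim_panel)
        a = select_statistical(ld, 0.4, maf=maf)
        b = select_statistical(ld, 0.4, maf=maf)
        np.testing.assert_array_equal(a.tags.marker_indices, b.tags.marker_indices)

    def test_invalid_threshold_rejected(self, sim_panel):
        with pytest.raises(ValueError, match="rt2"):
            select_statistical(ld_matrix(sim_panel), 1.5)


def _default_imputer(masked, reference):
    from tagimpute import HMMParams

    return impute(masked, reference, HMMParams(error_rate=1e-3))


def _mean_ia(truth, posterior, eval_at):
    return ia_overall(truth, posterior, eval_at).overall


class TestPredictiveSelection:
    def test_single_marker_is_the_tag(self, rng):
        panel = random_panel(rng, n_hap=12, n_markers=1)
        res = select_predictive(panel, 1, 3, _default_imputer, _mean_ia, seed=0)
        assert list(res.tags.marker_indices) == [0]

    def test_duplicate_columns_not_both_selected(self, rng):
        """With two identical SNP and one independent SNP, the pair carries
        no extra information: the search takes one duplicate plus the
        independent marker."""
        n_hap = 16
        while True:
            a = rng.integers(0, 2, n_hap)
            c = rng.integers(0, 2, n_hap)
            if 0 < a.sum() < n_hap and 0 < c.sum() < n_hap and not np.array_equal(a, c):
                break
        alleles = np.column_stack([a, a, c]).astype(np.int8)
        panel = HaplotypePanel(alleles, MarkerMap.from_positions([1000, 2000, 3000]))
        res = select_predictive(panel, 2, 3, _default_imputer, _mean_ia, seed=1, evaluate="all")
        tags = set(res.tags.marker_indices)
        assert 2 in tags
        assert tags & {0, 1} and len(tags) == 2

    def test_training_accuracy_non_decreasing_along_trace(self, rng):
        panel = random_panel(rng, n_hap=16, n_markers=6, spacing=100_000)
        res = select_predictive(panel, 4, 4, _default_imputer, _mean_ia, seed=2, evaluate="all")
        scores = [s for _, s in res.diagnostics["trace"]]
        assert all(b >= a - 1e-6 for a, b in zip(scores, scores[1:]))

    def test_deterministic_given_seed(self, rng):
        panel = random_panel(rng, n_hap=12, n_markers=5, spacing=100_000)
        a = select_predictive(panel, 3, 3, _default_imputer, _mean_ia, seed=7)
        b = select_predictive(panel, 3, 3, _default_imputer, _mean_ia, seed=7)
        np.testing.assert_array_equal(a.tags.marker_indices, b.tags.marker_indices)


class TestWeightedSpacing:
    def test_degenerate_score_matches_even_segment_occupancy(self):
        pos = np.arange(1, 101) * 100_000  # uniform 100-marker map
        mm = MarkerMap.from_positions(pos)
        k = 10
        res = select_weighted_spacing(
            mm, {"p": np.full(100, 0.25)}, {"p": 1.0},
            end_window_bp=0, end_density_multiplier=1.0, k_per_chromosome=k,
        )
        assert len(res) == k
        # each even-spacing segment holds exactly one tag (+-1)
        length = pos.max()
        seg = np.minimum((pos[res.tags.marker_indices] / (length / k)).astype(int), k - 1)
        counts = np.bincount(seg, minlength=k)
        assert np.all(np.abs(counts - 1) <= 1)

    def test_end_windows_receive_doubled_density(self):
        pos = np.arange(1, 201) * 50_000  # 10 Mb uniform map
        mm = MarkerMap.from_positions(pos)
        k = 30
        window = int(0.05 * pos.max())
        res = select_weighted_spacing(
            mm, {"p": np.full(200, 0.25)}, {"p": 1.0},
            end_window_bp=window, end_density_multiplier=2.0, k_per_chromosome=k,
        )
        tag_pos = pos[res.tags.marker_indices]
        lo, hi = pos.min(), pos.max()
        in_end = (tag_pos - lo <= window) | (hi - tag_pos <= window)
        end_len, interior_len = 2 * window, (hi - lo) - 2 * window
        density_ratio = (in_end.sum() / end_len) / ((~in_end).sum() / interior_len)
        expected_end = 2 * 0.1 * k / 1.1
        assert abs(in_end.sum() - expected_end) <= 1.5
        assert density_ratio > 1.3

    def test_zero_weight_population_ignored(self, rng):
        pos = np.arange(1, 61) * 100_000
        mm = MarkerMap.from_positions(pos)
        maf_a = rng.uniform(0.05, 0.5, 60)
        maf_b = rng.uniform(0.05, 0.5, 60)
        both = select_weighted_spacing(
            mm, {"a": maf_a, "b": maf_b}, {"a": 1.0, "b": 0.0},
            end_window_bp=0, end_density_multiplier=1.0, k_per_chromosome=12,
        )
        only_a = select_weighted_spacing(
            mm, {"a": maf_a}, {"a": 1.0},
            end_window_bp=0, end_density_multiplier=1.0, k_per_chromosome=12,
        )
        np.testing.assert_array_equal(both.tags.marker_indices, only_a.tags.marker_indices)

    def test_missing_maf_table_for_weighted_population(self):
        mm = MarkerMap.from_positions([1, 2, 3])
        with pytest.raises(ValueError, match="MAF table"):
            select_weighted_spacing(mm, {}, {"x": 1.0}, 0, 1.0, 2)


class TestSelectionOrdering:
    def test_statistical_beats_even_spacing_downstream(self, sim_panel):
        """At matched tag counts, LD-aware tags impute at least as well as
        evenly spaced tags (paired over replicates elsewhere; single panel
        here as a smoke check of the full selection-imputation loop)."""
        from tagimpute import mask_to_tagsnp, sample_unrelated

        ref = sim_panel.subset_haplotypes(range(64))
        geno, _ = sample_unrelated(sim_panel.subset_haplotypes(range(64, 226)), 15, seed=3)
        stat = statistical_tags_for_panel(ref, 0.3)
        even = select_even_spacing(geno.markers, len(stat))
        ias = {}
        for name, sel in [("stat", stat), ("even", even)]:
            masked = mask_to_tagsnp(geno, sel.tags)
            post = impute(masked, ref)
            ev = np.setdiff1d(np.arange(geno.n_markers), sel.tags.marker_indices)
            ias[name] = ia_overall(geno, post, ev).overall
        assert ias["stat"] > ias["even"] - 0.02
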