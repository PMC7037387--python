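"""EAP scoring, Lord-Wingersky summed-score tables, 0-100 rescaling."""

import itertools

import numpy as np
import pytest

from conftest import make_benchmark_items, simulate_single_group
from saqirt.calibrate import LatentGroupParams, QuadratureGrid
from saqirt.grm import GrmItemParams, category_probs
from saqirt.pipeline import result_from_items
from saqirt.scoring import (
    RescaleConfig,
    eap_pattern,
    rescale_0_100,
    score_matrix,
    summed_score_table,
)

SYMMETRIC = GrmItemParams("sym", 1.0, (2.0, 1.0, -1.0, -2.0))


def brute_force_table(items, grid):
    """Exhaustive-enumeration oracle for the summed-score distribution."""
    sums = {}
    for pattern in itertools.product(*[range(1, it.n_categories + 1) for it in items]):
        like = grid.weights.copy()
        for it, x in zip(items, pattern):
            like = like * category_probs(it, grid.nodes)[:, x - 1]
        s = sum(pattern)
        p, m = like.sum(), (like * grid.nodes).sum()
        if s in sums:
            sums[s] = (sums[s][0] + p, sums[s][1] + m)
        else:
            sums[s] = (p, m)
    return sums


class TestEapPattern:
    def test_symmetric_item_middle_response_scores_zero(self):
        score = eap_pattern([SYMMETRIC], [3])
        assert score.theta_hat == pytest.approx(0.0, abs=1e-12)
        assert score.theta_rounded == 0.0

    def test_matches_fine_grid_integration(self, bench_item_list):
        fine = QuadratureGrid.equally_spaced(10_001, -6, 6)
        rng = np.random.default_rng(0)
        for _ in range(25):
            pattern = rng.integers(1, 6, len(bench_item_list))
            coarse = eap_pattern(bench_item_list, pattern)
            exact = eap_pattern(bench_item_list, pattern, grid=fine)
            assert abs(coarse.theta_hat - exact.theta_hat) < 1e-6

    def test_monotone_in_each_response(self):
        items = make_benchmark_items(n_items=3, seed=2)
        ilist = list(items.values())
        for pattern in itertools.product(range(1, 6), repeat=3):
            base = eap_pattern(ilist, pattern).theta_hat
            for j in range(3):
                if pattern[j] == 5:
                    continue
                raised = list(pattern)
                raised[j] += 1
                assert eap_pattern(ilist, raised).theta_hat >= base - 1e-12

    def test_posterior_sd_shrinks_with_information(self, bench_item_list):
        prior_sd = 1.0
        partial = eap_pattern(bench_item_list, [4, None, None, None, None])
        full = eap_pattern(bench_item_list, [4, 4, 3, 5, 4])
        assert partial.posterior_sd < prior_sd
        assert full.posterior_sd <= partial.posterior_sd

    def test_group_prior_pulls_toward_group_mean(self, bench_item_list):
        low = LatentGroupParams("low", mu=-1.0, sigma=1.0)
        neutral = eap_pattern(bench_item_list, [3, 3, 3, 3, 3])
        shifted = eap_pattern(bench_item_list, [3, 3, 3, 3, 3], prior=low)
        assert shifted.theta_hat < neutral.theta_hat

    def test_all_missing_raises(self, bench_item_list):
        with pytest.raises(ValueError, match="missing"):
            eap_pattern(bench_item_list, [None] * 5)

    def test_grid_refinement_converged(self, bench_item_list):
        g49 = QuadratureGrid.equally_spaced(49)
        g97 = QuadratureGrid.equally_spaced(97)
        rng = np.random.default_rng(1)
        for _ in range(25):
            pattern = rng.integers(1, 6, 5)
            a = eap_pattern(bench_item_list, pattern, grid=g49).theta_hat
            b = eap_pattern(bench_item_list, pattern, grid=g97).theta_hat
            assert abs(a - b) < 1e-6


class TestScoreMatrix:
    def test_identical_patterns_identical_scores(self, bench_spec, bench_items):
        matrix, _ = simulate_single_group(bench_spec, bench_items, n=300, seed=5)
        calib = result_from_items(list(bench_items.values()), "D", bench_spec.item_ids)
        scores = score_matrix(matrix, calib, bench_spec)
        key = matrix.data.astype(str).agg("|".join, axis=1)
        grouped = scores.groupby(key)["D_theta"].nunique()
        assert (grouped == 1).all()

    def test_trait_recovery_correlation(self, bench_spec, bench_items):
        matrix, truth = simulate_single_group(bench_spec, bench_items, n=5000, seed=6)
        calib = result_from_items(list(bench_items.values()), "D", bench_spec.item_ids)
        scores = score_matrix(matrix, calib, bench_spec)
        r = np.corrcoef(scores["D_theta"], truth.theta["D"])[0, 1]
        assert r >= 0.85

    def test_rounded_column_is_2dp(self, bench_spec, bench_items):
        matrix, _ = simulate_single_group(bench_spec, bench_items, n=100, seed=7)
        calib = result_from_items(list(bench_items.values()), "D", bench_spec.item_ids)
        scores = score_matrix(matrix, calib, bench_spec)
        np.testing.assert_allclose(
            scores["D_theta_2dp"], np.round(scores["D_theta"], 2), atol=1e-12
        )


class TestSummedScoreTable:
    def test_matches_exhaustive_enumeration_two_items(self, bench_item_list):
        items = bench_item_list[:2]
        grid = QuadratureGrid.equally_spaced()
        table = summed_score_table(items, grid=grid)
        oracle = brute_force_table(items, grid)
        assert list(table.summed_score) == list(range(2, 11))
        for _, row in table.iterrows():
            p, m = oracle[int(row.summed_score)]
            assert row.probability == pytest.approx(p, abs=1e-12)
            assert row.eap == pytest.approx(m / p, abs=1e-12)

    def test_single_item_reduces_to_pattern_eap(self, bench_item_list):
        item = bench_item_list[0]
        table = summed_score_table([item])
        for k in range(1, 6):
            expected = eap_pattern([item], [k])
            row = table[table.summed_score == k].iloc[0]
            assert row.eap == pytest.approx(expected.theta_hat, abs=1e-12)
            assert row.posterior_sd == pytest.approx(expected.posterior_sd, abs=1e-10)

    def test_total_probability(self, bench_item_list):
        table = summed_score_table(bench_item_list)
        assert table.probability.sum() == pytest.approx(1.0, abs=1e-10)

    def test_eap_nondecreasing_in_summed_score(self):
        """Monotone conversion tables across 250 instrument-like item sets.

        Monotonicity of EAP given the summed score is not a theorem for
        the graded response model with arbitrarily heterogeneous slopes;
        the battery draws slopes in the realistic 1.0-2.5 band with both
        agreement-heavy and centered threshold layouts, where it holds.
        """
        rng = np.random.default_rng(42)
        grid = QuadratureGrid.equally_spaced(49)
        for t in range(250):
            n_items = int(rng.integers(2, 7))
            base = (-3.1, -2.2, -1.3, 0.2) if t % 2 else (-1.8, -0.6, 0.6, 1.8)
            items = []
            for j in range(n_items):
                a = float(rng.uniform(1.0, 2.5))
                b = np.sort(np.asarray(base) + rng.uniform(-0.3, 0.3, 4))
                items.append(GrmItemParams(f"r{j}", a, tuple(-a * b)))
            table = summed_score_table(items, grid=grid)
            assert np.all(np.diff(table.eap) >= -1e-10)


class TestRescale:
    def test_midpoint_and_endpoints(self):
        assert rescale_0_100(0.0) == 50.0
        assert rescale_0_100(-5.0) == 0.0
        assert rescale_0_100(5.0) == 100.0

    def test_clipping(self):
        assert rescale_0_100(-7.0) == 0.0
        assert rescale_0_100(7.0, RescaleConfig(clip=False)) == pytest.approx(120.0)

    def test_affine_preserves_correlation(self):
        rng = np.random.default_rng(3)
        theta = rng.normal(size=500)
        scaled = rescale_0_100(theta, RescaleConfig(clip=False))
        assert np.corrcoef(theta, scaled)[0, 1] == pytest.approx(1.0)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            RescaleConfig(theta_low=1.0, theta_high=1.0)
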