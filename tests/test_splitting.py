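import numpy as np
import pytest

import _oracles
from nuclei3d import (
    generate_cluster,
    generate_seeds,
    modified_distance_map,
    split_cluster,
)
from nuclei3d.splitting import SeedSet, Seed, classify_seed, seed_thresholds


class TestModifiedDistanceMap:
    def test_background_zero_everywhere(self):
        mask = _oracles.ball_mask(5)
        dmap = modified_distance_map(mask)
        for arr in (dmap.dist2, dmap.dist3, dmap.dist23):
            assert (arr[~mask] == 0).all()
            assert (arr[mask] > 0).all()

    def test_dist23_definition_and_bound(self):
        mask = _oracles.ball_mask(6)
        dmap = modified_distance_map(mask)
        np.testing.assert_allclose(dmap.dist23, dmap.dist2 + 2 * dmap.dist3)
        assert (dmap.dist23[mask] >= dmap.dist3[mask]).all()

    def test_single_slice_matches_2d_oracle(self, rng):
        mask2d = rng.random((20, 20)) > 0.6
        mask = mask2d[None, :, :]
        dmap = modified_distance_map(mask)
        oracle = _oracles.euclidean_distance_map(mask2d)
        np.testing.assert_allclose(dmap.dist2[0], oracle, atol=1e-9)
        # one-slice volume: 3D distances are capped by the Z boundary
        assert dmap.dist3.max() <= 1.0
        # dist23 is dominated by the in-plane term here
        np.testing.assert_allclose(
            dmap.dist23[0], oracle + 2 * dmap.dist3[0], atol=1e-9
        )

    def test_matches_bruteforce_oracle_3d(self, rng):
        mask = rng.random((14, 14, 14)) > 0.55
        if not mask.any():
            mask[7, 7, 7] = True
        dmap = modified_distance_map(mask)
        np.testing.assert_allclose(
            dmap.dist3, _oracles.euclidean_distance_map(mask), atol=1e-9
        )
        for z in range(mask.shape[0]):
            np.testing.assert_allclose(
                dmap.dist2[z], _oracles.euclidean_distance_map(mask[z]), atol=1e-9
            )

    def test_ball_peaks_at_centre(self):
        mask = _oracles.ball_mask(8, pad=4)
        dmap = modified_distance_map(mask)
        centre = tuple(s // 2 for s in mask.shape)
        assert dmap.dist23[centre] == dmap.dist23.max()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            modified_distance_map(np.zeros((4, 4, 4), dtype=bool))


class TestSchedule:
    def test_max_ten_factor_half(self):
        d = np.zeros((3, 3, 3))
        d[1, 1, 1] = 10.0
        d_max, d_min, schedule = seed_thresholds(d, factor=0.5, step=0.2)
        assert (d_max, d_min) == (10.0, 5.0)
        assert len(schedule) == 26
        assert schedule[0] == pytest.approx(10.0)
        assert schedule[-1] == pytest.approx(5.0)

    def test_max_four_gives_eleven_levels(self):
        d = np.zeros((3, 3, 3))
        d[1, 1, 1] = 4.0
        _, _, schedule = seed_thresholds(d, factor=0.5, step=0.2)
        assert len(schedule) == 11

    def test_factor_point_seven(self):
        d = np.zeros((3, 3, 3))
        d[1, 1, 1] = 10.0
        _, d_min, _ = seed_thresholds(d, factor=0.7)
        assert d_min == pytest.approx(7.0)


class TestClassifySeed:
    def test_empty_previous_is_new(self):
        assert classify_seed((0, 0, 0), 2.0, SeedSet()) is None

    def test_far_apart_is_new(self):
        prev = SeedSet(seeds=[Seed(1, (0.0, 0.0, 0.0), 3.0, 0, (0, 0, 0))])
        # centroids 10 apart, values 2 and 3: 10 >= 5 -> new
        assert classify_seed((0.0, 0.0, 10.0), 2.0, prev) is None

    def test_close_inherits_nearest(self):
        prev = SeedSet(
            seeds=[
                Seed(1, (0.0, 0.0, 0.0), 3.0, 0, (0, 0, 0)),
                Seed(2, (0.0, 0.0, 6.0), 3.0, 0, (0, 0, 6)),
            ]
        )
        # centroids 4 apart from seed 1, values 2 and 3: 4 < 5 -> existing
        assert classify_seed((0.0, 0.0, 4.0), 2.0, prev) == 2  # nearest violator


class TestGenerateSeeds:
    def test_single_ball_one_seed(self):
        dmap = modified_distance_map(_oracles.ball_mask(8))
        seeds = generate_seeds(dmap)
        assert len(seeds) == 1

    def test_two_fused_balls_two_seeds(self):
        mask, _ = generate_cluster([8.0, 8.0], [(0, 0, 0), (0, 0, 12.0)])
        seeds = generate_seeds(modified_distance_map(mask))
        assert len(seeds) == 2

    def test_ten_ball_chain_ten_seeds(self):
        centres = [(0.0, 0.0, 12.0 * i) for i in range(10)]
        mask, _ = generate_cluster([8.0] * 10, centres)
        seeds = generate_seeds(modified_distance_map(mask))
        assert len(seeds) == 10

    def test_anchor_inside_mask(self):
        mask, _ = generate_cluster([8.0, 8.0], [(0, 0, 0), (0, 0, 12.0)])
        seeds = generate_seeds(modified_distance_map(mask))
        for s in seeds.seeds:
            assert mask[s.anchor]


class TestSplitCluster:
    def test_one_seed_identity(self):
        mask = _oracles.ball_mask(6)
        dmap = modified_distance_map(mask)
        out = split_cluster(mask, generate_seeds(dmap), dmap=dmap)
        np.testing.assert_array_equal(out.labels > 0, mask)
        assert out.n_labels == 1

    def test_two_ball_dumbbell_recovery(self):
        mask, truth = generate_cluster([8.0, 8.0], [(0, 0, 0), (0, 0, 12.0)])
        dmap = modified_distance_map(mask)
        out = split_cluster(mask, generate_seeds(dmap), dmap=dmap)
        assert out.n_labels == 2
        for tid in truth.label_ids:
            tmask = truth.labels == tid
            under = out.labels[tmask]
            ids, counts = np.unique(under[under > 0], return_counts=True)
            assert counts.max() / tmask.sum() >= 0.9

    def test_partition_of_mask(self):
        mask, _ = generate_cluster(
            [8.0, 8.0, 8.0], [(0, 0, 0), (0, 0, 12.0), (0, 12.0, 6.0)]
        )
        dmap = modified_distance_map(mask)
        out = split_cluster(mask, generate_seeds(dmap), dmap=dmap)
        # union of labels equals the mask; labels pairwise disjoint by encoding
        np.testing.assert_array_equal(out.labels > 0, mask)

    def test_seed_outside_mask_rejected(self):
        mask = _oracles.ball_mask(5)
        bad = SeedSet(seeds=[Seed(1, (0.0, 0.0, 0.0), 1.0, 0, (0, 0, 0))])
        with pytest.raises(ValueError):
            split_cluster(mask, bad)

    @pytest.mark.parametrize("k", [2, 4, 6, 8, 10])
    def test_k_ball_monolayer_clusters(self, k):
        r = 8.0
        centres = _oracles.monolayer_cluster_centres(k, r, seed=7 * k)
        mask, truth = generate_cluster([r] * k, centres)
        dmap = modified_distance_map(mask)
        seeds = generate_seeds(dmap)
        out = split_cluster(mask, seeds, dmap=dmap)
        assert out.n_labels == k
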