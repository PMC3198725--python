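import numpy as np
import pytest

import synapsedetect as sd
from synapsedetect.classify import ProbabilityMap
from synapsedetect.postprocess import (
    PostprocessConfig,
    candidates_to_balls,
    candidates_to_dataframe,
    candidates_to_label_volume,
    suggested_min_size,
)
from synapsedetect.volume import Volume3D

CONN_OFFSETS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_components(mask, connectivity):
    """Brute-force BFS connected components; independent of scipy labeling."""
    offsets = CONN_OFFSETS[connectivity]
    visited = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        comp = []
        queue = [start]
        visited[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for o in offsets:
                n = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= n[d] < mask.shape[d] for d in range(3)):
                    if mask[n] and not visited[n]:
                        visited[n] = True
                        queue.append(n)
        comps.append(frozenset(comp))
    return comps


def prob_map(arr):
    arr = np.asarray(arr, dtype=np.float32)
    return ProbabilityMap(np.stack([arr, 1 - arr]), ("synapse", "background"))


def no_smooth(**kw):
    kw.setdefault("smoothing_sigma_vox", 0.0)
    kw.setdefault("min_size_vox", 1)
    return PostprocessConfig(**kw)


class TestConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            PostprocessConfig(core_threshold=0.4, relax_threshold=0.5)
        with pytest.raises(ValueError):
            PostprocessConfig(connectivity=4)
        with pytest.raises(ValueError):
            PostprocessConfig(min_size_vox=0)
        with pytest.raises(ValueError):
            PostprocessConfig(min_size_vox=1000, max_size_vox=1000)

    def test_min_size_rescaling(self):
        assert suggested_min_size((9, 5, 5)) == 1000
        assert suggested_min_size((18, 10, 10)) == 125


class TestSmoothProbability:
    def test_constant_preserved(self):
        pm = prob_map(np.full((16, 16, 16), 0.3))
        out = sd.smooth_probability(pm, "synapse", 5.0)
        np.testing.assert_allclose(out.data, 0.3, atol=1e-5)

    def test_impulse_spreads_with_mass_preserved(self):
        arr = np.zeros((48, 48, 48), dtype=np.float32)
        arr[24, 24, 24] = 1.0
        out = sd.smooth_probability(prob_map(arr), "synapse", 5.0)
        assert out.data.max() < 1.0
        assert abs(out.data.sum() - 1.0) < 1e-3

    def test_sigma_zero_is_identity(self):
        arr = np.random.default_rng(0).random((8, 8, 8)).astype(np.float32)
        out = sd.smooth_probability(prob_map(arr), "synapse", 0.0)
        np.testing.assert_array_equal(out.data, arr)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            sd.smooth_probability(prob_map(np.zeros((4, 4, 4))), "mitochondria", 1.0)


class TestExtractCores:
    def test_empty_map(self):
        cores = sd.extract_cores(Volume3D(np.zeros((8, 8, 8))), no_smooth())
        assert cores == []

    def test_size_filter_at_least_semantics(self):
        # a 10x10x10 cluster (1000 vox) survives min_size=1000; 999 does not
        arr = np.zeros((20, 40, 20), dtype=np.float32)
        arr[5:15, 2:12, 5:15] = 0.99  # 1000 voxels
        arr[5:15, 20:30, 5:15] = 0.99
        arr[5, 20, 5] = 0.0  # second cluster: 999 voxels
        cfg = PostprocessConfig(smoothing_sigma_vox=0, core_threshold=0.98, min_size_vox=1000)
        cores = sd.extract_cores(Volume3D(arr), cfg)
        assert len(cores) == 1
        assert len(cores[0]) == 1000
        assert cores[0][:, 1].max() < 15

    def test_strict_threshold(self):
        arr = np.full((6, 6, 6), 0.98, dtype=np.float32)
        cfg = no_smooth(core_threshold=0.98)
        assert sd.extract_cores(Volume3D(arr), cfg) == []  # equal is not greater
        arr2 = np.full((6, 6, 6), 0.981, dtype=np.float32)
        assert len(sd.extract_cores(Volume3D(arr2), cfg)) == 1

    def test_corner_touching_blobs_connectivity(self):
        arr = np.zeros((24, 24, 24), dtype=np.float32)
        arr[2:13, 2:13, 2:13] = 0.99  # 11^3 = 1331 voxels, corner at (12,12,12)
        arr[13:24, 13:24, 13:24] = 0.99  # corner at (13,13,13) — diagonal contact
        cfg26 = no_smooth(core_threshold=0.9, connectivity=26)
        cfg6 = no_smooth(core_threshold=0.9, connectivity=6)
        assert len(sd.extract_cores(Volume3D(arr), cfg26)) == 1
        assert len(sd.extract_cores(Volume3D(arr), cfg6)) == 2

    def test_max_size_filter(self):
        arr = np.zeros((12, 12, 12), dtype=np.float32)
        arr[2:10, 2:10, 2:10] = 0.99
        cfg = no_smooth(core_threshold=0.9, max_size_vox=100)
        assert sd.extract_cores(Volume3D(arr), cfg) == []

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        arr = (rng.random((16, 16, 16)) > 0.7).astype(np.float32) * 0.99
        cfg = no_smooth(core_threshold=0.9, connectivity=connectivity)
        cores = sd.extract_cores(Volume3D(arr), cfg)
        expected = flood_fill_components(arr > 0.9, connectivity)
        got = {frozenset(map(tuple, c)) for c in cores}
        assert got == set(expected)


class TestGrowSegments:
    def core_and_map(self, shell_value):
        arr = np.zeros((16, 16, 16), dtype=np.float32)
        arr[6:10, 6:10, 6:10] = 0.99
        # one-voxel shell around the core
        arr[5:11, 5:11, 5:11] = np.where(arr[5:11, 5:11, 5:11] == 0, shell_value, 0.99)
        cfg = no_smooth(core_threshold=0.9)
        sm = Volume3D(arr)
        cores = sd.extract_cores(sm, cfg)
        assert len(cores) == 1
        return cores, sm, cfg

    def test_shell_below_threshold_excluded(self):
        cores, sm, cfg = self.core_and_map(0.49)
        (cand,) = sd.grow_segments(cores, sm, cfg)
        assert cand.size_vox == 64
        np.testing.assert_array_equal(
            np.sort(cand.segment_voxels, axis=0), np.sort(cand.core_voxels, axis=0)
        )

    def test_shell_at_exactly_half_included(self):
        cores, sm, cfg = self.core_and_map(0.5)
        (cand,) = sd.grow_segments(cores, sm, cfg)
        assert cand.size_vox == 6**3

    def test_transitive_tail_growth(self):
        arr = np.zeros((8, 8, 24), dtype=np.float32)
        arr[2:6, 2:6, 2:6] = 0.99
        arr[3, 3, 6:16] = 0.6  # 10-voxel one-thick tail
        cfg = no_smooth(core_threshold=0.9)
        sm = Volume3D(arr)
        (cand,) = sd.grow_segments(sd.extract_cores(sm, cfg), sm, cfg)
        assert cand.size_vox == 64 + 10
        tail = {(3, 3, x) for x in range(6, 16)}
        assert tail <= set(map(tuple, cand.segment_voxels))

    def test_overlapping_cores_rejected(self):
        arr = np.full((6, 6, 6), 0.99, dtype=np.float32)
        core = np.argwhere(arr > 0)
        with pytest.raises(ValueError, match="disjoint"):
            sd.grow_segments([core, core], Volume3D(arr), no_smooth())

    def test_contested_voxels_go_to_nearest_core(self):
        # two cores joined by a bridge at relax level; bridge voxels split
        # by Euclidean distance to the cores
        arr = np.zeros((5, 5, 21), dtype=np.float32)
        arr[2, 2, 2:5] = 0.99  # core A (id 1)
        arr[2, 2, 16:19] = 0.99  # core B (id 2)
        arr[2, 2, 5:16] = 0.7  # bridge
        cfg = no_smooth(core_threshold=0.9)
        sm = Volume3D(arr)
        cands = sd.grow_segments(sd.extract_cores(sm, cfg), sm, cfg)
        assert len(cands) == 2
        a = set(map(tuple, cands[0].segment_voxels))
        b = set(map(tuple, cands[1].segment_voxels))
        assert a.isdisjoint(b)
        assert a | b == set(map(tuple, np.argwhere(arr >= 0.5)))
        # the midpoint x=10 is equidistant (4->10 is 6; 16->10 is 6): lower id wins
        assert (2, 2, 10) in a
        assert max(x for _, _, x in a) == 10 and min(x for _, _, x in b) == 11

    def test_hysteresis_nesting(self, rng):
        arr = sd.smooth_probability(prob_map(rng.random((20, 20, 20))), "synapse", 2.0).data
        sm = Volume3D(arr)
        t_hi = np.quantile(arr, 0.9)
        segs = {}
        for relax in (0.3, 0.45):
            cfg = PostprocessConfig(
                smoothing_sigma_vox=0, core_threshold=float(t_hi), min_size_vox=1,
                relax_threshold=relax,
            )
            cands = sd.grow_segments(sd.extract_cores(sm, cfg), sm, cfg)
            segs[relax] = set().union(*(set(map(tuple, c.segment_voxels)) for c in cands)) if cands else set()
        assert segs[0.45] <= segs[0.3]


class TestDetect:
    def planted_map(self):
        arr = np.zeros((32, 64, 64), dtype=np.float32)
        for cz, cy, cx in [(10, 15, 15), (15, 40, 40), (20, 15, 45)]:
            arr[cz - 4 : cz + 4, cy - 4 : cy + 4, cx - 4 : cx + 4] = 1.0
        return prob_map(arr)

    def test_all_background_empty(self):
        cands = sd.detect(prob_map(np.zeros((16, 16, 16))), PostprocessConfig())
        assert cands == []

    def test_three_planted_blobs_found(self):
        cfg = PostprocessConfig(smoothing_sigma_vox=2.0, core_threshold=0.5, min_size_vox=100)
        cands = sd.detect(self.planted_map(), cfg)
        assert len(cands) == 3
        assert [c.id for c in cands] == [1, 2, 3]
        assert all(c.size_vox >= c.core_voxels.shape[0] for c in cands)
        sizes = [c.size_vox for c in cands]
        assert sizes == sorted(sizes, reverse=True)

    def test_candidate_count_monotone_in_threshold(self):
        pm = self.planted_map()
        counts = []
        for t in (0.3, 0.6, 0.9, 0.99):
            cfg = PostprocessConfig(
                smoothing_sigma_vox=2.0, core_threshold=t, min_size_vox=50,
                relax_threshold=min(0.5, t),
            )
            counts.append(len(sd.detect(pm, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_candidate_count_monotone_in_min_size(self):
        pm = self.planted_map()
        counts = []
        for ms in (10, 300, 2000):
            cfg = PostprocessConfig(smoothing_sigma_vox=2.0, core_threshold=0.5, min_size_vox=ms)
            counts.append(len(sd.detect(pm, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_core_contained_in_segment(self):
        cfg = PostprocessConfig(smoothing_sigma_vox=2.0, core_threshold=0.5, min_size_vox=100)
        for cand in sd.detect(self.planted_map(), cfg):
            core = set(map(tuple, cand.core_voxels))
            seg = set(map(tuple, cand.segment_voxels))
            assert core <= seg


class TestExports:
    def test_dataframe_and_label_volume(self):
        arr = np.zeros((16, 16, 16), dtype=np.float32)
        arr[4:12, 4:12, 4:12] = 1.0
        cfg = PostprocessConfig(smoothing_sigma_vox=0, core_threshold=0.5, min_size_vox=10)
        cands = sd.detect(prob_map(arr), cfg)
        df = candidates_to_dataframe(cands)
        assert list(df["id"]) == [1]
        assert df.loc[0, "size_vox"] == 512
        lab = candidates_to_label_volume(cands, (16, 16, 16))
        assert (lab.data == 1).sum() == 512
        balls = candidates_to_balls(cands)
        assert len(balls) == 1
        # equivalent-sphere radius of 512 voxels
        assert balls[0].radius_vox == pytest.approx((3 * 512 / (4 * np.pi)) ** (1 / 3))
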