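import numpy as np
import pytest

from zharmon import (
    make_region_atlas,
    partition_central_marginal,
    region_correlation,
    region_correlation_table,
    region_mean_z,
    two_sample_tmap,
)
from zharmon.evaluation import ATLAS_LABELS, _filter_extent
from zharmon.phantoms import SubjectVolume
from zharmon.zscore import ZScoreMap

SHAPE = (16, 16, 16)
VOXEL = (3.5, 3.5, 3.5)


def _vol(counts, sid="s"):
    return SubjectVolume(np.asarray(counts, dtype=float), VOXEL, sid, "cam", True)


def _group(rng, n, mean=50.0, sd=3.0):
    return [_vol(np.clip(mean + rng.normal(0, sd, SHAPE), 0, None), f"s{i}") for i in range(n)]


@pytest.fixture()
def mask16():
    m = np.zeros(SHAPE, dtype=bool)
    m[2:14, 2:14, 2:14] = True
    return m


class TestTwoSampleTMap:
    def test_identical_groups_give_zero_t(self, mask16, rng):
        group = _group(rng, 4)
        dm = two_sample_tmap(group, list(group), mask16, extent_voxels=1)
        np.testing.assert_array_equal(dm.t, 0.0)
        assert not dm.decrease_mask.any() and not dm.increase_mask.any()

    def test_hand_checked_pooled_t(self, mask16):
        """a = {52, 48, 50}, b = {40, 44, 42}: pooled t = 8/sqrt(4*(2/3))."""
        a_vals, b_vals = [52.0, 48.0, 50.0], [40.0, 44.0, 42.0]
        a = [_vol(np.full(SHAPE, v)) for v in a_vals]
        b = [_vol(np.full(SHAPE, v)) for v in b_vals]
        dm = two_sample_tmap(a, b, mask16, extent_voxels=1)
        expected = 8.0 / np.sqrt(4.0 * (1 / 3 + 1 / 3))
        assert dm.df == 4
        idx = tuple(np.argwhere(mask16)[0])
        assert dm.t[idx] == pytest.approx(expected, rel=1e-12)
        assert dm.t[idx] == pytest.approx(4.899, abs=1e-3)
        assert dm.decrease_mask[idx] and not dm.increase_mask[idx]

    def test_matches_scalar_loop_oracle(self, rng):
        """Voxel-wise t equals an independent per-voxel scalar computation on
        an 8^3 fixture."""
        shape = (8, 8, 8)
        mask = np.ones(shape, dtype=bool)
        a = [np.abs(rng.normal(50, 5, shape)) for _ in range(4)]
        b = [np.abs(rng.normal(50, 5, shape)) for _ in range(5)]
        dm = two_sample_tmap(
            [_vol(x) for x in a], [_vol(x) for x in b], mask, extent_voxels=1
        )
        na, nb = len(a), len(b)
        for idx in np.ndindex(shape):
            xa = [x[idx] for x in a]
            xb = [x[idx] for x in b]
            va = sum((v - np.mean(xa)) ** 2 for v in xa) / (na - 1)
            vb = sum((v - np.mean(xb)) ** 2 for v in xb) / (nb - 1)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1 / na + 1 / nb))
            expected = (np.mean(xa) - np.mean(xb)) / se
            assert dm.t[idx] == pytest.approx(expected, rel=1e-10)

    def test_group_too_small_rejected(self, mask16, rng):
        with pytest.raises(ValueError):
            two_sample_tmap(_group(rng, 1), _group(rng, 3), mask16)


class TestExtentFilter:
    def test_small_clusters_removed_never_added(self):
        mask = np.zeros(SHAPE, dtype=bool)
        mask[1:3, 1:3, 1:3] = True  # 8-voxel cluster
        mask[8:12, 8:12, 8:12] = True  # 64-voxel cluster
        out = _filter_extent(mask, 50, 26)
        assert out.sum() == 64
        assert not np.any(out & ~mask)

    def test_surviving_component_not_split(self):
        mask = np.zeros(SHAPE, dtype=bool)
        mask[2:10, 2:10, 2] = True  # one 64-voxel plate
        out = _filter_extent(mask, 50, 26)
        np.testing.assert_array_equal(out, mask)

    def test_connectivity_matters_for_diagonal_touch(self):
        mask = np.zeros(SHAPE, dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        mask[6:10, 6:10, 6:10] = True  # touches only at a corner
        corner = _filter_extent(mask, 100, 26)  # one 128-voxel component
        assert corner.sum() == 128
        faces = _filter_extent(mask, 100, 6)  # two 64-voxel components
        assert faces.sum() == 0


class TestPartition:
    def test_partitions_brain_mask_exactly(self, mask16):
        central, marginal = partition_central_marginal(mask16, voxel_size_mm=VOXEL)
        assert not np.any(central & marginal)
        np.testing.assert_array_equal(central | marginal, mask16)

    def test_spherical_mask_splits_near_half_volume(self):
        g = np.ogrid[0:32, 0:32, 0:32]
        sphere = sum((x - 15.5) ** 2 for x in g) <= 12**2
        central, marginal = partition_central_marginal(sphere, voxel_size_mm=VOXEL)
        frac = central.sum() / sphere.sum()
        assert 0.45 <= frac <= 0.55

    def test_diff_mask_intersection_localizes_findings(self, mask16):
        """A difference confined to the deep brain intersects the central
        part only."""
        central, marginal = partition_central_marginal(mask16, voxel_size_mm=VOXEL)
        deep_diff = central.copy()
        c2, m2 = partition_central_marginal(mask16, deep_diff, voxel_size_mm=VOXEL)
        assert c2.any() and not m2.any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            partition_central_marginal(np.zeros(SHAPE, dtype=bool))


class TestRegionMeanZ:
    def test_constant_region_returns_constant(self, mask16):
        zm = ZScoreMap(np.where(mask16, 1.7, 0.0), mask16)
        assert region_mean_z(zm, mask16) == pytest.approx(1.7)

    def test_three_point_mean(self, mask16):
        z = np.zeros(SHAPE)
        region = np.zeros(SHAPE, dtype=bool)
        pts = np.argwhere(mask16)[:3]
        for p, v in zip(pts, (1.0, 2.0, 3.0)):
            z[tuple(p)] = v
            region[tuple(p)] = True
        assert region_mean_z(ZScoreMap(z, mask16), region) == pytest.approx(2.0)

    def test_empty_region_rejected(self, mask16):
        with pytest.raises(ValueError):
            region_mean_z(ZScoreMap(np.zeros(SHAPE), mask16), np.zeros(SHAPE, dtype=bool))


class TestRegionCorrelation:
    def test_self_correlation_is_one(self, brain32, rng):
        atlas = make_region_atlas(brain32)
        counts = np.where(brain32, rng.random(brain32.shape) + 0.1, 0.0)
        v = SubjectVolume(counts, VOXEL, "s", "c", True)
        series = region_correlation(v, v, atlas)
        assert set(series.index) == {"all", *ATLAS_LABELS}
        for val in series:
            assert val == pytest.approx(1.0, abs=1e-12)

    def test_negation_about_region_mean_gives_minus_one(self, brain32, rng):
        atlas = make_region_atlas(brain32)
        counts = np.where(brain32, rng.random(brain32.shape) + 1.0, 0.0)
        flipped = counts.copy()
        for rid in ATLAS_LABELS.values():
            m = atlas == rid
            flipped[m] = 2 * counts[m].mean() - counts[m]
        a = SubjectVolume(counts, VOXEL, "s", "c", True)
        b = SubjectVolume(np.clip(flipped, 0, None), VOXEL, "s", "c", True)
        series = region_correlation(b, a, atlas, region_ids=list(ATLAS_LABELS.values()))
        for val in series:
            assert val == pytest.approx(-1.0, abs=1e-9)

    def test_matches_scalar_loop_oracle(self, rng):
        """Region Pearson r equals an independent scalar implementation."""
        shape = (8, 8, 8)
        atlas = np.zeros(shape, dtype=np.int16)
        atlas[:4] = 1
        atlas[4:] = 2
        x = rng.random(shape)
        y = rng.random(shape)
        series = region_correlation(
            SubjectVolume(x, VOXEL, "a", "c", True),
            SubjectVolume(y, VOXEL, "b", "c", True),
            atlas,
            region_ids=[1, 2, "all"],
        )
        for rid, name in [(1, "1"), (2, "2")]:
            m = atlas == rid
            xs, ys = x[m], y[m]
            n = xs.size
            sx, sy = xs.sum(), ys.sum()
            sxx = (xs * xs).sum()
            syy = (ys * ys).sum()
            sxy = (xs * ys).sum()
            r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
            assert series[name] == pytest.approx(r, rel=1e-12)

    def test_zero_variance_region_flagged_and_excluded(self, rng):
        shape = (8, 8, 8)
        atlas = np.ones(shape, dtype=np.int16)
        flat = SubjectVolume(np.full(shape, 5.0), VOXEL, "a", "c", True)
        other = SubjectVolume(rng.random(shape), VOXEL, "b", "c", True)
        series = region_correlation(flat, other, atlas, region_ids=[1])
        assert np.isnan(series["1"])
        table = region_correlation_table([(flat, other), (other, other)], atlas, region_ids=[1])
        assert table.loc["mean", "1"] == pytest.approx(1.0)

    def test_tiny_region_rejected(self, rng):
        shape = (8, 8, 8)
        atlas = np.zeros(shape, dtype=np.int16)
        atlas[0, 0, 0] = 1
        v = SubjectVolume(rng.random(shape), VOXEL, "a", "c", True)
        with pytest.raises(ValueError):
            region_correlation(v, v, atlas, region_ids=[1])


class TestAtlas:
    def test_regions_partition_brain_and_are_nonempty(self, brain32):
        atlas = make_region_atlas(brain32)
        np.testing.assert_array_equal(atlas > 0, brain32)
        for name, rid in ATLAS_LABELS.items():
            assert (atlas == rid).sum() >= 3, name
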