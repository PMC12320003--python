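import numpy as np
import pandas as pd
import pytest

from laminapipe import connectome, phantom
from laminapipe.connectome import (
    ConnectivityMatrix,
    connectogram_edges,
    fisher_z,
    group_average,
    hierarchical_matrix,
    seed_map,
    seed_size_scaling,
    seed_timecourse,
)
from laminapipe.images import Image3D, Image4D, ImageKind


@pytest.fixture(scope="module")
def bold(small_atlas):
    _, atlas = small_atlas
    net = pd.DataFrame(
        [
            {"region_a": phantom.CTX_L, "region_b": phantom.CTX_R, "r": 0.6},
            {"region_a": phantom.CTX_L, "region_b": phantom.SUB_L, "r": 0.0},
        ]
    )
    series = phantom.simulate_bold(atlas, net, n_frames=4000, seed=2)
    return series, atlas, net


class TestSeedTimecourse:
    def test_single_voxel_region(self):
        labels = np.zeros((3, 3, 1), dtype=np.int32)
        labels[1, 1, 0] = 5
        atlas = _toy_atlas(labels, [5])
        data = np.arange(3 * 3 * 1 * 4, dtype=float).reshape(3, 3, 1, 4)
        series = Image4D(data, np.eye(4))
        np.testing.assert_array_equal(
            seed_timecourse(series, atlas, 5), data[1, 1, 0]
        )

    def test_two_voxel_mean(self):
        labels = np.zeros((2, 2, 1), dtype=np.int32)
        labels[0, 0, 0] = 5
        labels[1, 1, 0] = 5
        atlas = _toy_atlas(labels, [5])
        data = np.zeros((2, 2, 1, 3))
        data[0, 0, 0] = [1, 2, 3]
        data[1, 1, 0] = [3, 4, 5]
        series = Image4D(data, np.eye(4))
        np.testing.assert_allclose(
            seed_timecourse(series, atlas, 5), [2, 3, 4]
        )

    def test_phantom_region_matches_planted_course(self, bold):
        series, atlas, _ = bold
        tc = seed_timecourse(series, atlas, phantom.CTX_L)
        # reconstruct the planted course: the region voxel-mean equals the
        # course plus averaged-down jitter
        vox = series.data[
            np.isin(atlas.labels.data, atlas.descendants(phantom.CTX_L))
        ]
        np.testing.assert_allclose(tc, vox.mean(axis=0))

    def test_parent_course_is_voxel_mean_not_child_mean(self, bold):
        series, atlas, _ = bold
        parent = seed_timecourse(series, atlas, phantom.CTX)
        vox = np.isin(atlas.labels.data, atlas.descendants(phantom.CTX))
        np.testing.assert_allclose(parent, series.data[vox].mean(axis=0))

    def test_empty_region_errors(self, bold):
        series, atlas, _ = bold
        mask = Image3D(np.zeros(atlas.labels.shape), np.eye(4), ImageKind.mask)
        with pytest.raises(ValueError, match="no voxels"):
            seed_timecourse(series, atlas, phantom.CTX_L, mask=mask)


class TestSeedMap:
    def test_self_correlation_hits_cap(self):
        labels = np.zeros((3, 3, 1), dtype=np.int32)
        labels[0, 0, 0] = 5
        atlas = _toy_atlas(labels, [5])
        rngd = np.random.default_rng(1).normal(size=(3, 3, 1, 50))
        series = Image4D(rngd, np.eye(4))
        sm = seed_map(series, atlas, 5)
        cap = float(np.arctanh(connectome.Z_CAP_R))
        assert sm.zmap.data[0, 0, 0] == pytest.approx(cap)

    def test_z_equals_atanh_r(self):
        # oracle: direct Pearson + series expansion of atanh
        rng = np.random.default_rng(3)
        labels = np.zeros((4, 1, 1), dtype=np.int32)
        labels[0, 0, 0] = 5
        atlas = _toy_atlas(labels, [5])
        data = rng.normal(size=(4, 1, 1, 200))
        series = Image4D(data, np.eye(4))
        sm = seed_map(series, atlas, 5)
        for i in range(1, 4):
            r = np.corrcoef(data[0, 0, 0], data[i, 0, 0])[0, 1]
            assert sm.zmap.data[i, 0, 0] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_planted_correlation_recovered_within_3se(self, bold):
        series, atlas, net = bold
        sm = seed_map(series, atlas, phantom.CTX_L)
        target = np.isin(atlas.labels.data, atlas.descendants(phantom.CTX_R))
        mean_z = sm.zmap.data[target].mean()
        # Fisher sampling-variance oracle with band-limited effective frames
        n_eff = 4000 * 2 * (0.1 - 0.01) * 1.0
        se = 1.0 / np.sqrt(n_eff - 3)
        # voxel-level jitter attenuates the voxel-vs-seed correlation relative
        # to the planted region-level value
        assert abs(mean_z - np.arctanh(0.6)) < 3 * se + 0.08

    def test_zero_variance_voxels_masked(self):
        labels = np.zeros((3, 1, 1), dtype=np.int32)
        labels[0, 0, 0] = 5
        atlas = _toy_atlas(labels, [5])
        data = np.random.default_rng(0).normal(size=(3, 1, 1, 30))
        data[2] = 4.2  # constant voxel
        sm = seed_map(Image4D(data, np.eye(4)), atlas, 5)
        assert not sm.valid_mask[2, 0, 0]
        assert sm.zmap.data[2, 0, 0] == 0.0

    def test_too_few_frames_errors(self, bold):
        _, atlas, _ = bold
        data = np.zeros(atlas.labels.shape + (5,))
        with pytest.raises(ValueError, match="10 frames"):
            seed_map(Image4D(data, np.eye(4)), atlas, phantom.CTX_L)


class TestHierarchicalMatrix:
    def test_consistent_with_seed_primitives(self, bold):
        series, atlas, _ = bold
        mat = hierarchical_matrix(series, atlas, level=2)
        for i, ri in enumerate(mat.region_ids):
            tci = seed_timecourse(series, atlas, ri)
            for j, rj in enumerate(mat.region_ids):
                if i >= j:
                    continue
                tcj = seed_timecourse(series, atlas, rj)
                r = np.corrcoef(tci, tcj)[0, 1]
                assert mat.z[i, j] == pytest.approx(fisher_z(r), abs=1e-12)

    def test_independent_regions_near_zero(self, bold):
        series, atlas, _ = bold
        mat = hierarchical_matrix(series, atlas, level=2)
        idx = {r: i for i, r in enumerate(mat.region_ids)}
        n_eff = 4000 * 2 * 0.09
        se = 1.0 / np.sqrt(n_eff - 3)
        assert abs(mat.z[idx[phantom.CTX_L], idx[phantom.SUB_L]]) < 3 * se

    def test_block_structure(self, bold):
        series, atlas, _ = bold
        mat = hierarchical_matrix(series, atlas, level=2)
        idx = {r: i for i, r in enumerate(mat.region_ids)}
        within = mat.z[idx[phantom.CTX_L], idx[phantom.CTX_R]]
        between = [
            mat.z[idx[phantom.CTX_L], idx[phantom.SUB_L]],
            mat.z[idx[phantom.CTX_R], idx[phantom.SUB_R]],
        ]
        assert within > max(np.abs(between))

    def test_level_with_single_region_errors(self, bold):
        series, atlas, _ = bold
        with pytest.raises(ValueError, match="fewer than 2"):
            hierarchical_matrix(series, atlas, level=9)


class TestConnectogram:
    def test_zero_matrix_empty(self):
        mat = ConnectivityMatrix(np.zeros((3, 3)), [1, 2, 3], 1)
        assert len(connectogram_edges(mat, 0.2)) == 0

    def test_single_suprathreshold_cell(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 0.5
        mat = ConnectivityMatrix(z, [1, 2, 3], 1)
        edges = connectogram_edges(mat, 0.2)
        assert len(edges) == 1
        assert set(edges.loc[0, ["region_a", "region_b"]]) == {1, 2}

    def test_count_matches_brute_force_scan(self, rng):
        z = rng.normal(0, 0.3, (8, 8))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        mat = ConnectivityMatrix(z, list(range(8)), 1)
        edges = connectogram_edges(mat, 0.2)
        brute = sum(
            1 for i in range(8) for j in range(i + 1, 8) if z[i, j] > 0.2
        )
        assert len(edges) == brute
        # sorted by |z| descending
        assert (edges["z"].abs().diff().dropna() <= 1e-12).all()


class TestSeedSizeScaling:
    def test_slopes_match_closed_form_ols(self, bold):
        series, atlas, _ = bold
        ids = [phantom.CTX_L + 1, phantom.CTX_L, phantom.CTX]
        table, fits = seed_size_scaling(series, atlas, ids, threshold=0.1)
        ok = table["n_suprathreshold"] > 0
        lx = np.log10(table.loc[ok, "n_seed_voxels"].astype(float))
        ly = np.log10(table.loc[ok, "n_suprathreshold"].astype(float))
        slope = np.polyfit(lx, ly, 1)[0]
        assert fits["slope_log_count"] == pytest.approx(slope, abs=1e-10)

    def test_single_region_errors(self, bold):
        series, atlas, _ = bold
        with pytest.raises(ValueError, match="3 regions"):
            seed_size_scaling(series, atlas, [phantom.CTX_L])

    def test_seed_voxel_exclusion_flag(self, bold):
        series, atlas, _ = bold
        ids = [phantom.CTX_L + 1, phantom.CTX_L, phantom.CTX]
        t_excl, _ = seed_size_scaling(series, atlas, ids, include_seed_voxels=False)
        t_incl, _ = seed_size_scaling(series, atlas, ids, include_seed_voxels=True)
        assert (
            t_incl["n_suprathreshold"] >= t_excl["n_suprathreshold"]
        ).all()


class TestGroupAverage:
    def _map(self, data):
        from laminapipe.connectome import SeedMap

        return SeedMap(
            zmap=Image3D(data, np.eye(4), ImageKind.anatomical),
            seed_region_id=1, n_seed_voxels=3, threshold=0.2,
        )

    def test_identical_maps_average_unchanged(self, rng):
        d = rng.normal(size=(4, 4, 1))
        avg = group_average([self._map(d)] * 5)
        np.testing.assert_allclose(avg.zmap.data, d)

    def test_map_plus_negation_zero(self, rng):
        d = rng.normal(size=(4, 4, 1))
        avg = group_average([self._map(d), self._map(-d)])
        np.testing.assert_allclose(avg.zmap.data, 0, atol=1e-12)

    def test_sampling_oracle_20_subjects(self, small_atlas):
        _, atlas = small_atlas
        net = pd.DataFrame(
            [{"region_a": phantom.CTX_L, "region_b": phantom.CTX_R, "r": 0.4}]
        )
        maps = []
        for s in range(20):
            series = phantom.simulate_bold(atlas, net, n_frames=600, seed=100 + s)
            maps.append(seed_map(series, atlas, phantom.CTX_L))
        avg = group_average(maps)
        target = np.isin(atlas.labels.data, atlas.descendants(phantom.CTX_R))
        mean_z = avg.zmap.data[target].mean()
        n_eff = 600 * 2 * 0.09
        se = 1.0 / np.sqrt(n_eff - 3) / np.sqrt(20)
        assert abs(mean_z - np.arctanh(0.4)) < 3 * se + 0.05

    def test_grid_mismatch_errors(self, rng):
        a = self._map(rng.normal(size=(4, 4, 1)))
        b = self._map(rng.normal(size=(5, 4, 1)))
        with pytest.raises(ValueError, match="grid"):
            group_average([a, b])


def _toy_atlas(labels, ids):
    from laminapipe.images import AtlasHierarchy

    table = pd.DataFrame(
        {"region_id": ids, "acronym": [str(i) for i in ids], "parent_id": [None] * len(ids)}
    )
    return AtlasHierarchy(Image3D(labels, np.eye(4), ImageKind.label), table)


class TestInvariants:
    def test_fisher_z_monotone(self):
        r = np.linspace(-0.99, 0.99, 41)
        z = fisher_z(r)
        assert (np.diff(z) > 0).all()

    def test_correlation_invariant_to_affine_rescaling(self, bold):
        series, atlas, _ = bold
        sm1 = seed_map(series, atlas, phantom.CTX_L)
        rescaled = Image4D(series.data * 3.7 + 11.0, series.affine, series.tr_s)
        sm2 = seed_map(rescaled, atlas, phantom.CTX_L)
        np.testing.assert_allclose(sm1.zmap.data, sm2.zmap.data, atol=1e-9)
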