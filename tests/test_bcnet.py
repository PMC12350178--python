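import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import threshold_isodata

from hepmorph._errors import DegenerateHistogramError, StageError
from hepmorph.bcnet import (
    BCConfig,
    TwoChannelVolume,
    apical_overlap,
    build_networks,
    complete_lumina,
    diameter_histogram,
    filter_objects,
    isodata_threshold,
    largest_network_features,
    local_thickness,
    median_filter_3d,
    run_bc_pipeline,
    skeletonize_3d,
)
from hepmorph.geometry_io import VolumeSpec
from hepmorph.synthetic import gen_filter_fixture, gen_tube_phantom, random_tube_graph

S26 = np.ones((3, 3, 3), bool)
SPEC = VolumeSpec(voxel_size=0.3)


def ball_mask(shape, center, radius):
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius ** 2


def tube_mask(shape, radius, axis_range=None):
    """Straight tube along z, centered in y/x."""
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    m = (yy - shape[1] // 2) ** 2 + (xx - shape[2] // 2) ** 2 <= radius ** 2
    if axis_range is not None:
        m &= (zz >= axis_range[0]) & (zz < axis_range[1])
    return m


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 8), 7, np.uint16)
        assert np.array_equal(median_filter_3d(vol, 1), vol)

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.integers(0, 100, (6, 6, 6))
        assert np.array_equal(median_filter_3d(vol, 0), vol)

    def test_salt_voxel_removed(self):
        vol = np.zeros((7, 7, 7), np.uint16)
        vol[3, 3, 3] = 1000
        assert median_filter_3d(vol, 1)[3, 3, 3] == 0

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(1)
        vol = rng.integers(0, 255, (9, 9, 9)).astype(np.uint8)
        out = median_filter_3d(vol, 1)
        for z in range(2, 7):  # interior crop, no edge handling needed
            for y in range(2, 7):
                for x in range(2, 7):
                    win = vol[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2]
                    assert out[z, y, x] == np.median(win)


class TestIsodataThreshold:
    def test_two_value_volume_splits_at_midpoint(self):
        vol = np.array([10] * 500 + [20] * 500, np.uint16).reshape(10, 10, 10)
        t, mask = isodata_threshold(vol)
        assert t == pytest.approx(15.0)
        assert mask.sum() == 500 and (vol[mask] == 20).all()

    def test_bimodal_phantom_recovers_bright_class(self):
        rng = np.random.default_rng(2)
        truth = rng.random((20, 20, 20)) < 0.5
        vol = np.where(truth, 120.0, 30.0) + rng.normal(0, 5, truth.shape)
        t, mask = isodata_threshold(np.clip(vol, 0, 255).astype(np.uint8))
        assert 45 < t < 105
        assert (mask & truth).sum() / truth.sum() > 0.99

    def test_binary_volume_passthrough(self):
        vol = np.array([0, 255] * 500, np.uint8).reshape(10, 10, 10)
        _, mask = isodata_threshold(vol)
        assert np.array_equal(mask, vol > 0)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            isodata_threshold(np.full((5, 5, 5), 9, np.uint16))

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(3)
        vol = np.concatenate([rng.normal(40, 8, 4000), rng.normal(160, 12, 2000)])
        vol = np.clip(vol, 0, 255).astype(np.uint8).reshape(20, 20, 15)
        t, _ = isodata_threshold(vol)
        assert abs(t - threshold_isodata(vol)) <= 2.0


class TestOverlap:
    def test_disjoint_and_identical(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert not apical_overlap(a, b).any()
        assert np.array_equal(apical_overlap(a, a), a)

    def test_shell_against_shell_plus_sheets_is_shell(self):
        shape = (30, 24, 24)
        shell = tube_mask(shape, 5) & ~tube_mask(shape, 3)
        sheets = np.zeros(shape, bool)
        sheets[:, 2:4, :] = True
        cortical = shell | sheets
        assert np.array_equal(apical_overlap(shell, cortical), shell)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apical_overlap(np.zeros((3, 3, 3), bool), np.zeros((4, 3, 3), bool))


class TestCompleteLumina:
    def test_hollow_shell_becomes_solid_ball(self):
        zz, yy, xx = np.meshgrid(*(np.arange(20),) * 3, indexing="ij")
        d = np.sqrt((zz - 9.5) ** 2 + (yy - 9.5) ** 2 + (xx - 9.5) ** 2)
        shell = (d >= 4.5) & (d <= 5.5)
        out = complete_lumina(shell, BCConfig(k_in=2, k_out=2))
        oracle = d <= 5.5  # solid ball by distance threshold
        assert abs(int(out.sum()) - int(oracle.sum())) / oracle.sum() < 0.05

    def test_solid_ball_unchanged_within_surface_layer(self):
        solid = ball_mask((20, 20, 20), (10, 10, 10), 6)
        out = complete_lumina(solid, BCConfig(k_in=2, k_out=2))
        surface = int((solid & ~ndimage.binary_erosion(solid)).sum())
        assert abs(int(out.sum()) - int(solid.sum())) <= surface
        assert (out | solid).sum() == out.sum()  # extensive: output contains input

    def test_pure_fill_holes_leaves_open_tube_hollow(self):
        shape = (30, 20, 20)
        shell = tube_mask(shape, 6) & ~tube_mask(shape, 4)
        out = complete_lumina(shell, BCConfig(k_in=0, k_out=0))
        assert np.array_equal(out, shell)  # open ends: no enclosed cavity


class TestFilterObjects:
    def test_fixture_bookkeeping(self):
        mask = gen_filter_fixture()
        out, report = filter_objects(mask, BCConfig(min_size=500, border_policy="all"))
        assert ndimage.label(out, structure=S26)[1] == 2
        assert report == {"size": 2, "border": 1}

    def test_empty_mask(self):
        out, report = filter_objects(np.zeros((5, 5, 5), bool))
        assert not out.any() and report == {"size": 0, "border": 0}

    def test_no_filtering_is_identity(self):
        mask = gen_filter_fixture()
        out, report = filter_objects(mask, BCConfig(min_size=0, border_policy="none"))
        assert np.array_equal(out, mask)
        assert report == {"size": 0, "border": 0}

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(5)
        mask = ndimage.binary_dilation(rng.random((20, 20, 20)) < 0.02)
        out, _ = filter_objects(mask, BCConfig(min_size=10))
        assert not (out & ~mask).any()


class TestLocalThickness:
    def test_solid_ball_center(self):
        th = local_thickness(ball_mask((17, 17, 17), (8, 8, 8), 6), SPEC)
        assert th[8, 8, 8] == pytest.approx(3.6, abs=0.3)

    def test_cylinder_axis_constant(self):
        th = local_thickness(tube_mask((60, 17, 17), 4), SPEC)
        axis = th[20:40, 8, 8]
        assert np.allclose(axis, axis[0])
        assert axis[0] == pytest.approx(2.4, abs=0.3)

    def test_single_voxel_measures_its_inscribed_sphere(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        th = local_thickness(m, SPEC)
        # distance-ridge convention: radius = distance to nearest background
        # voxel center, so a lone voxel reads 2 voxel diameters
        assert th[4, 4, 4] == pytest.approx(2 * SPEC.voxel_size)
        assert th[m].size == 1 and not th[~m].any()


class TestSkeletonize:
    def test_straight_tube_gives_single_curve(self):
        vol = tube_mask((100, 16, 16), 3, axis_range=(5, 95))
        sk = skeletonize_3d(vol)
        assert ndimage.label(sk, structure=S26)[1] == 1
        assert abs(int(sk.sum()) - 90) <= 9
        assert not (sk & ~vol).any()

    def test_solid_ball_collapses_to_small_cluster(self):
        sk = skeletonize_3d(ball_mask((17, 17, 17), (8, 8, 8), 6))
        assert 0 < sk.sum() <= 27

    def test_empty_input(self):
        assert not skeletonize_3d(np.zeros((5, 5, 5), bool)).any()

    def test_component_count_preserved_on_random_blobs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seeds = rng.random((24, 24, 24)) < 0.004
            blobs = ndimage.binary_dilation(seeds, iterations=2)
            n_in = ndimage.label(blobs, structure=S26)[1]
            n_out = ndimage.label(skeletonize_3d(blobs), structure=S26)[1]
            assert n_in == n_out


def _y_phantom():
    """Three straight arms meeting at one voxel (a triple point)."""
    m = np.zeros((40, 40, 40), bool)
    c = np.array([20, 20, 20])
    for d in [(1, 0, 0), (-1, 1, 0), (-1, -1, 0)]:
        d = np.asarray(d, float)
        d /= np.linalg.norm(d)
        for s in range(15):
            z, y, x = np.round(c + s * d).astype(int)
            m[max(z - 1, 0):z + 2, max(y - 1, 0):y + 2, max(x - 1, 0):x + 2] = True
    return m


def _x_phantom():
    m = np.zeros((40, 40, 40), bool)
    c = np.array([20, 20, 20])
    for d in [(1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0)]:
        d = np.asarray(d, float)
        d /= np.linalg.norm(d)
        for s in range(16):
            z, y, x = np.round(c + s * d).astype(int)
            m[max(z - 1, 0):z + 2, max(y - 1, 0):y + 2, max(x - 1, 0):x + 2] = True
    return m


class TestBuildNetworks:
    def test_y_phantom_one_triple_junction(self):
        nets = build_networks(skeletonize_3d(_y_phantom()), SPEC)
        assert len(nets) == 1
        net = nets[0]
        assert net.n_branches == 3
        assert net.triple_junctions == 1
        assert net.quadruple_junctions == 0

    def test_x_phantom_one_quadruple_after_merging(self):
        nets = build_networks(skeletonize_3d(_x_phantom()), SPEC)
        assert len(nets) == 1
        net = nets[0]
        assert net.quadruple_junctions == 1
        assert net.triple_junctions == 0
        assert net.n_branches == 4

    def test_two_disjoint_tubes_two_networks(self):
        m = np.zeros((50, 30, 30), bool)
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in m.shape), indexing="ij")
        on_axis = (zz >= 5) & (zz < 45)
        m |= (((yy - 8) ** 2 + (xx - 15) ** 2 <= 4) & on_axis)
        m |= (((yy - 22) ** 2 + (xx - 15) ** 2 <= 4) & on_axis)
        nets = build_networks(skeletonize_3d(m), SPEC)
        assert len(nets) == 2
        assert all(n.total_junctions == 0 for n in nets)


class TestLargestNetworkFeatures:
    def test_selects_longest(self):
        m = np.zeros((60, 40, 20), bool)
        long_tube = tube_mask((60, 20, 20), 2, (3, 57))
        short_tube = tube_mask((60, 20, 20), 2, (20, 40))
        m[:, :20, :] = long_tube
        m[:, 20:, :] = short_tube
        nets = build_networks(skeletonize_3d(m), SPEC)
        feats = largest_network_features(nets)
        assert feats.n_networks == 2
        assert feats.total_length_um == max(n.total_length_um for n in nets)

    def test_grid_more_interconnected_than_chain(self):
        """A network with more junctions is more interconnected: a ladder
        layout beats a plain chain of the same total length."""
        grid_m = np.zeros((48, 48, 24), bool)
        for z in (12, 30):  # two rails
            grid_m[z - 1:z + 2, 6:42, 10:13] = True
        for y in (12, 30):  # two rungs
            grid_m[12:31, y - 1:y + 2, 10:13] = True
        chain_m = np.zeros((48, 48, 24), bool)
        chain_m[4:44, 10:13, 10:13] = True
        g = largest_network_features(build_networks(skeletonize_3d(grid_m), SPEC))
        c = largest_network_features(build_networks(skeletonize_3d(chain_m), SPEC))
        assert g.total_junctions > c.total_junctions

    def test_empty_network_list_flagged(self):
        feats = largest_network_features([])
        assert feats.empty and feats.total_length_um == 0


class TestDiameterHistogram:
    def test_hand_enumerated_example(self):
        edges, pct = diameter_histogram([1.0, 1.1, 1.6, 2.0])
        assert pct.sum() == pytest.approx(100.0)
        bins = {round(edges[i], 2): pct[i] for i in range(len(pct))}
        assert bins[1.00] == pytest.approx(50.0)
        assert bins[1.50] == pytest.approx(25.0)
        assert bins[2.00] == pytest.approx(25.0)
        assert bins.get(1.25, 0.0) == 0.0

    def test_single_value_single_bin(self):
        _, pct = diameter_histogram([0.8, 0.8, 0.8])
        assert (pct == [0, 0, 0, 100.0]).all()

    def test_edge_value_falls_in_upper_bin(self):
        edges, pct = diameter_histogram([1.25])
        assert edges[np.argmax(pct)] == pytest.approx(1.25)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            diameter_histogram([])
        with pytest.raises(ValueError):
            diameter_histogram([1.0, -0.5])


class TestPipeline:
    def test_phantom_recovery_with_noise(self):
        gt = random_tube_graph(n_edges=10, seed=21)
        vol = gen_tube_phantom(gt, snr=5.0, seed=21)
        feats, row, inter = run_bc_pipeline(vol)
        assert feats.triple_junctions == gt.triple_junctions
        assert feats.quadruple_junctions == gt.quadruple_junctions
        err = abs(feats.total_length_um - gt.total_length_um) / gt.total_length_um
        assert err < 0.10
        assert row["largest_network_length_um"] == feats.total_length_um
        assert set(inter) >= {"overlap", "completed", "filtered", "skeleton"}

    def test_noise_free_phantom_recovery(self):
        gt = random_tube_graph(n_edges=10, seed=22)
        vol = gen_tube_phantom(gt, snr=1e6, seed=22)
        feats, _, _ = run_bc_pipeline(vol)
        assert feats.triple_junctions == gt.triple_junctions
        assert feats.quadruple_junctions == gt.quadruple_junctions
        err = abs(feats.total_length_um - gt.total_length_um) / gt.total_length_um
        assert err < 0.10

    def test_blank_volume_aborts_at_threshold_stage(self):
        blank = TwoChannelVolume(
            apical=np.zeros((10, 10, 10), np.uint16),
            cortical=np.zeros((10, 10, 10), np.uint16),
            spec=SPEC,
        )
        with pytest.raises(StageError, match="threshold"):
            run_bc_pipeline(blank)
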