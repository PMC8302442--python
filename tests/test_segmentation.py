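"""Object creation: masks, linking, spots, contact surfaces."""

import itertools

import numpy as np
import pytest

from synapse4d import ImagingParams
from synapse4d.movie import Movie
from synapse4d.render import CTL_RADIUS_UM
from synapse4d.segmentation import (LabelVolume, detect_spots,
                                    extract_synapse_surface, link_labels,
                                    segment_cells)

VOX = (1.0, 0.5, 0.5)  # (z, y, x) um


def _movie(stacks, voxel_xyz=(0.5, 0.5, 1.0), interval=10.0,
           channels=("actin",)):
    data = np.asarray(stacks, dtype=np.float32)
    if data.ndim == 4:               # (T, Z, Y, X) single channel
        data = data[:, None]
    params = ImagingParams(voxel_size_xyz=voxel_xyz, frame_interval=interval,
                           n_frames=data.shape[0],
                           volume_shape=data.shape[2:],
                           channel_names=channels[:data.shape[1]])
    return Movie(data, params)


def _ball(shape, center, radius, voxel=VOX):
    zz, yy, xx = np.indices(shape).astype(float)
    zz *= voxel[0]
    yy *= voxel[1]
    xx *= voxel[2]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius ** 2


class TestSegmentCells:
    def test_recovers_sphere_volume_within_15pct(self):
        mask = _ball((16, 40, 40), (8.0, 10.0, 10.0), 4.0)
        img = 100.0 * mask + 5.0
        mv = _movie([img])
        labels = segment_cells(mv, "actin")
        vol = (labels.labels[0] > 0).sum() * np.prod(VOX)
        true = 4.0 / 3.0 * np.pi * 4.0 ** 3
        assert vol == pytest.approx(true, rel=0.15)

    def test_blank_volume_gives_no_labels(self, caplog):
        mv = _movie([np.zeros((8, 20, 20))])
        with caplog.at_level("WARNING"):
            labels = segment_cells(mv, "actin")
        assert labels.labels.max() == 0
        assert any("no objects" in r.message for r in caplog.records)

    def test_two_separated_cells_two_labels(self):
        m = (_ball((16, 60, 60), (8, 7, 7), 3.0)
             | _ball((16, 60, 60), (8, 22, 22), 3.0))
        labels = segment_cells(_movie([100.0 * m]), "actin")
        assert len(np.unique(labels.labels[0])) - 1 == 2

    @pytest.mark.parametrize("scale", [0.1, 1.0, 250.0])
    def test_otsu_masks_scale_invariant(self, scale):
        m = _ball((12, 30, 30), (6, 7.5, 7.5), 3.0)
        base = segment_cells(_movie([80.0 * m]), "actin")
        scaled = segment_cells(_movie([80.0 * scale * m]), "actin")
        assert np.array_equal(base.labels, scaled.labels)

    def test_small_objects_removed(self):
        m = _ball((16, 40, 40), (8, 10, 10), 4.0)
        m |= _ball((16, 40, 40), (8, 17, 3), 0.9)   # ~3 um^3 debris
        labels = segment_cells(_movie([100.0 * m]), "actin",
                               min_volume_um3=30.0)
        assert len(np.unique(labels.labels[0])) - 1 == 1


class TestLinkLabels:
    def _volume(self, centers_per_frame, shape=(10, 40, 40)):
        frames = []
        for centers in centers_per_frame:
            lab = np.zeros(shape, dtype=np.uint16)
            for i, c in enumerate(centers, start=1):
                lab[_ball(shape, c, 2.0)] = i
            frames.append(lab)
        return LabelVolume(np.stack(frames), VOX, 10.0)

    def test_static_object_single_identity(self):
        lv = self._volume([[(5.0, 10.0, 10.0)]] * 10)
        linked = link_labels(lv)
        ids = {int(i) for f in range(10)
               for i in np.unique(linked.labels[f]) if i}
        assert ids == {1}

    def test_slow_motion_keeps_identity(self):
        centers = [[(5.0, 10.0, 5.0 + f * 1.0)] for f in range(8)]
        linked = link_labels(self._volume(centers))
        ids = {int(i) for f in range(8)
               for i in np.unique(linked.labels[f]) if i}
        assert ids == {1}

    def test_gate_blocks_long_jumps(self):
        # object disappears and a far one appears: new identity
        centers = [[(5.0, 8.0, 8.0)], [(5.0, 8.0, 16.0)]]
        linked = link_labels(self._volume(centers), max_displacement_um=5.0)
        assert int(linked.labels[1].max()) == 2

    def test_greedy_matches_bruteforce_assignment(self):
        # two objects drift; greedy nearest-centroid must match the optimal
        # assignment because a swap would exceed the per-pair distances
        f0 = [(5.0, 8.0, 8.0), (5.0, 8.0, 14.0)]
        f1 = [(5.0, 9.0, 8.5), (5.0, 7.5, 13.0)]
        lv = self._volume([f0, f1])
        linked = link_labels(lv)
        c0 = linked.centroids_um(0)
        c1 = linked.centroids_um(1)
        # brute-force optimal assignment on true centres
        best = min(itertools.permutations(range(2)),
                   key=lambda p: sum(np.linalg.norm(np.subtract(f1[p[i]],
                                                                f0[i]))
                                     for i in range(2)))
        for i in range(2):
            d = np.linalg.norm(c1[i + 1] - np.asarray(f1[best[i]]))
            assert d < 1.0


class TestDetectSpots:
    def _spot_movie(self, centers, shape=(12, 40, 40), amp=50.0):
        zz, yy, xx = np.indices(shape).astype(float)
        zz *= VOX[0]
        yy *= VOX[1]
        xx *= VOX[2]
        img = np.zeros(shape)
        for c in centers:
            img += amp * np.exp(-(((zz - c[0]) / 0.8) ** 2
                                  + ((yy - c[1]) / 0.4) ** 2
                                  + ((xx - c[2]) / 0.4) ** 2) / 2)
        return _movie([img], channels=("granule",))

    def test_single_spot_recovered_within_one_voxel(self):
        c = (6.0, 10.25, 9.75)
        spots = detect_spots(self._spot_movie([c]), "granule", 0.4)
        pos = spots.positions_um(0)
        assert len(pos) == 1
        assert np.all(np.abs(pos[0] - c) <= np.asarray(VOX))

    def test_blank_channel_empty(self):
        mv = _movie([np.zeros((12, 40, 40))], channels=("granule",))
        assert detect_spots(mv, "granule", 0.4).positions_um(0).shape[0] == 0

    def test_two_separated_spots_detected(self):
        centers = [(6.0, 10.0, 8.0), (6.0, 10.0, 12.0)]   # 4 um apart
        spots = detect_spots(self._spot_movie(centers), "granule", 0.4)
        assert len(spots.positions_um(0)) == 2

    def test_invalid_radius_raises(self):
        with pytest.raises(ValueError):
            detect_spots(self._spot_movie([(6, 10, 10)]), "granule", 0.0)

    def test_centrosome_keeps_brightest_per_cell(self):
        mv = self._spot_movie([(6.0, 10.0, 8.0)], amp=50.0)
        mv.data[0, 0] += self._spot_movie([(6.0, 10.0, 13.0)],
                                          amp=20.0).data[0, 0]
        lab = np.ones((1, 12, 40, 40), dtype=np.uint16)
        labels = LabelVolume(lab, VOX, 10.0)
        spots = detect_spots(mv, "granule", 0.4, labels=labels,
                             kind="centrosome")
        pos = spots.positions_um(0)
        assert len(pos) == 1
        assert abs(pos[0][2] - 8.0) < 0.6


class TestSynapseSurface:
    def test_abutting_half_spaces_share_face(self):
        a = np.zeros((6, 6, 10), dtype=bool)
        b = np.zeros((6, 6, 10), dtype=bool)
        a[:, :, :5] = True
        b[:, :, 5:] = True
        surf = extract_synapse_surface(a, b, VOX)
        assert not surf.is_empty
        assert set(surf.voxels[:, 2]) == {4}
        assert len(surf.voxels) == 36

    def test_separated_masks_give_empty_surface(self):
        a = np.zeros((6, 6, 10), dtype=bool)
        b = np.zeros((6, 6, 10), dtype=bool)
        a[:, :, :4] = True
        b[:, :, 6:] = True
        assert extract_synapse_surface(a, b, VOX).is_empty

    def test_contact_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.random((5, 8, 8)) > 0.6
            b = rng.random((5, 8, 8)) > 0.6
            b &= ~a
            ab = extract_synapse_surface(a, b, VOX).is_empty
            ba = extract_synapse_surface(b, a, VOX).is_empty
            assert ab == ba

    def test_cap_area_grows_with_overlap_depth(self):
        shape = (20, 30, 30)
        plane = np.zeros(shape, dtype=bool)
        plane[:, :, 20:] = True
        areas = []
        for depth in (0.5, 1.5, 2.5):
            center_x = 20 * VOX[2] - 4.0 + depth
            sphere = _ball(shape, (10 * VOX[0], 15 * VOX[1], center_x), 4.0)
            sphere &= ~plane
            surf = extract_synapse_surface(sphere, plane, VOX)
            areas.append(len(surf.voxels))
        assert areas[0] < areas[1] < areas[2]
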