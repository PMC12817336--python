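"""Segmentation-chain operations against brute-force pixel oracles."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from ptcrescue.imaging_proximity import (
    ChannelImage,
    ProximityConfig,
    adaptive_filter,
    disk_footprint,
    intensity_per_cell,
    label_objects,
    nearest_distances,
    normalize_contrast,
    phansalkar_threshold,
    rolling_ball_background,
    segment_channel,
    watershed_split,
)


def img(pixels, px=0.1):
    return ChannelImage(np.asarray(pixels, dtype=np.float64), px)


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - cy, xx - cx) <= r


class TestNormalizeContrast:
    def test_full_range_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.random((64, 64))
        x[0, 0], x[1, 1] = 0.0, 1.0
        out = normalize_contrast(img(x)).pixels
        np.testing.assert_allclose(out, x, atol=0.02)

    def test_constant_image_warns_and_passes_through(self):
        x = np.full((16, 16), 3.0)
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_contrast(img(x))
        np.testing.assert_array_equal(out.pixels, x)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.random((32, 32))
        a = normalize_contrast(img(x)).pixels
        b = normalize_contrast(img(5.0 * x + 11.0)).pixels
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_monotone(self):
        rng = np.random.default_rng(2)
        x = rng.random((32, 32))
        out = normalize_contrast(img(x)).pixels
        order_in = np.argsort(x.ravel())
        assert (np.diff(out.ravel()[order_in]) >= -1e-12).all()


class TestRollingBall:
    def test_constant_to_zero(self):
        out = rolling_ball_background(img(np.full((64, 64), 7.0)), radius_px=10)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.random((64, 64))
        a = rolling_ball_background(img(x), radius_px=10).pixels
        b = rolling_ball_background(img(x + 5.0), radius_px=10).pixels
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_small_feature_preserved_vs_bruteforce_opening(self):
        """Exact path equals brute-force disc opening; punctum survives."""
        x = np.zeros((48, 48))
        x[20:23, 20:23] = 100.0
        radius = 10
        out = rolling_ball_background(img(x), radius_px=radius).pixels
        # brute-force opening: sliding min then sliding max over the disc
        fp = disk_footprint(radius)
        off = np.argwhere(fp) - radius
        pad = np.pad(x, radius, mode="reflect")

        def sweep(a, fn):
            res = np.empty_like(x)
            for i in range(x.shape[0]):
                for j in range(x.shape[1]):
                    vals = [a[i + radius + dy, j + radius + dx] for dy, dx in off]
                    res[i, j] = fn(vals)
            return res

        eroded = sweep(pad, min)
        opened = sweep(np.pad(eroded, radius, mode="reflect"), max)
        np.testing.assert_allclose(out, x - opened, atol=1e-9)
        assert out[20:23, 20:23].min() > 90.0  # punctum preserved

    def test_large_radius_flat_background_warning(self):
        with pytest.warns(UserWarning, match="radius exceeds"):
            out = rolling_ball_background(img(np.ones((8, 8))), radius_px=50)
        assert (out.pixels >= 0).all()

    def test_gradient_removed_downsampled_path(self):
        # interior of the field: a flat disc opening follows a linear ramp
        # exactly; border effects are confined to roughly one radius
        grad = np.tile(np.linspace(0, 30, 256), (256, 1))
        out = rolling_ball_background(img(grad), radius_px=50).pixels
        assert out[:, 60:-60].max() < 0.5


class TestPhansalkar:
    @staticmethod
    def oracle(pixels, radius, k=0.25, r=0.5, p=2.0, q=10.0):
        """Direct per-pixel evaluation of the published formula."""
        fp = disk_footprint(radius)
        off = np.argwhere(fp) - radius
        pad = np.pad(pixels, radius, mode="reflect")
        t = np.empty_like(pixels)
        for i in range(pixels.shape[0]):
            for j in range(pixels.shape[1]):
                vals = np.array([pad[i + radius + dy, j + radius + dx] for dy, dx in off])
                m, s = vals.mean(), vals.std()
                t[i, j] = m * (1.0 + p * np.exp(-q * m) + k * ((s / r) - 1.0))
        return pixels > t, t

    def test_pixelwise_oracle_32x32(self):
        rng = np.random.default_rng(4)
        x = np.clip(rng.normal(0.08, 0.03, (32, 32)), 0, 1)
        x[10:16, 10:16] = 0.9  # bright block
        mask = phansalkar_threshold(img(x), radius_px=5)
        oracle_mask, t = self.oracle(x, 5)
        margin = np.abs(x - t) > 1e-7  # ignore knife-edge ties
        np.testing.assert_array_equal(mask[margin], oracle_mask[margin])
        assert margin.mean() > 0.99

    def test_bright_disc_on_dark_background(self):
        x = np.full((32, 32), 0.05)
        x += np.random.default_rng(5).normal(0, 0.01, x.shape)
        x = np.clip(x, 0, 1)
        d = disc_mask(x.shape, 16, 16, 6)
        x[d] = 1.0
        mask = phansalkar_threshold(img(x), radius_px=15)
        inner = disc_mask(x.shape, 16, 16, 4)
        assert mask[inner].all()

    def test_constant_image_all_background(self):
        x = np.full((16, 16), 0.1)
        mask = phansalkar_threshold(img(x), radius_px=3)
        assert not mask.any()

    def test_radius_validated(self):
        with pytest.raises(ValueError):
            phansalkar_threshold(img(np.ones((4, 4))), radius_px=0)


class TestAdaptiveFilter:
    def test_isolated_pixel_removed(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert not adaptive_filter(m).any()

    def test_solid_square_unchanged(self):
        m = np.zeros((11, 11), bool)
        m[3:8, 3:8] = True
        np.testing.assert_array_equal(adaptive_filter(m), m)

    def test_matches_bruteforce_median_on_random_masks(self):
        rng = np.random.default_rng(6)
        fp = disk_footprint(1)
        off = np.argwhere(fp) - 1
        for _ in range(5):
            m = rng.random((16, 16)) < 0.4
            out = adaptive_filter(m)
            # scipy's "reflect" boundary equals numpy's "symmetric" padding
            pad = np.pad(m, 1, mode="symmetric")
            expect = np.empty_like(m)
            for i in range(16):
                for j in range(16):
                    vals = [pad[i + 1 + dy, j + 1 + dx] for dy, dx in off]
                    expect[i, j] = np.median(vals) > 0.5
            np.testing.assert_array_equal(out, expect)


class TestWatershed:
    def test_two_separated_discs(self):
        m = disc_mask((64, 64), 16, 16, 8) | disc_mask((64, 64), 45, 45, 8)
        lm = watershed_split(m)
        assert lm.n_objects == 2
        assert (lm.labels[m] > 0).all()

    def test_fused_discs_split_by_erosion_markers(self):
        m = disc_mask((64, 64), 32, 20, 9) | disc_mask((64, 64), 32, 44, 9)
        m[30:35, 20:45] = True  # thin fusing neck
        assert ndi.label(m)[1] == 1
        lm = watershed_split(m, erosion_cycles=5)
        assert lm.n_objects == 2
        assert (lm.labels[m] > 0).all()

    def test_small_disc_rescued_not_lost(self):
        m = disc_mask((32, 32), 16, 16, 3)  # erodes away within 5 cycles
        assert not ndi.binary_erosion(m, iterations=5).any()
        lm = watershed_split(m, erosion_cycles=5)
        assert lm.n_objects == 1
        assert (lm.labels[m] > 0).all()

    def test_empty_mask(self):
        lm = watershed_split(np.zeros((8, 8), bool))
        assert lm.n_objects == 0

    def test_determinism(self):
        rng = np.random.default_rng(7)
        m = rng.random((64, 64)) < 0.3
        a = watershed_split(m).labels
        b = watershed_split(m).labels
        np.testing.assert_array_equal(a, b)


class TestLabelObjects:
    def test_single_pixel_object(self):
        lab = np.zeros((8, 8), np.int32)
        lab[3, 5] = 1
        from ptcrescue.imaging_proximity import LabelMap

        ot = label_objects(LabelMap(lab), img(np.ones((8, 8))), min_area_px=1)
        assert len(ot) == 1
        assert ot.table.iloc[0]["y_px"] == 3.0 and ot.table.iloc[0]["x_px"] == 5.0

    def test_disc_centroid_geometry(self):
        from ptcrescue.imaging_proximity import LabelMap

        m = disc_mask((40, 40), 20, 20, 5)
        ot = label_objects(LabelMap(m.astype(np.int32)), img(np.ones((40, 40))), 1)
        assert ot.table.iloc[0]["y_px"] == pytest.approx(20.0, abs=0.1)
        assert ot.table.iloc[0]["x_px"] == pytest.approx(20.0, abs=0.1)

    def test_min_area_drops_planted_speckles(self):
        from ptcrescue.imaging_proximity import LabelMap

        lab = np.zeros((32, 32), np.int32)
        lab[2, 2] = 1  # speckle
        lab[10:14, 10:14] = 2  # real object (16 px)
        lab[20, 20:22] = 3  # speckle (2 px)
        ot = label_objects(LabelMap(lab), img(np.ones((32, 32))), min_area_px=4)
        assert len(ot) == 1 and ot.n_dropped_small == 2


def brute_force_nearest(src_labels, tgt_labels, px):
    """Independent O(n^2) oracle: pixel sets, 4-neighbor boundaries."""
    def objects(lab):
        out = {}
        for lbl in np.unique(lab):
            if lbl == 0:
                continue
            coords = np.argwhere(lab == lbl)
            pix = {tuple(c) for c in coords}
            boundary = [
                c for c in coords
                if any(
                    (c[0] + dy, c[1] + dx) not in pix
                    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
                )
            ]
            out[int(lbl)] = (coords.mean(axis=0), pix, np.array(boundary))
        return out

    S, T = objects(src_labels), objects(tgt_labels)
    rows = {}
    for sl, (sc, spix, sbound) in S.items():
        best = None
        for tl in sorted(T):
            tc, tpix, tbound = T[tl]
            if spix & tpix:
                e = 0.0
            else:
                e = min(
                    np.hypot(a[0] - b[0], a[1] - b[1]) for a in sbound for b in tbound
                )
            if best is None or e < best[0] - 1e-12:
                best = (e, tl, np.hypot(*(sc - tc)))
        rows[sl] = (best[1], best[2] * px, best[0] * px)
    return rows


class TestNearestDistances:
    def _tables(self, src_labels, tgt_labels, px=0.1):
        from ptcrescue.imaging_proximity import LabelMap

        shape = src_labels.shape
        one = img(np.ones(shape), px)
        return (
            label_objects(LabelMap(src_labels), one, 1),
            label_objects(LabelMap(tgt_labels), one, 1),
        )

    def test_concentric_objects_zero(self):
        s = np.zeros((32, 32), np.int32)
        t = np.zeros((32, 32), np.int32)
        s[disc_mask(s.shape, 16, 16, 3)] = 1
        t[disc_mask(t.shape, 16, 16, 6)] = 1
        src, tgt = self._tables(s, t)
        summ = nearest_distances(src, tgt)
        row = summ.per_source.iloc[0]
        assert row["edge_to_edge_um"] == 0.0
        assert row["center_to_center_um"] == pytest.approx(0.0, abs=1e-9)

    def test_two_single_pixels_two_apart(self):
        s = np.zeros((16, 16), np.int32)
        t = np.zeros((16, 16), np.int32)
        s[8, 4] = 1
        t[8, 6] = 1
        src, tgt = self._tables(s, t)
        row = nearest_distances(src, tgt).per_source.iloc[0]
        assert row["center_to_center_um"] == pytest.approx(0.2)
        assert row["edge_to_edge_um"] == pytest.approx(0.2)

    def test_random_scenes_match_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(3):
            s = np.zeros((48, 48), np.int32)
            t = np.zeros((48, 48), np.int32)
            for lab, n in ((s, 6), (t, 5)):
                k = 0
                while k < n:
                    cy, cx = rng.integers(3, 45, 2)
                    r = rng.integers(1, 3)
                    sel = disc_mask(lab.shape, cy, cx, r) & (lab == 0)
                    if sel.sum() >= 1:
                        k += 1
                        lab[sel] = k
            src, tgt = self._tables(s, t)
            summ = nearest_distances(src, tgt)
            oracle = brute_force_nearest(s, t, 0.1)
            for _, row in summ.per_source.iterrows():
                tl, c2c, edge = oracle[int(row["source_label"])]
                assert row["nearest_target"] == tl
                assert row["center_to_center_um"] == pytest.approx(c2c, abs=1e-9)
                assert row["edge_to_edge_um"] == pytest.approx(edge, abs=1e-9)

    def test_edge_le_center_and_fraction_monotone(self):
        rng = np.random.default_rng(9)
        s = (rng.random((64, 64)) < 0.02).astype(np.int32)
        s = ndi.label(s)[0]
        t = ndi.label((rng.random((64, 64)) < 0.02))[0]
        if s.max() == 0 or t.max() == 0:
            pytest.skip("degenerate draw")
        src, tgt = self._tables(s, t)
        summ = nearest_distances(src, tgt)
        ps = summ.per_source
        assert (ps["edge_to_edge_um"] <= ps["center_to_center_um"] + 1e-9).all()
        radii = np.linspace(0, 10, 25)
        fracs = [summ.fraction_within(r) for r in radii]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == 1.0

    def test_pixel_size_mismatch_rejected(self):
        s = np.zeros((8, 8), np.int32)
        s[2, 2] = 1
        src, _ = self._tables(s, s)
        _, tgt = self._tables(s, s, px=0.2)
        with pytest.raises(ValueError, match="pixel size"):
            nearest_distances(src, tgt)

    def test_empty_target_warns(self):
        s = np.zeros((8, 8), np.int32)
        s[2, 2] = 1
        src, _ = self._tables(s, s)
        _, tgt = self._tables(np.zeros((8, 8), np.int32), np.zeros((8, 8), np.int32))
        with pytest.warns(UserWarning, match="empty"):
            summ = nearest_distances(src, tgt)
        assert summ.n_source == 0


class TestIntensityPerCell:
    def test_reference_gives_100(self):
        flag = img(np.full((16, 16), 2.0))
        mask = np.zeros((16, 16), bool)
        mask[2:6, 2:6] = True
        out = intensity_per_cell(flag, [mask], reference_condition_mean=2.0)
        assert out.iloc[0]["relative_percent"] == pytest.approx(100.0)

    def test_zero_signal_and_linearity(self):
        base = np.zeros((16, 16))
        base[2:6, 2:6] = 4.0
        mask = np.zeros((16, 16), bool)
        mask[2:6, 2:6] = True
        zero = intensity_per_cell(img(np.zeros((16, 16))), [mask], 1.0)
        assert zero.iloc[0]["relative_percent"] == 0.0
        one = intensity_per_cell(img(base), [mask], 1.0)
        two = intensity_per_cell(img(2 * base), [mask], 1.0)
        assert two.iloc[0]["relative_percent"] == pytest.approx(
            2 * one.iloc[0]["relative_percent"]
        )

    def test_overlapping_masks_rejected(self):
        m1 = np.zeros((8, 8), bool)
        m1[1:4, 1:4] = True
        m2 = np.zeros((8, 8), bool)
        m2[3:6, 3:6] = True
        with pytest.raises(ValueError, match="overlap"):
            intensity_per_cell(img(np.ones((8, 8))), [m1, m2], 1.0)


def test_segmentation_deterministic_on_scene():
    from ptcrescue.presets import scene_spec
    from ptcrescue.synthetic_data import simulate_image_scene

    spec = scene_spec("wild_type", seed=21, n_fuca1=30)
    image, _ = simulate_image_scene(spec)
    cfg = ProximityConfig()
    a = segment_channel(ChannelImage(image[0], 0.1), cfg)
    b = segment_channel(ChannelImage(image[0], 0.1), cfg)
    assert a.table.equals(b.table)
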