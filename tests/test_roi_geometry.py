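import numpy as np
import pytest

import octaquant as oq
from octaquant.errors import ValidationError
from octaquant.pixel_rf import SegmentationMask
from octaquant.roi_geometry import (
    ROIMask,
    build_peripapillary_annulus,
    extract_avascular_region,
    um_to_px,
)


def _seg(mask):
    return SegmentationMask(mask=mask, probability=mask.astype(float), threshold=0.5)


def _disc(n, cy, cx, r):
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def flood_fill_components(mask):
    """Independent 8-connected component oracle (BFS, no library)."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], []
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < mask.shape[0]
                                and 0 <= nx < mask.shape[1]
                                and mask[ny, nx]
                                and not seen[ny, nx]
                            ):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(comp)
    return comps


class TestExtractAvascularRegion:
    def test_largest_blob_specks_removed(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask |= _disc(60, 30, 30, 12)  # ~450 px blob
        for y, x in [(2, 2), (2, 55), (55, 2)]:
            mask[y : y + 2, x : x + 2] = True  # 4-px specks
        core = extract_avascular_region(_seg(mask), min_area_px=50)
        assert core.mask.sum() >= 400
        assert not core.mask[2, 2] and not core.mask[55, 2]

    def test_hole_filled_area_increases(self):
        blob = np.zeros((40, 40), dtype=bool)
        blob[10:30, 10:30] = True
        holey = blob.copy()
        holey[18:20, 18:23] = False  # 10-px hole
        core = extract_avascular_region(_seg(holey), min_area_px=10)
        assert core.mask.sum() == blob.sum()
        assert core.area_px == holey.sum() + 10

    def test_equal_area_tiebreak_row_major(self):
        # two equal blobs; oracle enumerates components and finds which
        # contains the row-major-first pixel
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:10, 30:35] = True  # first in row-major order (row 5)
        mask[20:25, 2:7] = True
        comps = flood_fill_components(mask)
        assert len(comps) == 2 and len(comps[0]) == len(comps[1])
        first_pixel = min(min(c) for c in comps)
        expected = next(c for c in comps if first_pixel in c)
        core = extract_avascular_region(_seg(mask), min_area_px=5)
        got = {(y, x) for y, x in zip(*np.nonzero(core.mask))}
        assert got == set(expected)

    def test_no_region_raises(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValidationError, match="no avascular region"):
            extract_avascular_region(_seg(mask), min_area_px=50)

    def test_area_um2(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        core = extract_avascular_region(_seg(mask), min_area_px=10, pixel_size_um=10.0)
        assert core.area_um2 == core.area_px * 100.0


class TestAnnulus:
    def _edt_oracle(self, core_mask, radius_px):
        """Exhaustive per-pixel Euclidean distance to the core."""
        n, m = core_mask.shape
        core_pts = np.argwhere(core_mask)
        out = np.zeros_like(core_mask)
        for i in range(n):
            for j in range(m):
                if core_mask[i, j]:
                    continue
                d2 = ((core_pts - (i, j)) ** 2).sum(axis=1).min()
                if d2 <= radius_px**2:
                    out[i, j] = True
        return out

    def test_matches_bruteforce_oracle_small(self):
        n = 48
        core = ROIMask(mask=_disc(n, 24, 24, 8), role="avascular_core", pixel_size_um=10.0)
        annulus = build_peripapillary_annulus(core, band_width_um=100.0)
        oracle = self._edt_oracle(core.mask, 10.0)
        np.testing.assert_array_equal(annulus.mask, oracle)

    def test_matches_oracle_irregular_core(self):
        rng = np.random.default_rng(0)
        n = 40
        blob = _disc(n, 20, 18, 6)
        blob |= _disc(n, 24, 26, 4)
        core = ROIMask(mask=blob, role="avascular_core", pixel_size_um=10.0)
        annulus = build_peripapillary_annulus(core, band_width_um=55.0)
        oracle = self._edt_oracle(core.mask, 5.5)
        np.testing.assert_array_equal(annulus.mask, oracle)

    def test_disc_example_distance_band(self):
        # centered disc r=30 px, pixel 10 um, band 640 um -> pixels with
        # distance in (0, 64] px of the core
        from scipy import ndimage

        n = 200
        core = ROIMask(mask=_disc(n, 100, 100, 30), role="avascular_core", pixel_size_um=10.0)
        annulus = build_peripapillary_annulus(core, band_width_um=640.0)
        dist = ndimage.distance_transform_edt(~core.mask)
        np.testing.assert_array_equal(annulus.mask, (dist > 0) & (dist <= 64.0))

    def test_nesting_monotone_in_band_width(self):
        n = 128
        core = ROIMask(mask=_disc(n, 64, 64, 10), role="avascular_core", pixel_size_um=40.0)
        a640 = build_peripapillary_annulus(core, 640.0)
        a920 = build_peripapillary_annulus(core, 920.0)
        a1960 = build_peripapillary_annulus(core, 1960.0)
        assert np.all(a920.mask[a640.mask])
        assert np.all(a1960.mask[a920.mask])
        # annulus never intersects the core
        for a in (a640, a920, a1960):
            assert not np.any(a.mask & core.mask)

    def test_circular_core_area_formula(self):
        # far from borders: area ~= pi * ((r+w)^2 - r^2) within 3%
        n = 400
        r, w_px = 40, 60
        core = ROIMask(mask=_disc(n, 200, 200, r), role="avascular_core", pixel_size_um=10.0)
        annulus = build_peripapillary_annulus(core, band_width_um=w_px * 10.0)
        expected = np.pi * ((r + w_px) ** 2 - r**2)
        assert annulus.area_px == pytest.approx(expected, rel=0.03)

    def test_border_clipping(self):
        n = 30
        core = ROIMask(mask=_disc(n, 2, 2, 4), role="avascular_core", pixel_size_um=10.0)
        annulus = build_peripapillary_annulus(core, band_width_um=100.0)
        assert annulus.mask.shape == (n, n)
        assert not np.any(annulus.mask & core.mask)

    def test_subpixel_band_rejected(self):
        core = ROIMask(mask=_disc(20, 10, 10, 3), role="avascular_core", pixel_size_um=10.0)
        with pytest.raises(ValidationError, match="band width"):
            build_peripapillary_annulus(core, band_width_um=5.0)

    def test_empty_core_rejected(self):
        core = ROIMask(
            mask=np.zeros((10, 10), dtype=bool), role="avascular_core", pixel_size_um=10.0
        )
        with pytest.raises(ValidationError, match="empty"):
            build_peripapillary_annulus(core, band_width_um=100.0)


class TestUmToPx:
    def test_ratio_at_device_calibration(self):
        assert um_to_px(640.0, 3000 / 304) == pytest.approx(640 / (3000 / 304))
        assert um_to_px(640.0, 3000 / 304) == pytest.approx(64.85, abs=0.01)

    def test_exact(self):
        assert um_to_px(640.0, 10.0) == 64.0

    def test_zero(self):
        assert um_to_px(0.0, 10.0) == 0.0

    def test_invalid(self):
        with pytest.raises(ValidationError):
            um_to_px(10.0, 0.0)
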