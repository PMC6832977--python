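import math

import numpy as np
import pytest

from octava.errors import FAZDetectionError, UndefinedZoneError, ValidationError
from octava.etdrs_density import (
    ZONES,
    analyze_visit,
    build_etdrs_masks,
    zonal_density,
)
from octava.image_io import OCTAImage
from octava.vessel_map import SkeletonMask

from conftest import make_image

SCALE_320 = 3.0 / 320


def _center_disk(shape, center, radius_mm, scale):
    rows = np.arange(shape[0])[:, None] + 0.5 - center[0]
    cols = np.arange(shape[1])[None, :] + 0.5 - center[1]
    return np.hypot(rows, cols) * scale <= radius_mm


class TestBuildMasks:
    def test_closed_form_areas(self):
        zm = build_etdrs_masks((320, 320), (160, 160), SCALE_320, "OD")
        px_area = SCALE_320**2
        assert zm["foveal"].sum() * px_area == pytest.approx(math.pi * 0.25, rel=0.02)
        for q in ("upper", "nasal", "temporal", "lower"):
            assert zm[q].sum() * px_area == pytest.approx(math.pi * 2 / 4, rel=0.02)

    def test_resolution_convergence(self):
        # closed-form areas are approached as the grid refines
        for n, tol in [(320, 0.02), (1280, 0.005)]:
            zm = build_etdrs_masks((n, n), (n / 2, n / 2), 3.0 / n, "OD")
            px_area = (3.0 / n) ** 2
            assert zm["foveal"].sum() * px_area == pytest.approx(math.pi * 0.25, rel=tol)
            assert zm["upper"].sum() * px_area == pytest.approx(math.pi / 2, rel=tol)

    def test_partition_of_outer_disk(self):
        zm = build_etdrs_masks((320, 320), (160, 160), SCALE_320, "OD")
        union = np.zeros((320, 320), bool)
        for z in ZONES:
            assert not (union & zm[z]).any()
            union |= zm[z]
        disk = _center_disk((320, 320), (160, 160), 1.5, SCALE_320)
        assert np.array_equal(union, disk)

    def test_foveal_is_inner_disk(self):
        zm = build_etdrs_masks((320, 320), (160, 160), SCALE_320, "OD")
        assert np.array_equal(zm["foveal"], _center_disk((320, 320), (160, 160), 0.5, SCALE_320))

    def test_od_os_mirror(self):
        od = build_etdrs_masks((320, 320), (160, 160), SCALE_320, "OD")
        os_ = build_etdrs_masks((320, 320), (160, 160), SCALE_320, "OS")
        assert np.array_equal(od["upper"], os_["upper"])
        assert np.array_equal(od["lower"], os_["lower"])
        assert np.array_equal(od["nasal"], os_["temporal"])
        assert np.array_equal(od["temporal"], os_["nasal"])

    def test_off_center_clipped_at_border(self):
        zm = build_etdrs_masks((320, 320), (20, 20), SCALE_320, "OD")
        assert zm["foveal"].sum() > 0  # clipped but non-empty

    def test_center_outside_rejected(self):
        with pytest.raises(ValidationError):
            build_etdrs_masks((320, 320), (400, 160), SCALE_320, "OD")


class TestZonalDensity:
    def _zones(self):
        return build_etdrs_masks((320, 320), (160, 160), SCALE_320, "OD")

    def test_empty_skeleton(self):
        profile = zonal_density(np.zeros((320, 320), bool), self._zones())
        assert all(profile.zone(z) == 0.0 for z in ZONES)
        assert profile.dens_global == 0.0

    def test_full_foveal_mask(self):
        zm = self._zones()
        profile = zonal_density(zm["foveal"].copy(), zm)
        assert profile.dens_foveal == 1.0
        assert all(profile.zone(z) == 0.0 for z in ZONES if z != "foveal")

    def test_global_toy_frame(self):
        sk = np.zeros((5, 5), bool)
        sk[0, :5] = True
        zones = build_etdrs_masks((5, 5), (2.5, 2.5), 0.5, "OD")
        profile = zonal_density(sk, zones)
        assert profile.dens_global == 5 / 25 == 0.2

    def test_partition_identity(self, rng):
        # sum of zone counts equals the skeleton count inside the 3 mm disk
        zm = self._zones()
        sk = rng.random((320, 320)) < 0.1
        profile = zonal_density(sk, zm)
        total = sum(
            round(profile.zone(z) * zm[z].sum()) for z in ZONES
        )
        disk = _center_disk((320, 320), (160, 160), 1.5, SCALE_320)
        assert total == int(np.count_nonzero(sk & disk))

    def test_monotonicity(self, rng):
        zm = self._zones()
        sk = rng.random((320, 320)) < 0.05
        base = zonal_density(sk, zm)
        extra = sk.copy()
        rows, cols = np.nonzero(zm["upper"] & ~sk)
        extra[rows[:50], cols[:50]] = True
        more = zonal_density(extra, zm)
        assert more.dens_upper > base.dens_upper
        for z in ("foveal", "nasal", "temporal", "lower"):
            assert more.zone(z) == base.zone(z)

    def test_empty_zone_raises(self):
        zones = build_etdrs_masks((20, 20), (1, 1), 3.0 / 20, "OD")
        with pytest.raises(UndefinedZoneError):
            zonal_density(np.zeros((20, 20), bool), zones)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            zonal_density(np.zeros((10, 10), bool), self._zones())

    def test_accepts_skeleton_mask(self):
        zm = self._zones()
        sk = SkeletonMask(np.zeros((320, 320), bool))
        assert zonal_density(sk, zm).dens_global == 0.0


# --- analyze_visit with an exactly hand-countable fixture ---------------------

N = 320


def _grid_lines(gap_half=None):
    m = np.zeros((N, N), bool)
    for p in range(8, N, 16):
        m[p, :] = True
        m[:, p] = True
    if gap_half is not None:
        rr = np.abs(np.arange(N)[:, None] - (N - 1) / 2)
        cc = np.abs(np.arange(N)[None, :] - (N - 1) / 2)
        m[np.maximum(rr, cc) <= gap_half] = False
    return m


def _square_ring():
    m = np.zeros((N, N), bool)
    m[128, 128:192] = True
    m[191, 128:192] = True
    m[128:192, 128] = True
    m[128:192, 191] = True
    return m


def _visit_images(laterality="OD"):
    scp3 = _grid_lines(gap_half=34) | _square_ring()
    images = {("SCP", 3.0): make_image(scp3 * np.uint8(200), 3.0, "SCP", laterality, "v1")}
    for plexus, extent in [("SCP", 6.0), ("DCP", 3.0), ("DCP", 6.0)]:
        images[(plexus, extent)] = make_image(
            _grid_lines() * np.uint8(200), extent, plexus, laterality, "v1"
        )
    return images, scp3


def _hand_density(drawn, extent, center, laterality="OD"):
    """Independent per-pixel zone classification and counting (plain loops)."""
    scale = extent / N
    counts = dict.fromkeys(ZONES, 0)
    sizes = dict.fromkeys(ZONES, 0)
    for r in range(N):
        for c in range(N):
            dy = r + 0.5 - center[0]
            dx = c + 0.5 - center[1]
            d = math.hypot(dy, dx) * scale
            if d <= 0.5:
                z = "foveal"
            elif d <= 1.5:
                th = math.degrees(math.atan2(-dy, dx)) % 360
                if 45 <= th < 135:
                    z = "upper"
                elif 135 <= th < 225:
                    z = "temporal" if laterality == "OD" else "nasal"
                elif 225 <= th < 315:
                    z = "lower"
                else:
                    z = "nasal" if laterality == "OD" else "temporal"
            else:
                continue
            sizes[z] += 1
            if drawn[r, c]:
                counts[z] += 1
    return {z: counts[z] / sizes[z] for z in ZONES}


class TestAnalyzeVisit:
    def test_densities_match_hand_counts(self):
        images, scp3 = _visit_images()
        record = analyze_visit(images, real_va_decimal=0.8)
        # the drawn patterns are fixed points of the skeletonizer and the
        # FAZ centroid is the exact frame centre, so every density must
        # equal an independent per-pixel count
        center = (160.0, 160.0)
        for (plexus, extent), key in [
            (("SCP", 3.0), ("SCP", 3)),
            (("SCP", 6.0), ("SCP", 6)),
            (("DCP", 3.0), ("DCP", 3)),
            (("DCP", 6.0), ("DCP", 6)),
        ]:
            drawn = images[(plexus, extent)].pixels > 0
            expected = _hand_density(drawn, extent, center)
            for z in ZONES:
                assert record.vd[(key[0], key[1], z)] == expected[z], (plexus, extent, z)
        assert record.real_va_decimal == 0.8
        assert record.faz_area_scp3_mm2 > 0

    def test_scp_only_mode(self):
        images, _ = _visit_images()
        del images[("DCP", 3.0)], images[("DCP", 6.0)]
        record = analyze_visit(images, real_va_decimal=0.5, require_dcp=False)
        assert len(record.vd) == 10  # 2 scans x 5 zones
        assert record.faz_area_scp3_mm2 > 0

    def test_missing_scan_raises(self):
        images, _ = _visit_images()
        del images[("DCP", 6.0)]
        with pytest.raises(ValidationError, match="missing scan"):
            analyze_visit(images)

    def test_mismatched_laterality(self):
        images, _ = _visit_images()
        bad = images[("DCP", 6.0)]
        images[("DCP", 6.0)] = OCTAImage(bad.pixels, 6.0, "DCP", "OS", "v1")
        with pytest.raises(ValidationError, match="laterality"):
            analyze_visit(images)

    def test_faz_failure_carries_visit_id(self):
        images, _ = _visit_images()
        flat = _grid_lines() * np.uint8(200)  # no enclosed avascular region
        images[("SCP", 3.0)] = make_image(flat, 3.0, "SCP", "OD", "v1")
        with pytest.raises(FAZDetectionError, match="v1"):
            analyze_visit(images)
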