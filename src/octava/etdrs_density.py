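"""ETDRS grid construction and zonal vascular-density quantification.

The grid has a 1 mm diameter inner ring (foveal zone) and a 3 mm diameter
outer ring whose annulus is split into upper, nasal, temporal and lower
quadrants by the two diagonals through the grid centre.  The density of a
zone is the fraction of its pixels occupied by the vessel skeleton; the
global density is the skeleton pixel count over the whole frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import FAZDetectionError, UndefinedZoneError, ValidationError
from .faz_segmentation import FAZConfig, DEFAULT_FAZ_CONFIG, detect_faz
from .image_io import DCP, OD, OS, SCP, OCTAImage
from .vessel_map import SkeletonMask, binarize, otsu_threshold, skeletonize
from .va_estimator import VisitRecord

#: zone labels, in feature order
ZONES = ("foveal", "upper", "nasal", "temporal", "lower")

QUADRANTS = ("upper", "nasal", "temporal", "lower")


@dataclass(frozen=True)
class ZoneMasks:
    """The five ETDRS zone masks plus the geometry they were built from."""

    masks: Mapping  # zone name -> bool array
    center_px: tuple
    scale_mm_per_px: float
    laterality: str
    inner_diameter_mm: float = 1.0
    outer_diameter_mm: float = 3.0

    def __getitem__(self, zone: str) -> np.ndarray:
        return self.masks[zone]

    def zone_sizes(self) -> dict:
        return {z: int(self.masks[z].sum()) for z in ZONES}


@dataclass(frozen=True)
class DensityProfile:
    """Per-zone and global skeleton densities of one scan (fractions in [0, 1])."""

    dens_foveal: float
    dens_upper: float
    dens_nasal: float
    dens_temporal: float
    dens_lower: float
    dens_global: float
    plexus: str = ""
    extent_mm: float = float("nan")

    def zone(self, name: str) -> float:
        return getattr(self, f"dens_{name}")

    def as_dict(self) -> dict:
        return {z: self.zone(z) for z in ZONES} | {"global": self.dens_global}


def quadrant_of_angle(theta_deg: np.ndarray, laterality: str) -> np.ndarray:
    """Map polar angles (from image-right, counterclockwise) to quadrant indices.

    Half-open intervals keep the partition deterministic on the +/-45 deg
    diagonals: upper = [45, 135), lower = [225, 315).  For OD the nasal
    retina lies on the image-right side ([315, 45)); OS is mirrored.
    Returns indices into :data:`QUADRANTS`.
    """
    theta = np.mod(theta_deg, 360.0)
    out = np.empty(theta.shape, dtype=np.int8)
    upper = (theta >= 45.0) & (theta < 135.0)
    left = (theta >= 135.0) & (theta < 225.0)
    lower = (theta >= 225.0) & (theta < 315.0)
    right = ~(upper | left | lower)
    out[upper] = QUADRANTS.index("upper")
    out[lower] = QUADRANTS.index("lower")
    nasal_right = laterality == OD
    out[right] = QUADRANTS.index("nasal" if nasal_right else "temporal")
    out[left] = QUADRANTS.index("temporal" if nasal_right else "nasal")
    return out


def build_etdrs_masks(
    shape: tuple,
    center_px: tuple,
    scale_mm_per_px: float,
    laterality: str,
    inner_diameter_mm: float = 1.0,
    outer_diameter_mm: float = 3.0,
) -> ZoneMasks:
    """Build the five ETDRS zone masks on a pixel grid.

    ``center_px`` is a continuous (row, col) coordinate in pixel units;
    pixel membership is decided by the distance of each pixel centre
    (``row + 0.5, col + 0.5``) from the grid centre.  The outer circle is
    clipped at the image border; the centre itself must lie inside.
    """
    H, W = shape
    cr, cc = float(center_px[0]), float(center_px[1])
    if not (0.0 <= cr <= H and 0.0 <= cc <= W):
        raise ValidationError(f"grid centre {center_px} outside image of shape {shape}")
    if laterality not in (OD, OS):
        raise ValidationError(f"laterality must be OD or OS, got {laterality!r}")
    rows = np.arange(H, dtype=np.float64)[:, None] + 0.5 - cr
    cols = np.arange(W, dtype=np.float64)[None, :] + 0.5 - cc
    d_mm = np.hypot(rows, cols) * scale_mm_per_px
    inner_r = inner_diameter_mm / 2.0
    outer_r = outer_diameter_mm / 2.0
    foveal = d_mm <= inner_r
    annulus = (d_mm > inner_r) & (d_mm <= outer_r)
    # row axis points down, so negate it for counterclockwise angles
    theta = np.degrees(np.arctan2(-rows, np.broadcast_to(cols, (H, W))))
    quad = quadrant_of_angle(theta, laterality)
    masks = {"foveal": foveal}
    for i, name in enumerate(QUADRANTS):
        masks[name] = annulus & (quad == i)
    return ZoneMasks(
        masks=masks,
        center_px=(cr, cc),
        scale_mm_per_px=scale_mm_per_px,
        laterality=laterality,
        inner_diameter_mm=inner_diameter_mm,
        outer_diameter_mm=outer_diameter_mm,
    )


def zonal_density(
    skeleton: SkeletonMask,
    zones: ZoneMasks,
    plexus: str = "",
    extent_mm: float = float("nan"),
) -> DensityProfile:
    """Skeleton-pixel fraction per ETDRS zone plus the whole-frame density."""
    sk = skeleton.pixels if isinstance(skeleton, SkeletonMask) else np.asarray(skeleton, bool)
    values = {}
    for z in ZONES:
        m = zones[z]
        if m.shape != sk.shape:
            raise ValidationError("skeleton and zone masks must share shape")
        n = int(m.sum())
        if n == 0:
            raise UndefinedZoneError(f"zone {z!r} contains no pixels")
        values[z] = float(np.count_nonzero(sk & m)) / n
    dens_global = float(np.count_nonzero(sk)) / sk.size
    return DensityProfile(
        dens_foveal=values["foveal"],
        dens_upper=values["upper"],
        dens_nasal=values["nasal"],
        dens_temporal=values["temporal"],
        dens_lower=values["lower"],
        dens_global=dens_global,
        plexus=plexus,
        extent_mm=extent_mm,
    )


def _scan_density(
    image: OCTAImage,
    center_px: tuple,
    grid_outer_mm: float,
) -> DensityProfile:
    t = otsu_threshold(image).threshold
    skeleton = skeletonize(binarize(image, t))
    zones = build_etdrs_masks(
        image.pixels.shape,
        center_px,
        image.scale_mm_per_px,
        image.laterality,
        outer_diameter_mm=grid_outer_mm,
    )
    return zonal_density(skeleton, zones, plexus=image.plexus, extent_mm=image.extent_mm)


def analyze_visit(
    images: Mapping,
    real_va_decimal: float = float("nan"),
    *,
    require_dcp: bool = True,
    grid_outer_mm: float = 3.0,
    center_6mm_from_faz: bool = False,
    faz_config: FAZConfig = DEFAULT_FAZ_CONFIG,
    extras: Mapping | None = None,
) -> VisitRecord:
    """Extract all biomarkers of one visit.

    ``images`` maps ``(plexus, extent_mm)`` keys to :class:`OCTAImage`.
    The FAZ is detected on the SCP 3x3 mm scan; the ETDRS grid is centred
    at its centroid for the 3x3 mm scans and at the frame centre for the
    6x6 mm scans (all captures are fovea-centred), unless
    ``center_6mm_from_faz`` propagates the 3 mm centroid instead.
    With ``require_dcp=False`` a visit holding only SCP scans yields an
    SCP-only record.
    """
    images = dict(images)
    needed = [(SCP, 3.0), (SCP, 6.0)]
    if require_dcp:
        needed += [(DCP, 3.0), (DCP, 6.0)]
    missing = [k for k in needed if k not in images]
    if missing:
        raise ValidationError(f"missing scan(s): {missing}")
    lateralities = {im.laterality for im in images.values()}
    if len(lateralities) != 1:
        raise ValidationError(f"mismatched laterality across scans: {sorted(lateralities)}")
    visit_ids = {im.visit_id for im in images.values()}
    if len(visit_ids) != 1:
        raise ValidationError(f"mismatched visit_id across scans: {sorted(visit_ids)}")
    visit_id = visit_ids.pop()

    scp3 = images[(SCP, 3.0)]
    try:
        faz = detect_faz(scp3, config=faz_config)
    except FAZDetectionError as exc:
        raise FAZDetectionError(f"visit {visit_id!r}: {exc}") from exc

    vd = {}
    for (plexus, extent), image in images.items():
        if extent == 3.0:
            center = faz.centroid_px
        elif center_6mm_from_faz:
            # propagate the 3 mm centroid assuming co-centred captures
            n3 = scp3.width
            offset_mm = (
                (faz.centroid_px[0] - n3 / 2.0) * scp3.scale_mm_per_px,
                (faz.centroid_px[1] - n3 / 2.0) * scp3.scale_mm_per_px,
            )
            H, W = image.pixels.shape
            s = image.scale_mm_per_px
            center = (H / 2.0 + offset_mm[0] / s, W / 2.0 + offset_mm[1] / s)
        else:
            H, W = image.pixels.shape
            center = (H / 2.0, W / 2.0)
        profile = _scan_density(image, center, grid_outer_mm)
        for zone in ZONES:
            vd[(plexus, int(extent), zone)] = profile.zone(zone)

    return VisitRecord(
        visit_id=visit_id,
        laterality=scp3.laterality,
        faz_area_scp3_mm2=faz.area_mm2,
        vd=vd,
        real_va_decimal=float(real_va_decimal),
        extras=dict(extras or {}),
    )
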