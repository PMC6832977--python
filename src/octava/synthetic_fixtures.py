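"""Seeded synthetic OCTA-like fixtures with known ground truth.

Two generators:

* :func:`generate_vessel_image` renders a jittered vessel lattice with an
  optional central avascular disk (ringed by a capillary border, as the
  real FAZ is), per-zone vessel dropout and additive noise, and returns
  the pre-noise geometric ground truth alongside the image.
* :func:`generate_cohort` draws biomarker vectors from plausible ranges
  and computes decimal VA from a known linear law plus Gaussian noise.

Zone geometry for the ground truth is computed locally so that fixture
truth does not depend on the analysis code it is used to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import ValidationError
from .image_io import DCP, OD, OS, SCP, OCTAImage, write_octa_image
from .va_estimator import FEATURE_NAMES, SCP_DCP, VisitRecord

ZONES = ("foveal", "upper", "nasal", "temporal", "lower")

_SEGMENT_LEN = 8  # px; unit of vessel dropout


@dataclass(frozen=True)
class VesselFixtureSpec:
    size_px: int = 320
    extent_mm: float = 3.0
    plexus: str = SCP
    laterality: str = OD
    visit_id: str = ""
    faz_radius_mm: float = 0.3  # 0 disables the avascular disk
    vessel_spacing_px: int = 12
    vessel_width_px: int = 3
    #: zone name -> fraction of vessel segments erased
    dropout: Mapping = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    #: additional avascular disks (row_px, col_px, radius_mm), for
    #: false-positive disambiguation fixtures
    extra_avascular: tuple = ()

    def __post_init__(self) -> None:
        if self.size_px <= 0 or self.vessel_spacing_px <= 0 or self.vessel_width_px <= 0:
            raise ValidationError("size, spacing and width must be positive")
        if self.faz_radius_mm < 0 or self.noise_sd < 0:
            raise ValidationError("faz_radius_mm and noise_sd must be non-negative")
        if self.faz_radius_mm >= self.extent_mm / 2:
            raise ValidationError(
                f"faz_radius_mm {self.faz_radius_mm} must be < extent/2 = {self.extent_mm / 2}"
            )
        for name, frac in self.dropout.items():
            if name not in ZONES or not 0.0 <= frac <= 1.0:
                raise ValidationError(f"bad dropout entry {name!r}: {frac}")

    @property
    def scale_mm_per_px(self) -> float:
        return self.extent_mm / self.size_px


@dataclass(frozen=True)
class GroundTruth:
    """Pre-noise geometry of a generated fixture."""

    faz_mask: np.ndarray  # pixel-centre disk of the true FAZ (bool)
    faz_area_mm2: float  # analytic pi * r^2
    faz_center_px: tuple
    centerline: np.ndarray  # true one-pixel vessel skeleton (bool)
    zone_counts: dict  # zone -> centerline pixel count (grid at image centre)
    zone_sizes: dict  # zone -> zone pixel count


def _zone_index_map(size: int, scale: float, laterality: str) -> np.ndarray:
    """Zone index per pixel (0..4 for ZONES order, -1 outside the grid).

    Independent re-statement of the ETDRS geometry: pixel-centre distance
    and polar angle from the image centre, half-open quadrant intervals,
    nasal on image-right for OD.
    """
    c = size / 2.0
    rows = np.arange(size)[:, None] + 0.5 - c
    cols = np.arange(size)[None, :] + 0.5 - c
    d_mm = np.hypot(rows, cols) * scale
    theta = np.mod(np.degrees(np.arctan2(-rows, np.broadcast_to(cols, (size, size)))), 360.0)
    out = np.full((size, size), -1, dtype=np.int8)
    out[d_mm <= 0.5] = ZONES.index("foveal")
    ann = (d_mm > 0.5) & (d_mm <= 1.5)
    upper = ann & (theta >= 45) & (theta < 135)
    left = ann & (theta >= 135) & (theta < 225)
    lower = ann & (theta >= 225) & (theta < 315)
    right = ann & ~(upper | left | lower)
    out[upper] = ZONES.index("upper")
    out[lower] = ZONES.index("lower")
    out[right] = ZONES.index("nasal" if laterality == OD else "temporal")
    out[left] = ZONES.index("temporal" if laterality == OD else "nasal")
    return out


def _pixel_center_dist(size: int, center: tuple) -> np.ndarray:
    rows = np.arange(size)[:, None] + 0.5 - center[0]
    cols = np.arange(size)[None, :] + 0.5 - center[1]
    return np.hypot(rows, cols)


def _erase_disk_and_ring(
    centerline: np.ndarray, center: tuple, r_px: float, width: int
) -> None:
    """Clear centerlines inside a disk and add the centerline of its border ring."""
    dist = _pixel_center_dist(centerline.shape[0], center)
    centerline[dist < r_px + width] = False
    mid = r_px + width / 2.0
    centerline[(dist >= mid - 0.5) & (dist < mid + 0.5)] = True


def generate_vessel_image(spec: VesselFixtureSpec):
    """Render a fixture image; returns ``(OCTAImage, GroundTruth)``.

    Deterministic for a fixed spec (same seed => bit-identical image).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    scale = spec.scale_mm_per_px
    w = spec.vessel_width_px
    center = (n / 2.0, n / 2.0)

    # quasi-regular lattice of one-pixel centerlines with per-line jitter
    centerline = np.zeros((n, n), dtype=bool)
    base = np.arange(spec.vessel_spacing_px // 2, n, spec.vessel_spacing_px)
    jit_rows = np.clip(base + rng.integers(-2, 3, size=base.size), 0, n - 1)
    jit_cols = np.clip(base + rng.integers(-2, 3, size=base.size), 0, n - 1)
    centerline[jit_rows, :] = True
    centerline[:, jit_cols] = True

    # per-zone dropout of fixed-length vessel segments
    if any(f > 0 for f in spec.dropout.values()):
        zmap = _zone_index_map(n, scale, spec.laterality)
        frac = np.zeros(len(ZONES))
        for name, f in spec.dropout.items():
            frac[ZONES.index(name)] = f
        for r in jit_rows:
            for c0 in range(0, n, _SEGMENT_LEN):
                mid = min(c0 + _SEGMENT_LEN // 2, n - 1)
                z = zmap[r, mid]
                if z >= 0 and rng.random() < frac[z]:
                    centerline[r, c0 : c0 + _SEGMENT_LEN] = False
        for c in jit_cols:
            for r0 in range(0, n, _SEGMENT_LEN):
                mid = min(r0 + _SEGMENT_LEN // 2, n - 1)
                z = zmap[mid, c]
                if z >= 0 and rng.random() < frac[z]:
                    centerline[r0 : r0 + _SEGMENT_LEN, c] = False

    # carve the FAZ (and any extra avascular decoys), each ringed by a border vessel
    faz_r_px = spec.faz_radius_mm / scale
    if spec.faz_radius_mm > 0:
        _erase_disk_and_ring(centerline, center, faz_r_px, w)
    for row, col, radius_mm in spec.extra_avascular:
        _erase_disk_and_ring(centerline, (row, col), radius_mm / scale, w)

    # render to width; border rings are drawn as exact distance bands so the
    # avascular interiors are precisely the disks of the requested radii
    vessel = ndimage.binary_dilation(centerline, structure=disk((w - 1) // 2))
    if spec.faz_radius_mm > 0:
        dist = _pixel_center_dist(n, center)
        vessel[(dist >= faz_r_px) & (dist < faz_r_px + w)] = True
        vessel[dist < faz_r_px] = False
    for row, col, radius_mm in spec.extra_avascular:
        dist = _pixel_center_dist(n, (row, col))
        r_px = radius_mm / scale
        vessel[(dist >= r_px) & (dist < r_px + w)] = True
        vessel[dist < r_px] = False

    # clearly bimodal intensity model: bright vessels on a dark background
    img = rng.integers(0, 61, size=(n, n))
    img[vessel] = rng.integers(180, 256, size=int(vessel.sum()))
    if spec.noise_sd > 0:
        img = np.round(img + rng.normal(0.0, spec.noise_sd, size=(n, n)))
    pixels = np.clip(img, 0, 255).astype(np.uint8)

    faz_mask = (
        _pixel_center_dist(n, center) < faz_r_px
        if spec.faz_radius_mm > 0
        else np.zeros((n, n), dtype=bool)
    )
    zmap = _zone_index_map(n, scale, spec.laterality)
    zone_counts = {
        z: int(np.count_nonzero(centerline & (zmap == i))) for i, z in enumerate(ZONES)
    }
    zone_sizes = {z: int(np.count_nonzero(zmap == i)) for i, z in enumerate(ZONES)}
    truth = GroundTruth(
        faz_mask=faz_mask,
        faz_area_mm2=float(np.pi * spec.faz_radius_mm**2),
        faz_center_px=center,
        centerline=centerline,
        zone_counts=zone_counts,
        zone_sizes=zone_sizes,
    )
    image = OCTAImage(
        pixels=pixels,
        extent_mm=spec.extent_mm,
        plexus=spec.plexus,
        laterality=spec.laterality,
        visit_id=spec.visit_id,
    )
    return image, truth


@dataclass(frozen=True)
class CohortSpec:
    n_visits: int = 150
    #: weight per biomarker, in FEATURE_NAMES["scp_dcp"] order (length 21)
    weights: Sequence = ()
    intercept: float = 0.0
    va_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_visits < 15:
            raise ValidationError(f"n_visits must be >= 15, got {self.n_visits}")
        if self.va_noise_sd < 0:
            raise ValidationError("va_noise_sd must be >= 0")
        if len(self.weights) != 21:
            raise ValidationError(f"need 21 weights, got {len(self.weights)}")


def default_cohort_weights(dcp_signal: bool = True) -> tuple:
    """A linear VA law with moderate signal spread and negligible clipping.

    With ``dcp_signal=False`` the ten DCP densities carry zero weight, so
    an SCP-only model sees the full signal.
    """
    if dcp_signal:
        w = dict.fromkeys(FEATURE_NAMES[SCP_DCP], 0.45)
        w["faz_area_scp3_mm2"] = -0.17
    else:
        # concentrate the same overall spread on the 10 SCP densities
        w = dict.fromkeys(FEATURE_NAMES[SCP_DCP], 0.0)
        for name in FEATURE_NAMES[SCP_DCP]:
            if name.startswith("vd_scp"):
                w[name] = 0.62
        w["faz_area_scp3_mm2"] = -0.2
    return tuple(w[name] for name in FEATURE_NAMES[SCP_DCP])


def default_cohort_intercept(weights: Sequence) -> float:
    """Intercept centring the expected VA at 0.5 for the default feature ranges."""
    w = np.asarray(weights, dtype=np.float64)
    means = np.array([0.8] + [0.135] * 20)  # E[faz], E[density]
    return float(0.5 - w @ means)


def generate_cohort(spec: CohortSpec):
    """Draw a synthetic cohort; returns ``(records, weights)``.

    Biomarkers: FAZ area ~ U(0.1, 1.5) mm^2, densities ~ U(0.02, 0.25);
    VA = clip(intercept + w.x + N(0, va_noise_sd), 0, 1).
    """
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.weights, dtype=np.float64)
    records = []
    for i in range(spec.n_visits):
        faz = rng.uniform(0.1, 1.5)
        dens = rng.uniform(0.02, 0.25, size=20)
        x = np.concatenate([[faz], dens])
        va = spec.intercept + float(w @ x)
        if spec.va_noise_sd > 0:
            va += rng.normal(0.0, spec.va_noise_sd)
        vd = {}
        j = 0
        for plexus in (SCP, DCP):
            for extent in (3, 6):
                for zone in ZONES:
                    vd[(plexus, extent, zone)] = float(dens[j])
                    j += 1
        records.append(
            VisitRecord(
                visit_id=f"V{i:04d}",
                faz_area_scp3_mm2=float(faz),
                vd=vd,
                real_va_decimal=float(np.clip(va, 0.0, 1.0)),
                laterality=OD if i % 2 == 0 else OS,
            )
        )
    return records, w


def simulate_cohort_dir(
    outdir: str | Path,
    n_visits: int = 15,
    seed: int = 0,
    size_px: int = 160,
    vessel_spacing_px: int = 8,
    noise_sd: float = 8.0,
) -> Path:
    """Write a self-contained image cohort: PNGs, sidecars and cohort.csv.

    VA follows a deterministic law on the generated ground truth (FAZ area
    and dropout severity) plus seeded noise, so the end-to-end pipeline has
    real signal to recover.  Returns the cohort CSV path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_visits):
        visit_id = f"V{i:04d}"
        laterality = OD if i % 2 == 0 else OS
        faz_r = float(rng.uniform(0.18, 0.42))
        severity = float(rng.uniform(0.0, 0.5))
        dropout = {z: severity for z in ("upper", "nasal", "temporal", "lower")}
        va = float(
            np.clip(1.15 - 1.2 * np.pi * faz_r**2 - 0.9 * severity
                    + rng.normal(0.0, 0.03), 0.02, 1.0)
        )
        row = {"visit_id": visit_id, "va_decimal": round(va, 4), "laterality": laterality,
               "treated": "yes" if i % 3 else "no",
               "lens_status": "pseudophakic" if i % 4 == 0 else "phakic"}
        for plexus in (SCP, DCP):
            for extent in (3.0, 6.0):
                name = f"{visit_id}_{plexus.lower()}{int(extent)}.png"
                spec = VesselFixtureSpec(
                    size_px=size_px,
                    extent_mm=extent,
                    plexus=plexus,
                    laterality=laterality,
                    visit_id=visit_id,
                    faz_radius_mm=faz_r if (plexus, extent) == (SCP, 3.0) else 0.0,
                    vessel_spacing_px=vessel_spacing_px,
                    dropout=dropout,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31)),
                )
                image, _ = generate_vessel_image(spec)
                write_octa_image(image, outdir / name, sidecar=True)
                row[f"path_{plexus.lower()}{int(extent)}"] = name
        rows.append(row)
    import pandas as pd

    csv_path = outdir / "cohort.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
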