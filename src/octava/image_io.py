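"""Reading and writing of en-face angiograms and cohort tables.

Physical-scale bookkeeping lives here: an :class:`OCTAImage` carries the
side length of the scanned square in millimetres, from which the
millimetre-per-pixel scale is derived.  The coordinate convention used
throughout the package is row 0 = superior (top of the image), column 0 =
left, 0-based indices, with pixel centres at ``(row + 0.5, col + 0.5)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import ImageReadError, ValidationError

SCP = "SCP"
DCP = "DCP"
OD = "OD"
OS = "OS"

PLEXUSES = (SCP, DCP)
LATERALITIES = (OD, OS)

#: (plexus, extent_mm) keys of the four scans of a complete visit.
SCAN_KEYS = ((SCP, 3.0), (SCP, 6.0), (DCP, 3.0), (DCP, 6.0))

#: cohort CSV column holding the image path of each scan
SCAN_PATH_COLUMNS = {
    (SCP, 3.0): "path_scp3",
    (SCP, 6.0): "path_scp6",
    (DCP, 3.0): "path_dcp3",
    (DCP, 6.0): "path_dcp6",
}

_REQUIRED_COHORT_COLUMNS = ("visit_id", "va_decimal", "laterality")


def _validate_plexus(plexus: str) -> str:
    if plexus not in PLEXUSES:
        raise ValidationError(f"plexus must be one of {PLEXUSES}, got {plexus!r}")
    return plexus


def _validate_laterality(laterality: str) -> str:
    if laterality not in LATERALITIES:
        raise ValidationError(
            f"laterality must be one of {LATERALITIES}, got {laterality!r}"
        )
    return laterality


@dataclass(frozen=True)
class OCTAImage:
    """A grayscale en-face angiogram with physical-scale metadata.

    Parameters
    ----------
    pixels
        Square 2-D array of 8-bit intensities (rows = height).
    extent_mm
        Physical side length of the scanned square (3.0 or 6.0 mm
        for the supported captures, but any positive value is accepted).
    plexus
        ``"SCP"`` or ``"DCP"``.
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    visit_id
        Opaque identifier linking the scan to a cohort row.
    """

    pixels: np.ndarray
    extent_mm: float
    plexus: str
    laterality: str
    visit_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if px.shape[0] != px.shape[1]:
            raise ValidationError(f"image must be square, got shape {px.shape}")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.floating) and not np.all(px == np.round(px)):
                raise ValidationError("pixel intensities must be integers in [0, 255]")
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not self.extent_mm > 0:
            raise ValidationError(f"extent_mm must be > 0, got {self.extent_mm}")
        _validate_plexus(self.plexus)
        _validate_laterality(self.laterality)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def scale_mm_per_px(self) -> float:
        return self.extent_mm / self.width


def read_sidecar(path: str | Path) -> dict:
    """Read a JSON metadata sidecar ``{extent_mm, plexus, laterality, visit_id}``."""
    with open(path) as fh:
        meta = json.load(fh)
    missing = {"extent_mm", "plexus", "laterality"} - set(meta)
    if missing:
        raise ValidationError(f"sidecar {path} missing keys {sorted(missing)}")
    return meta


def _decode_grayscale(path: str | Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageReadError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 3:
        # RGB(A) screenshots of OCTA exports: accept only if channels agree.
        rgb = arr[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
            raise ValidationError(f"{path}: colored image is not a grayscale angiogram")
        arr = rgb[..., 0]
    if arr.dtype != np.uint8:
        raise ValidationError(f"{path}: only 8-bit images are supported, got {arr.dtype}")
    return arr


def read_octa_image(
    path: str | Path,
    meta: Mapping | None = None,
    *,
    extent_mm: float | None = None,
    plexus: str | None = None,
    laterality: str | None = None,
    visit_id: str = "",
) -> OCTAImage:
    """Read an 8-bit PNG/TIFF angiogram together with its metadata.

    Metadata may be given as a mapping (e.g. a parsed sidecar) or as
    keyword arguments; keywords win over the mapping.
    """
    meta = dict(meta or {})
    extent_mm = extent_mm if extent_mm is not None else meta.get("extent_mm")
    plexus = plexus if plexus is not None else meta.get("plexus")
    laterality = laterality if laterality is not None else meta.get("laterality")
    visit_id = visit_id or meta.get("visit_id", "")
    if extent_mm is None or plexus is None or laterality is None:
        raise ValidationError(
            "extent_mm, plexus and laterality are required (sidecar or keyword)"
        )
    arr = _decode_grayscale(path)
    return OCTAImage(
        pixels=arr,
        extent_mm=float(extent_mm),
        plexus=plexus,
        laterality=laterality,
        visit_id=str(visit_id),
    )


def write_octa_image(image: OCTAImage, path: str | Path, sidecar: bool = False) -> None:
    """Write the pixel grid as an 8-bit grayscale PNG/TIFF (by extension).

    With ``sidecar=True`` a ``<path>.json`` metadata file is written next
    to the image so that :func:`read_octa_image` can recover it.
    """
    Image.fromarray(image.pixels, mode="L").save(path)
    if sidecar:
        meta = {
            "extent_mm": image.extent_mm,
            "plexus": image.plexus,
            "laterality": image.laterality,
            "visit_id": image.visit_id,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


@dataclass(frozen=True)
class CohortRow:
    visit_id: str
    va_decimal: float
    laterality: str
    scan_paths: dict = field(default_factory=dict)  # (plexus, extent_mm) -> path
    extras: dict = field(default_factory=dict)  # subgroup labels etc.

    def __post_init__(self) -> None:
        if not 0.0 <= self.va_decimal <= 1.0:
            raise ValidationError(
                f"visit {self.visit_id!r}: va_decimal {self.va_decimal} outside [0, 1]"
            )
        _validate_laterality(self.laterality)


@dataclass(frozen=True)
class CohortTable:
    rows: tuple

    def __post_init__(self) -> None:
        ids = [r.visit_id for r in self.rows]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate visit_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Required columns: ``visit_id``, ``va_decimal``, ``laterality`` and at
    least one of the four scan path columns (``path_scp3`` ...).  Any other
    column is preserved in ``CohortRow.extras`` (used for subgroup labels
    such as treatment or lens status).  Row order is preserved.
    """
    try:
        df = pd.read_csv(path, dtype={"visit_id": str})
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ValidationError(f"cannot read cohort CSV {path}: {exc}") from exc
    missing = set(_REQUIRED_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("cohort CSV has no data rows")
    known = set(_REQUIRED_COHORT_COLUMNS) | set(SCAN_PATH_COLUMNS.values())
    rows = []
    for idx, rec in df.iterrows():
        va = float(rec["va_decimal"])
        if not 0.0 <= va <= 1.0:
            raise ValidationError(
                f"row {idx} (visit {rec['visit_id']!r}): va_decimal {va} outside [0, 1]"
            )
        paths = {
            key: str(rec[col])
            for key, col in SCAN_PATH_COLUMNS.items()
            if col in df.columns and isinstance(rec[col], str) and rec[col]
        }
        extras = {c: rec[c] for c in df.columns if c not in known}
        rows.append(
            CohortRow(
                visit_id=str(rec["visit_id"]),
                va_decimal=va,
                laterality=str(rec["laterality"]),
                scan_paths=paths,
                extras=extras,
            )
        )
    return CohortTable(rows=tuple(rows))
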