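"""Vessel segmentation and skeletonization.

Binarization uses Otsu's histogram criterion: the threshold maximizing the
between-class variance of the two gray-level segments (equivalently, the
ratio of between- to within-class variance, since the two always sum to
the fixed total variance).  The vasculature mask is then reduced to a
one-pixel-wide skeleton with a two-subiteration parallel thinning, plus a
topology-preserving cleanup pass so that no 2x2 foreground block remains
wherever that is topologically possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateImageError, ValidationError
from .image_io import OCTAImage

_S8 = np.ones((3, 3), int)
_S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class OtsuResult:
    """Optimal histogram threshold and its variance decomposition.

    ``criterion_q`` is the between/within variance ratio; it is ``inf``
    for perfectly separable two-level images (within-class variance 0).
    """

    threshold: int
    between_var: float
    within_var: float
    criterion_q: float
    total_var: float


@dataclass(frozen=True)
class BinaryMask:
    """Binary vessel segmentation; same shape and scale as its source image."""

    pixels: np.ndarray
    scale_mm_per_px: float = float("nan")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            if not np.isin(px, (0, 1)).all():
                raise ValidationError("mask values must be 0/1")
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass(frozen=True)
class SkeletonMask:
    """One-pixel-wide skeleton of a :class:`BinaryMask`."""

    pixels: np.ndarray
    scale_mm_per_px: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def _as_array(image) -> np.ndarray:
    if isinstance(image, OCTAImage):
        return image.pixels
    return np.asarray(image)


def otsu_threshold(image) -> OtsuResult:
    """Find the gray level maximizing between-class variance.

    Accepts an :class:`OCTAImage` or a plain uint8 array.  A pixel belongs
    to the background class when its intensity is <= t.  Ties are broken
    toward the smallest threshold.  Raises :class:`DegenerateImageError`
    for constant images, which no threshold can partition.
    """
    arr = _as_array(image)
    hist = np.bincount(arr.ravel().astype(np.int64), minlength=256).astype(np.float64)
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    mean_total = (hist * levels).sum() / n
    total_var = (hist * (levels - mean_total) ** 2).sum() / n
    if total_var == 0.0:
        raise DegenerateImageError("constant image: no threshold partitions it")

    w0 = np.cumsum(hist)  # pixels with level <= t
    m0 = np.cumsum(hist * levels)
    w1 = n - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, m0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, (m0[-1] - m0) / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2, -np.inf)
    t = int(np.argmax(between))  # argmax takes the first (smallest) maximizer
    between_var = float(between[t])
    within_var = float(total_var - between_var)
    q = float("inf") if within_var <= 0 else between_var / within_var
    return OtsuResult(
        threshold=t,
        between_var=between_var,
        within_var=within_var,
        criterion_q=q,
        total_var=float(total_var),
    )


def binarize(image, t: int) -> BinaryMask:
    """Threshold: foreground (vessel) iff intensity strictly greater than ``t``.

    Vessels carry the bright flow signal in en-face OCTA, so foreground is
    the high-intensity class.
    """
    if not 0 <= t <= 255:
        raise ValidationError(f"threshold must be in [0, 255], got {t}")
    arr = _as_array(image)
    scale = image.scale_mm_per_px if isinstance(image, OCTAImage) else float("nan")
    return BinaryMask(pixels=arr > t, scale_mm_per_px=scale)


def _neighbors(img: np.ndarray):
    """P2..P9: the 8 neighbours of every pixel, clockwise from north."""
    p = np.pad(img, 1)
    return (
        p[:-2, 1:-1], p[:-2, 2:], p[1:-1, 2:], p[2:, 2:],
        p[2:, 1:-1], p[2:, :-2], p[1:-1, :-2], p[:-2, :-2],
    )


def _thin_parallel(mask: np.ndarray) -> np.ndarray:
    """Two-subiteration parallel thinning until stable."""
    img = mask.astype(np.uint8).copy()
    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            P2, P3, P4, P5, P6, P7, P8, P9 = _neighbors(img)
            B = P2 + P3 + P4 + P5 + P6 + P7 + P8 + P9
            seq = (P2, P3, P4, P5, P6, P7, P8, P9, P2)
            A = sum(
                ((seq[i] == 0) & (seq[i + 1] == 1)).astype(np.uint8) for i in range(8)
            )
            if step == 0:
                cond = (P2 * P4 * P6 == 0) & (P4 * P6 * P8 == 0)
            else:
                cond = (P2 * P4 * P8 == 0) & (P2 * P6 * P8 == 0)
            delete = (img == 1) & (B >= 2) & (B <= 6) & (A == 1) & cond
            if delete.any():
                img[delete] = 0
                changed = True
    return img.astype(bool)


def _is_simple(img: np.ndarray, r: int, c: int) -> bool:
    """8-simple point test: deletion preserves local foreground/background topology."""
    H, W = img.shape
    patch = np.zeros((3, 3), bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W:
                patch[dr + 1, dc + 1] = img[rr, cc]
    fg = patch.copy()
    fg[1, 1] = False
    if not fg.any():
        return False  # isolated pixel: deletion removes a component
    _, n_fg = ndimage.label(fg, structure=_S8)
    if n_fg != 1:
        return False
    bg = ~patch
    bg[1, 1] = True
    lab, _ = ndimage.label(bg, structure=_S4)
    comps = {lab[0, 1], lab[1, 0], lab[1, 2], lab[2, 1]} - {0}
    return len(comps) == 1


def _prune_2x2(img: np.ndarray) -> np.ndarray:
    """Sequentially delete simple points inside residual 2x2 blocks.

    Parallel thinning can leave 2x2 blocks at vessel junctions.  Each such
    block is reduced by deleting one topology-preserving pixel at a time,
    in deterministic raster order.  Blocks whose four pixels are all
    non-simple (four branches meeting diagonally) are left untouched:
    removing any pixel there would disconnect the skeleton.
    """
    img = img.copy()
    while True:
        block = img[:-1, :-1] & img[1:, :-1] & img[:-1, 1:] & img[1:, 1:]
        if not block.any():
            return img
        progress = False
        for r, c in zip(*np.nonzero(block)):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if img[rr, cc] and _is_simple(img, rr, cc):
                    img[rr, cc] = False
                    progress = True
                    break
        if not progress:
            return img


def skeletonize(mask: BinaryMask) -> SkeletonMask:
    """Thin the vessel mask to a one-pixel-wide skeleton.

    Guarantees: the skeleton is a subset of the mask; idempotent; every
    8-connected component of the mask keeps at least one skeleton pixel
    (small blobs the parallel rules would erase entirely are restored as
    a single pixel nearest their centroid).
    """
    src = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    scale = mask.scale_mm_per_px if isinstance(mask, BinaryMask) else float("nan")
    out = _prune_2x2(_thin_parallel(src))
    lab, n = ndimage.label(src, structure=_S8)
    if n:
        survived = np.zeros(n + 1, bool)
        survived[lab[out]] = True
        for i in range(1, n + 1):
            if not survived[i]:
                rs, cs = np.nonzero(lab == i)
                k = int(np.argmin((rs - rs.mean()) ** 2 + (cs - cs.mean()) ** 2))
                out[rs[k], cs[k]] = True
    return SkeletonMask(pixels=out, scale_mm_per_px=scale)
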