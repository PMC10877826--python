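"""Whole-slide image handling: reader abstraction, tissue segmentation
and multi-scale patch tiling.

Slides are accessed through :class:`SlideHandle`, which wraps either a
pyramidal TIFF (via ``tifffile``), a plain raster image (PNG/TIFF via
Pillow, treated as a single-level slide) or an in-memory array.  All
patch coordinates live in level-0 pixel space (0-based, half-open
boxes); per-scale pixel sizes are derived from the magnification ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from skimage import filters, measure, morphology
from skimage.color import rgb2hsv
from skimage.transform import resize

__all__ = [
    "ConfigurationError",
    "SlideHandle",
    "TissueMask",
    "PatchRef",
    "open_slide",
    "segment_tissue",
    "tile_patches",
    "read_patch",
    "patches_to_frame",
    "PATCH_SIZE",
]

PATCH_SIZE = 256
DEFAULT_BASE_MAG = 40.0

SCALE_MAG = {"5x": 5.0, "10x": 10.0, "20x": 20.0}


class ConfigurationError(ValueError):
    """Requested configuration cannot be realised (e.g. scale above base)."""


def _scale_mag(scale) -> float:
    if isinstance(scale, str):
        key = scale.lower()
        if key not in SCALE_MAG:
            raise ConfigurationError(f"unknown scale {scale!r}; expected 5x/10x/20x")
        return SCALE_MAG[key]
    return float(scale)


def scale_name(mag: float) -> str:
    return f"{mag:g}x"


class SlideHandle:
    """Uniform access to pyramidal or single-level slides.

    Attributes
    ----------
    id : slide identifier (file stem by default)
    level_dims : list of (width, height) per pyramid level, level 0 first
    mag_per_level : nominal magnification per level, decreasing
    path : source file, or ``None`` for in-memory slides
    """

    def __init__(self, id: str, levels: List[np.ndarray],
                 base_mag: Optional[float] = None, path: Optional[str] = None):
        if not levels:
            raise IOError("slide has no image levels")
        self._levels = [np.ascontiguousarray(lv) for lv in levels]
        self.id = id
        self.path = path
        self.level_dims = [(lv.shape[1], lv.shape[0]) for lv in self._levels]
        w0 = self.level_dims[0][0]
        for (w, _), (w2, _) in zip(self.level_dims, self.level_dims[1:]):
            if w2 > w:
                raise ValueError("pyramid level dims must be non-increasing")
        if base_mag is None:
            warnings.warn(
                f"slide {id!r} has no magnification metadata; assuming level 0 = "
                f"{DEFAULT_BASE_MAG:g}x", stacklevel=2)
            base_mag = DEFAULT_BASE_MAG
        self.mag_per_level = [base_mag * (w / w0) for w, _ in self.level_dims]

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_array(cls, image: np.ndarray, id: str = "slide",
                   base_mag: float = DEFAULT_BASE_MAG) -> "SlideHandle":
        image = np.asarray(image)
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        return cls(id, [image.astype(np.uint8)], base_mag=base_mag)

    # -- geometry -----------------------------------------------------------
    @property
    def dimensions(self) -> Tuple[int, int]:
        return self.level_dims[0]

    def _best_level_for(self, downscale: float) -> int:
        w0 = self.level_dims[0][0]
        best, best_ds = 0, 1.0
        for i, (w, _) in enumerate(self.level_dims):
            ds = w0 / w
            if ds <= downscale + 1e-9:
                best, best_ds = i, ds
        return best

    def read_region(self, x: int, y: int, w: int, h: int,
                    out_size: Optional[Tuple[int, int]] = None) -> np.ndarray:
        """Read the level-0 box ``[x, x+w) x [y, y+h)`` as RGB uint8,
        resampled (bilinear) to ``out_size = (out_w, out_h)`` if given.

        The closest pyramid level at least as fine as the requested output
        resolution is used as the source.
        """
        W0, H0 = self.dimensions
        if x < 0 or y < 0 or x + w > W0 or y + h > H0:
            raise ValueError(f"region [{x},{x + w})x[{y},{y + h}) exceeds slide bounds")
        if out_size is None:
            level = 0
        else:
            level = self._best_level_for(w / out_size[0])
        ds = self.level_dims[0][0] / self.level_dims[level][0]
        lx, ly = int(math.floor(x / ds)), int(math.floor(y / ds))
        lw = max(1, int(round(w / ds)))
        lh = max(1, int(round(h / ds)))
        img = self._levels[level][ly: ly + lh, lx: lx + lw]
        if out_size is not None and (img.shape[1], img.shape[0]) != tuple(out_size):
            img = resize(img, (out_size[1], out_size[0]), order=1,
                         preserve_range=True, anti_aliasing=False)
        return np.clip(img, 0, 255).astype(np.uint8)

    def thumbnail(self, downscale: int) -> np.ndarray:
        """Whole-slide RGB thumbnail of shape ``ceil(dims / downscale)``."""
        W0, H0 = self.dimensions
        out = (math.ceil(H0 / downscale), math.ceil(W0 / downscale))
        level = self._best_level_for(downscale)
        img = self._levels[level]
        if img.shape[:2] != out:
            img = resize(img, out, order=1, preserve_range=True, anti_aliasing=True)
        return np.clip(img, 0, 255).astype(np.uint8)


def open_slide(path, id: Optional[str] = None,
               base_mag: Optional[float] = None) -> SlideHandle:
    """Open a pyramidal TIFF or plain raster image as a slide.

    Plain images become single-level slides; missing magnification
    metadata falls back to 40x for level 0 (with a warning), overridable
    via ``base_mag``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"slide file not found: {path}")
    sid = id or path.stem
    if path.suffix.lower() in (".tif", ".tiff", ".svs"):
        import tifffile

        try:
            with tifffile.TiffFile(str(path)) as tf:
                series = tf.series[0]
                levels = [lvl.asarray() for lvl in series.levels]
        except Exception as exc:  # pragma: no cover - corrupt input
            raise IOError(f"cannot read slide {path}: {exc}") from exc
        levels = [lv[..., :3] if lv.ndim == 3 else np.stack([lv] * 3, -1)
                  for lv in levels]
        return SlideHandle(sid, levels, base_mag=base_mag, path=str(path))
    try:
        img = np.asarray(Image.open(path).convert("RGB"))
    except Exception as exc:
        raise IOError(f"cannot read slide {path}: {exc}") from exc
    return SlideHandle(sid, [img], base_mag=base_mag, path=str(path))


# ---------------------------------------------------------------------------
# tissue segmentation
# ---------------------------------------------------------------------------

@dataclass
class TissueMask:
    """Binary tissue mask at the segmentation working resolution."""

    mask: np.ndarray
    downscale: int
    contours: List[np.ndarray] = field(default_factory=list)
    is_empty: bool = False

    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


# saturation below this on a [0,1] scale is considered unstained glass
_MIN_SATURATION = 0.05


def segment_tissue(slide: SlideHandle, downscale: int = 8,
                   min_region_area: int = 64) -> TissueMask:
    """Threshold-based tissue detection on a downscaled slide.

    The thumbnail is converted to HSV; the saturation channel (high for
    stained tissue, ~0 for white glass) is median-filtered, thresholded
    with Otsu's method and cleaned up by morphological closing and
    removal of connected components below ``min_region_area`` pixels.
    Deterministic for a fixed input.  A slide with no detectable stain
    yields an all-background mask flagged ``is_empty`` (with a warning),
    not an error.
    """
    if downscale < 1:
        raise ValueError("downscale must be >= 1")
    thumb = slide.thumbnail(downscale).astype(float) / 255.0
    sat = rgb2hsv(thumb)[..., 1]
    from scipy.ndimage import median_filter

    sat = median_filter(sat, size=3)
    if float(sat.max()) < _MIN_SATURATION:
        warnings.warn(f"slide {slide.id!r}: no stained tissue detected", stacklevel=2)
        return TissueMask(np.zeros(sat.shape, dtype=bool), downscale, [], is_empty=True)
    thr = filters.threshold_otsu(sat)
    mask = sat > max(thr, _MIN_SATURATION)
    mask = morphology.closing(mask, morphology.disk(2))
    mask = morphology.remove_small_objects(mask, max_size=int(min_region_area) - 1)
    mask = morphology.remove_small_holes(mask, max_size=int(min_region_area) - 1)
    if not mask.any():
        warnings.warn(f"slide {slide.id!r}: no stained tissue detected", stacklevel=2)
        return TissueMask(mask, downscale, [], is_empty=True)
    contours = measure.find_contours(mask.astype(float), 0.5)
    return TissueMask(mask, downscale, contours, is_empty=False)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchRef:
    """One 256x256 patch at a given magnification.

    ``(x, y)`` is the top-left corner in level-0 pixels; the box is the
    half-open ``[x, x+w) x [y, y+h)`` where ``w = h = 256 * base_mag/mag``.
    """

    slide_id: str
    scale: str          # "5x" / "10x" / "20x"
    x: int
    y: int
    w: int
    h: int
    size_at_scale: int = PATCH_SIZE
    stride: int = PATCH_SIZE  # stride at the target scale, pixels

    @property
    def mag(self) -> float:
        return _scale_mag(self.scale)


def tissue_fraction_of_box(mask: np.ndarray, downscale: int,
                           x: int, y: int, w: int, h: int) -> float:
    """Mean mask coverage of a level-0 box mapped to mask coordinates."""
    x0 = int(x // downscale)
    y0 = int(y // downscale)
    x1 = min(int(math.ceil((x + w) / downscale)), mask.shape[1])
    y1 = min(int(math.ceil((y + h) / downscale)), mask.shape[0])
    window = mask[y0:y1, x0:x1]
    return float(window.mean()) if window.size else 0.0


def tile_patches(slide: SlideHandle, mask: TissueMask, scale,
                 overlap: float = 0.0, tissue_frac_min: float = 0.5) -> List[PatchRef]:
    """Enumerate 256x256 patches at ``scale`` covering the tissue mask.

    The stride at the target scale is ``256 * (1 - overlap)``; a patch is
    kept iff its tissue-covered fraction is at least ``tissue_frac_min``.
    Enumeration is row-major (y outer, x inner) and fully deterministic;
    for ``overlap = 0`` the kept boxes are pairwise disjoint.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    mag = _scale_mag(scale)
    base_mag = slide.mag_per_level[0]
    if mag > base_mag + 1e-9:
        raise ConfigurationError(
            f"scale {mag:g}x not representable: slide base magnification "
            f"is {base_mag:g}x")
    ratio = base_mag / mag
    w0 = int(round(PATCH_SIZE * ratio))
    stride_scale = PATCH_SIZE * (1.0 - overlap)
    stride0 = max(1, int(round(stride_scale * ratio)))
    W0, H0 = slide.dimensions
    name = scale if isinstance(scale, str) else scale_name(mag)

    # integral image for O(1) tissue-fraction queries
    m = mask.mask.astype(np.int64)
    ii = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = m.cumsum(0).cumsum(1)
    ds = mask.downscale

    out: List[PatchRef] = []
    for y in range(0, H0 - w0 + 1, stride0):
        y0 = y // ds
        y1 = min(math.ceil((y + w0) / ds), m.shape[0])
        for x in range(0, W0 - w0 + 1, stride0):
            x0 = x // ds
            x1 = min(math.ceil((x + w0) / ds), m.shape[1])
            area = (y1 - y0) * (x1 - x0)
            if area <= 0:
                continue
            covered = ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]
            if covered / area >= tissue_frac_min:
                out.append(PatchRef(slide_id=slide.id, scale=name, x=x, y=y,
                                    w=w0, h=w0, stride=int(round(stride_scale))))
    return out


def read_patch(slide: SlideHandle, ref: PatchRef) -> np.ndarray:
    """Extract a patch as a 256x256 RGB uint8 array (bilinear resampling
    from the nearest adequate pyramid level when the ratio is non-unit)."""
    return slide.read_region(ref.x, ref.y, ref.w, ref.h,
                             out_size=(ref.size_at_scale, ref.size_at_scale))


def patches_to_frame(patches: Sequence[PatchRef]):
    """Patch manifest as a DataFrame (slide_id, scale, x, y, w, h)."""
    import pandas as pd

    return pd.DataFrame(
        [(p.slide_id, p.scale, p.x, p.y, p.w, p.h) for p in patches],
        columns=["slide_id", "scale", "x", "y", "w", "h"],
    )
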