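"""Slide loading, tile extraction, and HSV color-threshold fibrosis segmentation.

The fibrosis signal in a Masson's-trichrome section is the blue-green
collagen stain. Segmentation is a pointwise HSV box: a pixel is fibrotic iff
its hue lies in ``[hue_min, hue_max]`` degrees (red at 0°, green at 120°, on
the full 0–360 circle — note many imaging libraries use a 0–179 half-scale,
this module does not), its saturation is at least ``sat_min`` (excludes
near-white background and glass), and its value lies in
``[val_min, val_max]`` (excludes glare above, hematoxylin-dark nuclei below).

The default box is an implementation choice, not measured ground truth — the
original threshold was picked by eye — so every output records the
parameters used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.color import rgb2hsv
from skimage.draw import polygon2mask

from .errors import DegenerateInputError, ImageError, OutOfBoundsError, UnsupportedDepthError

#: sentinel returned by tile_window under edge_policy="skip"
SKIP = None

DEFAULT_TILE_SIZE = 512


@dataclass
class SlideImage:
    """An 8-bit RGB section image (H x W x 3, channel order always RGB)."""

    pixels: np.ndarray
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageError(f"expected H x W x 3 RGB array, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise UnsupportedDepthError(
                f"expected 8-bit pixels, got dtype {px.dtype}; no silent rescale"
            )
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class TileWindow:
    """Axis-aligned half-open pixel window sampled around a tubule centroid."""

    tubule_id: str
    x0: int
    y0: int
    x1: int
    y1: int
    nominal_size: int = DEFAULT_TILE_SIZE
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise DegenerateInputError(f"empty window {self}")
        if not self.clipped:
            assert (self.x1 - self.x0) == (self.y1 - self.y0) == self.nominal_size

    @property
    def area_px(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def crop(self, image: SlideImage) -> np.ndarray:
        return image.pixels[self.y0 : self.y1, self.x0 : self.x1]


@dataclass(frozen=True)
class FibrosisParams:
    """HSV box defining which pixels count as fibrosis."""

    hue_min: float = 90.0
    hue_max: float = 180.0
    sat_min: float = 0.15
    val_min: float = 0.20
    val_max: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.hue_min < self.hue_max <= 360.0):
            raise ValueError(f"need 0 <= hue_min < hue_max <= 360, got {self}")
        for name in ("sat_min", "val_min", "val_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "hue_min": self.hue_min,
            "hue_max": self.hue_max,
            "sat_min": self.sat_min,
            "val_min": self.val_min,
            "val_max": self.val_max,
        }


@dataclass
class FibrosisMask:
    """Boolean per-pixel fibrosis mask for one tile, plus provenance."""

    mask: np.ndarray
    params_used: FibrosisParams
    excluded_px: int = 0  # pixels removed from the denominator by the exclusion polygon


def load_image(path) -> SlideImage:
    """Load a TIFF or PNG section image as 8-bit RGB (alpha dropped)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise ImageError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(
            f"{path}: bit depth {arr.dtype} unsupported; expected 8-bit"
        )
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ImageError(f"{path}: expected 3 or 4 channels, got shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return SlideImage(pixels=np.ascontiguousarray(arr), source_path=str(path))


def tile_window(
    centroid: tuple[float, float],
    nominal_size: int,
    image_dims: tuple[int, int],
    edge_policy: str = "clip",
    tubule_id: str = "",
) -> Optional[TileWindow]:
    """Compute the half-open pixel window of size ``nominal_size`` centered on a tubule.

    ``image_dims`` is (W, H). Under ``edge_policy="clip"`` an out-of-image
    window is intersected with the image and marked clipped; under ``"skip"``
    it yields ``None``. A centroid outside the image raises
    :class:`OutOfBoundsError`.
    """
    if nominal_size < 2 or nominal_size % 2 != 0:
        raise ValueError(f"nominal_size must be even and >= 2, got {nominal_size}")
    if edge_policy not in ("clip", "skip"):
        raise ValueError(f"edge_policy must be 'clip' or 'skip', got {edge_policy!r}")
    cx, cy = centroid
    W, H = image_dims
    if not (0 <= cx < W and 0 <= cy < H):
        raise OutOfBoundsError(
            f"centroid ({cx}, {cy}) outside image bounds {W} x {H}"
        )
    half = nominal_size / 2.0
    x0 = int(np.floor(cx - half + 0.5))
    y0 = int(np.floor(cy - half + 0.5))
    x1, y1 = x0 + nominal_size, y0 + nominal_size
    in_bounds = x0 >= 0 and y0 >= 0 and x1 <= W and y1 <= H
    if in_bounds:
        return TileWindow(tubule_id, x0, y0, x1, y1, nominal_size, clipped=False)
    if edge_policy == "skip":
        return SKIP
    return TileWindow(
        tubule_id,
        max(x0, 0),
        max(y0, 0),
        min(x1, W),
        min(y1, H),
        nominal_size,
        clipped=True,
    )


def segment_fibrosis(
    tile_pixels: np.ndarray,
    params: FibrosisParams,
    exclusion_polygon: Optional[Sequence[tuple[float, float]]] = None,
) -> FibrosisMask:
    """Classify each tile pixel as fibrotic or not by the HSV box.

    ``exclusion_polygon`` (tile-local (x, y) vertices, e.g. the annotated
    tubule's own interior) forces its pixels non-fibrotic; the number of
    excluded pixels is reported so the metric denominator can be adjusted.
    """
    px = np.asarray(tile_pixels)
    if px.size == 0:
        raise DegenerateInputError("empty tile")
    if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
        raise DegenerateInputError(
            f"tile must be 8-bit RGB (H x W x 3 uint8), got {px.shape} {px.dtype}"
        )
    hsv = rgb2hsv(px)
    hue = hsv[:, :, 0] * 360.0
    sat = hsv[:, :, 1]
    val = hsv[:, :, 2]
    mask = (
        (hue >= params.hue_min)
        & (hue <= params.hue_max)
        & (sat >= params.sat_min)
        & (val >= params.val_min)
        & (val <= params.val_max)
    )
    excluded_px = 0
    if exclusion_polygon is not None:
        poly_rc = [(y, x) for x, y in exclusion_polygon]  # polygon2mask wants (row, col)
        inside = polygon2mask(mask.shape, np.asarray(poly_rc, dtype=float))
        excluded_px = int(inside.sum())
        mask &= ~inside
    return FibrosisMask(mask=mask, params_used=params, excluded_px=excluded_px)
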