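"""Whole-slide-image front-end: tiling, tissue filtering, feature extraction.

Turns a slide into one MIL bag: a regular grid of non-overlapping square
tiles (default 512 px), a saturation-Otsu tissue mask to discard mostly
background tiles, and a pluggable per-tile feature extractor.  Slide access
goes through a small reader contract; plain RGB arrays and PNG/TIFF images
are supported directly, and pyramid formats can be plugged in behind the
same contract.

Coordinates are 0-based pixels with half-open extents [x0, x0+size).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence
import warnings

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .data import Bag

__all__ = [
    "Tile",
    "TissueMask",
    "FeatureExtractor",
    "SlideReader",
    "ArraySlide",
    "ImageSlide",
    "tile_slide",
    "tissue_mask",
    "tissue_filter",
    "extract_features",
    "ColorHistogramExtractor",
    "slide_to_bag",
]


@dataclass(frozen=True)
class Tile:
    """One square patch: top-left corner (x0, y0), side length, nominal power."""

    x0: int
    y0: int
    size: int
    level_magnification: float = 20.0

    def __post_init__(self):
        if self.x0 < 0 or self.y0 < 0 or self.size <= 0:
            raise ValueError("tile coordinates must be non-negative, size positive")


@dataclass
class TissueMask:
    """Binary tissue map at a stated integer downsample of the slide."""

    mask: np.ndarray  # (H/ds, W/ds), entries in {0, 1}
    downsample: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    def non_tissue_fraction(self, tile: Tile) -> float:
        ds = self.downsample
        r0, r1 = tile.y0 // ds, -(-(tile.y0 + tile.size) // ds)
        c0, c1 = tile.x0 // ds, -(-(tile.x0 + tile.size) // ds)
        if r1 > self.mask.shape[0] or c1 > self.mask.shape[1]:
            raise ValueError(
                f"tile ({tile.x0},{tile.y0},{tile.size}) exceeds mask extent "
                f"{self.mask.shape} at downsample {ds}"
            )
        window = self.mask[r0:r1, c0:c1]
        return float(1.0 - window.mean())


class SlideReader(Protocol):
    """Reader contract: pixel dimensions plus region access at full resolution."""

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        ...

    def read_region(self, x0: int, y0: int, size: int) -> np.ndarray:
        """RGB uint8 array of shape (size, size, 3)."""
        ...


class ArraySlide:
    """In-memory RGB array behind the reader contract (fixtures, tests)."""

    def __init__(self, rgb: np.ndarray):
        rgb = np.asarray(rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB array")
        self.rgb = rgb.astype(np.uint8)

    @property
    def dimensions(self) -> tuple[int, int]:
        h, w = self.rgb.shape[:2]
        return (w, h)

    def read_region(self, x0: int, y0: int, size: int) -> np.ndarray:
        region = self.rgb[y0 : y0 + size, x0 : x0 + size]
        if region.shape[:2] != (size, size):
            raise IOError(f"region ({x0},{y0},{size}) outside slide bounds")
        return region


class ImageSlide(ArraySlide):
    """PNG/TIFF image file behind the reader contract (via Pillow)."""

    def __init__(self, path: str | Path):
        with Image.open(path) as im:
            super().__init__(np.asarray(im.convert("RGB")))
        self.path = Path(path)


# ----------------------------------------------------------------------
# Tiling
# ----------------------------------------------------------------------

def tile_slide(width: int, height: int, tile_size: int = 512,
               level_magnification: float = 20.0) -> list[Tile]:
    """Non-overlapping grid tiles in row-major order.

    Returns floor(width/tile_size) × floor(height/tile_size) tiles; partial
    border tiles are dropped.  An oversized tile_size yields an empty list
    with a warning rather than an error.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if tile_size > min(width, height):
        warnings.warn(
            f"tile_size {tile_size} exceeds slide extent ({width}x{height}); "
            "no tiles produced"
        )
        return []
    nx, ny = width // tile_size, height // tile_size
    return [
        Tile(x0=ix * tile_size, y0=iy * tile_size, size=tile_size,
             level_magnification=level_magnification)
        for iy in range(ny)
        for ix in range(nx)
    ]


# ----------------------------------------------------------------------
# Tissue detection and filtering
# ----------------------------------------------------------------------

def tissue_mask(slide: SlideReader | np.ndarray, downsample: int = 32) -> TissueMask:
    """Otsu threshold on the HSV saturation channel of a downsampled thumbnail.

    Stained tissue is saturated; glass background is not.  This is the
    common histopathology default when no annotation exists.
    """
    rgb = slide.rgb if isinstance(slide, ArraySlide) else np.asarray(slide)
    thumb = rgb[::downsample, ::downsample]
    sat = rgb2hsv(thumb)[..., 1]
    if np.ptp(sat) < 1e-12:  # uniform image: Otsu undefined
        return TissueMask(mask=np.zeros(sat.shape, dtype=np.uint8),
                          downsample=downsample)
    thr = threshold_otsu(sat)
    return TissueMask(mask=(sat > thr).astype(np.uint8), downsample=downsample)


def tissue_filter(tiles: Sequence[Tile], mask: TissueMask,
                  max_background: float = 0.5) -> list[Tile]:
    """Keep tiles whose non-tissue fraction is <= max_background.

    Tiles *strictly* above the threshold are discarded; a tile at exactly
    the threshold is kept.  Output preserves input order.
    """
    if not (0 <= max_background <= 1):
        raise ValueError("max_background must be in [0, 1]")
    return [t for t in tiles if mask.non_tissue_fraction(t) <= max_background]


# ----------------------------------------------------------------------
# Feature extraction
# ----------------------------------------------------------------------

class FeatureExtractor(Protocol):
    """Deterministic map from an RGB tile array to a fixed-length vector."""

    @property
    def feature_dim(self) -> int: ...

    def __call__(self, rgb: np.ndarray) -> np.ndarray: ...


class ColorHistogramExtractor:
    """Per-channel color histogram, 8 bins each by default (d = 24).

    Deterministic and dependency-free; the default extractor for tests and
    fixtures.  A pretrained CNN backbone (e.g. a ResNet-18 trunk) drops in
    behind the same contract for real slides.
    """

    def __init__(self, bins_per_channel: int = 8):
        self.bins = bins_per_channel

    @property
    def feature_dim(self) -> int:
        return 3 * self.bins

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        rgb = np.asarray(rgb)
        feats = [
            np.histogram(rgb[..., c], bins=self.bins, range=(0, 256))[0]
            for c in range(3)
        ]
        out = np.concatenate(feats).astype(np.float64)
        return out / out.sum()


def extract_features(tiles: Sequence[Tile], slide: SlideReader,
                     extractor: FeatureExtractor) -> np.ndarray:
    """(n_tiles, d) matrix; row i is the extractor applied to tile i."""
    rows = []
    for t in tiles:
        try:
            region = slide.read_region(t.x0, t.y0, t.size)
        except Exception as exc:
            raise IOError(f"failed to read tile ({t.x0},{t.y0},{t.size}): {exc}")
        rows.append(extractor(region))
    if not rows:
        return np.empty((0, extractor.feature_dim))
    return np.vstack(rows)


def slide_to_bag(slide: SlideReader, bag_id: str, label: int,
                 extractor: FeatureExtractor | None = None,
                 tile_size: int = 512, max_background: float = 0.5,
                 mask_downsample: int = 32) -> tuple[Bag, list[Tile]]:
    """Full front-end: tile, tissue-filter, extract — one bag per slide.

    Returns the bag and the kept tiles (aligned with the bag's rows) so
    attention scores can be mapped back to slide coordinates.
    """
    extractor = extractor or ColorHistogramExtractor()
    w, h = slide.dimensions
    tiles = tile_slide(w, h, tile_size)
    mask = tissue_mask(slide, downsample=mask_downsample)
    kept = tissue_filter(tiles, mask, max_background)
    if not kept:
        raise ValueError(f"slide {bag_id!r}: no tiles passed the tissue filter")
    X = extract_features(kept, slide, extractor)
    return Bag(bag_id=bag_id, instances=X, label=label), kept
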