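"""Slide reading, magnification handling, grid tiling and tissue masking.

Conventions used throughout the package: 0-based pixel coordinates with x
as column and y as row, half-open windows ``[x, x+size) x [y, y+size)``,
and all tile positions expressed at the working magnification.  Right and
bottom margins not covered by a full tile are dropped; max-aggregation at
the slide level is insensitive to a thin margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.transform import resize

from milwsi import constants


@dataclass(frozen=True)
class TileSpec:
    """One grid cell: top-left corner (x, y), square side, and grid indices."""

    x: int
    y: int
    size: int
    row: int
    col: int


class SlideImage:
    """An in-memory slide at working magnification with a block pixel accessor."""

    def __init__(
        self,
        slide_id: str,
        pixels: np.ndarray,
        base_magnification: float = 10.0,
        working_magnification: float = 10.0,
    ) -> None:
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError("slide pixels must be (H, W, 3)")
        if working_magnification > base_magnification:
            raise ValueError(
                f"working magnification {working_magnification} exceeds base {base_magnification}"
            )
        self.slide_id = slide_id
        self._pixels = pixels
        self.base_magnification = float(base_magnification)
        self.working_magnification = float(working_magnification)

    @property
    def height(self) -> int:
        return self._pixels.shape[0]

    @property
    def width(self) -> int:
        return self._pixels.shape[1]

    def read_block(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        """RGB block at working magnification; half-open window."""
        if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
            raise ValueError(
                f"block ({x},{y},{w},{h}) outside slide {self.slide_id} "
                f"({self.width}x{self.height})"
            )
        return self._pixels[y : y + h, x : x + w]

    def thumbnail(self, max_side: int = 512) -> np.ndarray:
        f = max(self.width, self.height) / max_side
        if f <= 1:
            return self._pixels.copy()
        out_h, out_w = int(self.height / f), int(self.width / f)
        return (
            resize(self._pixels, (out_h, out_w), anti_aliasing=True, preserve_range=True)
            .astype(np.uint8)
        )


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def _area_downsample(pixels: np.ndarray, factor: Fraction) -> np.ndarray:
    """Area-averaging downsample by a rational factor >= 1."""
    if factor == 1:
        return pixels
    h, w = pixels.shape[:2]
    out_h = int(h / factor)
    out_w = int(w / factor)
    if factor.denominator == 1:
        f = factor.numerator
        hh, ww = out_h * f, out_w * f
        block = pixels[:hh, :ww].reshape(out_h, f, out_w, f, 3)
        return block.mean(axis=(1, 3)).round().astype(np.uint8)
    return (
        resize(pixels, (out_h, out_w), anti_aliasing=True, preserve_range=True)
        .round()
        .astype(np.uint8)
    )


def load_slide(
    image_path: str | Path,
    target_magnification: float = 10.0,
    base_magnification: float | None = None,
    slide_id: str | None = None,
) -> SlideImage:
    """Load a raster slide and downsample it to the working magnification.

    If no base magnification is known (neither passed nor in a manifest),
    the file is treated as already at the target.  Upsampling is refused.
    """
    path = Path(image_path)
    if not path.exists():
        raise FileNotFoundError(f"slide image not found: {path}")
    base = float(base_magnification) if base_magnification is not None else float(target_magnification)
    if target_magnification > base:
        raise ValueError(
            f"target magnification {target_magnification} exceeds base {base} for {path.name}"
        )
    pixels = _read_raster(path)
    factor = Fraction(base).limit_denominator(1000) / Fraction(float(target_magnification)).limit_denominator(1000)
    pixels = _area_downsample(pixels, factor)
    return SlideImage(
        slide_id=slide_id or path.stem,
        pixels=pixels,
        base_magnification=base,
        working_magnification=float(target_magnification),
    )


def tile_grid(width: int, height: int, tile_size: int, stride: int) -> list[TileSpec]:
    """Row-major grid of fully-contained square tiles.

    Count is ``(floor((W-T)/S)+1) * (floor((H-T)/S)+1)`` when both dims hold
    at least one tile, else the empty list.
    """
    if tile_size <= 0 or stride <= 0:
        raise ValueError("tile_size and stride must be positive")
    if width < tile_size or height < tile_size:
        return []
    n_cols = (width - tile_size) // stride + 1
    n_rows = (height - tile_size) // stride + 1
    return [
        TileSpec(x=c * stride, y=r * stride, size=tile_size, row=r, col=c)
        for r in range(n_rows)
        for c in range(n_cols)
    ]


class TissueMask:
    """Boolean tissue raster at slide resolution with per-tile coverage."""

    def __init__(self, mask: np.ndarray) -> None:
        self.mask = mask

    def tissue_fraction(self, tile: TileSpec) -> float:
        window = self.mask[tile.y : tile.y + tile.size, tile.x : tile.x + tile.size]
        return float(window.mean()) if window.size else 0.0


def tissue_mask(slide: SlideImage) -> TissueMask:
    """Background = near-white pixels (every channel above the whiteness cut)."""
    pixels = slide.read_block(0, 0, slide.width, slide.height)
    return TissueMask(pixels.min(axis=2) < constants.TISSUE_MIN_CHANNEL_BELOW)


def extract_tile(slide: SlideImage, tile: TileSpec) -> np.ndarray:
    """Exactly size x size RGB pixels at working magnification."""
    return slide.read_block(tile.x, tile.y, tile.size, tile.size)
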