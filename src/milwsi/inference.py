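"""Sliding-window slide scoring, max-probability aggregation and heatmaps.

A slide's carcinoma probability is the maximum probability over its scored
tiles (background cells are excluded so they can neither dilute nor
dominate the maximum).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from PIL import Image

from milwsi import constants
from milwsi.wsi import SlideImage, extract_tile, tile_grid, tissue_mask


@dataclass
class ProbabilityMap:
    """Per-grid-cell carcinoma probabilities; NaN marks filtered cells."""

    slide_id: str
    values: np.ndarray  # (rows, cols) float, NaN = missing
    stride: int
    tile_size: int

    @property
    def n_scored(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass(frozen=True)
class SlidePrediction:
    slide_id: str
    probability: float
    predicted_label: str
    n_tiles_scored: int


def score_slide(
    model,
    slide: SlideImage,
    tile_size: int = 512,
    stride: int = 256,
    tissue_threshold: float = 0.1,
) -> ProbabilityMap:
    """Score every tissue tile of the grid in inference mode."""
    tiles = tile_grid(slide.width, slide.height, tile_size, stride)
    if not tiles:
        raise ValueError(f"slide {slide.slide_id} is smaller than one tile")
    mask = tissue_mask(slide)
    n_rows = max(t.row for t in tiles) + 1
    n_cols = max(t.col for t in tiles) + 1
    values = np.full((n_rows, n_cols), np.nan)
    keep = [t for t in tiles if mask.tissue_fraction(t) >= tissue_threshold]
    if not keep:
        raise ValueError(f"slide {slide.slide_id} has no scorable tissue tiles")
    batch = np.stack([extract_tile(slide, t) for t in keep])
    probs = model.predict_proba(batch)
    for t, p in zip(keep, probs):
        values[t.row, t.col] = float(p)
    return ProbabilityMap(slide_id=slide.slide_id, values=values, stride=stride, tile_size=tile_size)


def aggregate_slide(pmap: ProbabilityMap, threshold: float = 0.5) -> SlidePrediction:
    """Slide probability = maximum over scored cells."""
    finite = pmap.values[np.isfinite(pmap.values)]
    if finite.size == 0:
        raise ValueError(f"probability map for {pmap.slide_id} has no scored cells")
    prob = float(finite.max())
    label = "carcinoma" if prob >= threshold else "non_neoplastic"
    return SlidePrediction(
        slide_id=pmap.slide_id,
        probability=prob,
        predicted_label=label,
        n_tiles_scored=int(finite.size),
    )


def render_heatmap(pmap: ProbabilityMap, slide_thumbnail: np.ndarray) -> np.ndarray:
    """Overlay the probability map on a slide thumbnail.

    Cell colours follow a fixed monotone colour ramp of probability; missing
    cells leave the thumbnail untouched.  Output has the thumbnail's shape.
    """
    th, tw = slide_thumbnail.shape[:2]
    rows, cols = pmap.values.shape
    slide_w = (cols - 1) * pmap.stride + pmap.tile_size
    slide_h = (rows - 1) * pmap.stride + pmap.tile_size
    if abs(tw / slide_w - th / slide_h) > 0.05 * (th / slide_h):
        raise ValueError("thumbnail aspect ratio does not match the probability map")

    cmap = plt.get_cmap(constants.HEATMAP_COLORMAP)
    out = slide_thumbnail.astype(np.float64).copy()
    sx = tw / slide_w
    sy = th / slide_h
    for r in range(rows):
        for c in range(cols):
            v = pmap.values[r, c]
            if not np.isfinite(v):
                continue
            x0 = int(c * pmap.stride * sx)
            y0 = int(r * pmap.stride * sy)
            x1 = min(int((c * pmap.stride + pmap.tile_size) * sx), tw)
            y1 = min(int((r * pmap.stride + pmap.tile_size) * sy), th)
            colour = np.asarray(cmap(float(v))[:3]) * 255.0
            a = constants.HEATMAP_ALPHA
            out[y0:y1, x0:x1] = (1 - a) * out[y0:y1, x0:x1] + a * colour
    return np.clip(out, 0, 255).astype(np.uint8)


def write_probability_map(pmap: ProbabilityMap, path: str | Path) -> None:
    """Persist a map as TSV with a 4-line header."""
    with open(path, "w") as fh:
        fh.write(f"# slide_id\t{pmap.slide_id}\n")
        fh.write(f"# dims\t{pmap.values.shape[0]}\t{pmap.values.shape[1]}\n")
        fh.write(f"# stride\t{pmap.stride}\n")
        fh.write(f"# tile_size\t{pmap.tile_size}\n")
        for row in pmap.values:
            fh.write("\t".join("NA" if not np.isfinite(v) else f"{v:.6f}" for v in row) + "\n")


def read_probability_map(path: str | Path) -> ProbabilityMap:
    lines = Path(path).read_text().splitlines()
    slide_id = lines[0].split("\t")[1]
    rows, cols = int(lines[1].split("\t")[1]), int(lines[1].split("\t")[2])
    stride = int(lines[2].split("\t")[1])
    tile_size = int(lines[3].split("\t")[1])
    values = np.full((rows, cols), np.nan)
    for r, line in enumerate(lines[4 : 4 + rows]):
        for c, tok in enumerate(line.split("\t")):
            if tok != "NA":
                values[r, c] = float(tok)
    return ProbabilityMap(slide_id=slide_id, values=values, stride=stride, tile_size=tile_size)


def save_heatmap_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image).save(path)
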