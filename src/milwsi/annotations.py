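"""Region annotations, tile label assignment and the slide-label priority rule.

Tile labels are assigned by majority coverage: the class whose regions
cover the largest fraction of a tile wins, provided that fraction reaches
``min_overlap``; ties go to carcinoma, and tiles below the threshold are
``unlabelled``.  A slide containing any carcinoma region is labelled
carcinoma regardless of its other regions (the diagnosis priority rule).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from shapely import affinity
from shapely.geometry import Polygon, box, shape

from milwsi.wsi import SlideImage, TileSpec, tile_grid, tissue_mask

logger = logging.getLogger(__name__)

LABEL_CARCINOMA = "carcinoma"
LABEL_NON_NEOPLASTIC = "non_neoplastic"
LABEL_UNLABELLED = "unlabelled"
VALID_LABELS = (LABEL_CARCINOMA, LABEL_NON_NEOPLASTIC)


@dataclass
class RegionAnnotation:
    """A labelled polygon in working-magnification pixel coordinates."""

    polygon: Polygon
    label: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown region label {self.label!r}; expected one of {VALID_LABELS}")
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("region polygon must be simple with positive area")


@dataclass
class SlideRecord:
    """A slide with its regions and slide-level diagnosis."""

    slide: SlideImage
    regions: list[RegionAnnotation]
    slide_label: str

    @property
    def slide_id(self) -> str:
        return self.slide.slide_id


@dataclass(frozen=True)
class LabelledTile:
    tile: TileSpec
    slide_id: str
    label: str


def read_annotations(path: str | Path, scale: float = 1.0) -> list[RegionAnnotation]:
    """Parse a GeoJSON FeatureCollection of labelled polygons.

    Files store coordinates at base magnification; pass
    ``scale = working / base`` to rescale on load (1.0 when they coincide).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot parse annotation file {path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    regions = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise ValueError(f"{path}: feature {i} has malformed geometry: {exc}") from exc
        if geom.geom_type != "Polygon":
            raise ValueError(f"{path}: feature {i} is {geom.geom_type}, expected Polygon")
        label = feat.get("properties", {}).get("label")
        if label not in VALID_LABELS:
            raise ValueError(
                f"{path}: feature {i} has label {label!r}; expected one of {VALID_LABELS}"
            )
        if scale != 1.0:
            geom = affinity.scale(geom, xfact=scale, yfact=scale, origin=(0, 0))
        regions.append(RegionAnnotation(polygon=geom, label=label))
    return regions


def _coverage_by_class(tile: TileSpec, regions: list[RegionAnnotation]) -> dict[str, float]:
    window = box(tile.x, tile.y, tile.x + tile.size, tile.y + tile.size)
    area = float(window.area)
    cov = {LABEL_CARCINOMA: 0.0, LABEL_NON_NEOPLASTIC: 0.0}
    for label in cov:
        polys = [r.polygon for r in regions if r.label == label]
        if not polys:
            continue
        inter = 0.0
        merged = None
        for p in polys:
            merged = p if merged is None else merged.union(p)
        inter = window.intersection(merged).area
        cov[label] = inter / area
    return cov


def assign_tile_label(
    tile: TileSpec, regions: list[RegionAnnotation], min_overlap: float = 0.5
) -> str:
    """Majority-coverage tile label; ties toward carcinoma; else unlabelled."""
    if not 0.0 < min_overlap <= 1.0:
        raise ValueError("min_overlap must be in (0, 1]")
    cov = _coverage_by_class(tile, regions)
    best = max(cov.values())
    if best < min_overlap:
        return LABEL_UNLABELLED
    if cov[LABEL_CARCINOMA] >= cov[LABEL_NON_NEOPLASTIC]:
        return LABEL_CARCINOMA
    return LABEL_NON_NEOPLASTIC


def derive_slide_label(regions: list[RegionAnnotation]) -> str:
    """Diagnosis priority: carcinoma if any region is carcinoma."""
    if not regions:
        raise ValueError("cannot derive a slide label from an empty region list")
    if any(r.label == LABEL_CARCINOMA for r in regions):
        return LABEL_CARCINOMA
    return LABEL_NON_NEOPLASTIC


def build_supervised_dataset(
    records: list[SlideRecord],
    tile_size: int,
    stride: int,
    min_overlap: float = 0.5,
    tissue_threshold: float = 0.1,
) -> list[LabelledTile]:
    """All labelled grid tiles across slides, in slide order then row-major.

    Tiles failing the tissue filter or labelled ``unlabelled`` are dropped;
    a slide yielding no usable tiles is skipped with a warning.
    """
    out: list[LabelledTile] = []
    for rec in records:
        mask = tissue_mask(rec.slide)
        n_before = len(out)
        for tile in tile_grid(rec.slide.width, rec.slide.height, tile_size, stride):
            if mask.tissue_fraction(tile) < tissue_threshold:
                continue
            label = assign_tile_label(tile, rec.regions, min_overlap)
            if label == LABEL_UNLABELLED:
                continue
            out.append(LabelledTile(tile=tile, slide_id=rec.slide_id, label=label))
        if len(out) == n_before:
            logger.warning("slide %s yielded no labelled tiles; skipped", rec.slide_id)
    return out
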