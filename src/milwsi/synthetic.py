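"""Synthetic slide cohorts with region annotations and controllable label noise.

Real cohorts of this kind have a property that makes region-derived tile
labels noisy: carcinoma-annotated regions internally contain stretches of
non-neoplastic tissue (necrosis, inflammation), and the *same* tissue
appearance also occurs on slides with no carcinoma at all.  A tile
classifier trained on region labels therefore sees one texture under two
labels, and at inference that texture on a benign slide can drive the
slide-level maximum up.

The generator reproduces that structure procedurally.  Each slide carries:

* a background (near-white) field,
* a "normal tissue" convex blob annotated ``non_neoplastic``,
* on carcinoma slides, a disjoint convex blob annotated ``carcinoma`` whose
  interior mixes carcinoma texture with a confounder texture covering
  ``necrosis_in_carcinoma`` of its area,
* on a ``necrosis_in_negative`` fraction of non-carcinoma slides, patches of
  the *identical* confounder texture inside the normal blob.

Textures are per-class mean colours plus band-pass spatial noise (see
:mod:`milwsi.constants`); no image assets are shipped.  A per-pixel truth
mask is emitted alongside every slide for testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from PIL import Image
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import MultiPoint, Polygon, box, mapping

from milwsi import constants

LABEL_CARCINOMA = "carcinoma"
LABEL_NON_NEOPLASTIC = "non_neoplastic"

#: Area of the confounder patch on affected non-neoplastic slides, as a
#: fraction of the normal-tissue blob.  Kept small relative to the
#: confounder share of carcinoma regions so that, under region labels, the
#: confounder texture is predominantly labelled carcinoma — the asymmetry
#: that makes the fully-supervised baseline overcall benign necrosis.
NEG_CONFOUNDER_FRACTION = 0.10

#: Smoothing scale (px) of the random field whose upper quantile places
#: confounder patches.  Large relative to the desk tile size (64) so that
#: patches span whole tiles: the tile-label noise only bites when a tile is
#: confounder through and through, with no disambiguating context.
CONFOUNDER_FIELD_SIGMA = 40.0

#: Area ranges (fraction of slide area) for the tissue blobs.  The lesion
#: blob (carcinoma polygon, or the whole tissue blob of a negative slide)
#: is large so that confounder patches inside it span several whole tiles;
#: carcinoma slides additionally carry a smaller normal-tissue blob.
LESION_AREA_RANGE = (0.28, 0.36)
SMALL_NORMAL_AREA_RANGE = (0.10, 0.13)

#: A fraction of carcinoma slides carry a *small* lesion instead of a large
#: blob: a focus whose area is a sub-tile fraction of tile_size**2.  Such
#: lesions never reach majority coverage of any grid tile, so the
#: region-label route yields no carcinoma training tile for them, while
#: top-k selection still surfaces (and trains on) their best tile — the
#: small-focus false-negative regime that separates the two methods.
SMALL_LESION_FRACTION = 0.3
SMALL_LESION_AREA_TILE_RANGE = (0.3, 1.2)  # units of tile_size**2

#: Small foci are rendered in the upper (more normal-like) part of the
#: shade range, emulating early, well-differentiated lesions: both small
#: and subtle, they are the cases a region-label-trained model misses while
#: iterative top-k training still surfaces their best tile.
SMALL_LESION_SHADE_RANGE = (0.45, 0.8)

#: Lesions below this area (units of tile_size**2) carry no necrosis:
#: central necrosis is a feature of bulky tumours, not of tiny foci.
NECROSIS_MIN_LESION_TILES = 1.5

class InvalidSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    ``necrosis_in_carcinoma`` is the fraction of each carcinoma polygon's
    area rendered with the confounder texture; ``necrosis_in_negative`` is
    the probability that a non-neoplastic slide carries confounder patches.
    """

    n_slides: int
    carcinoma_fraction: float = 0.5
    slide_size: tuple[int, int] = (512, 512)  # (width, height)
    tile_size: int = 64
    necrosis_in_carcinoma: float = 0.3
    necrosis_in_negative: float = 0.5
    texture_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides < 0:
            raise InvalidSpecError("n_slides must be >= 0")
        for name in ("carcinoma_fraction", "necrosis_in_carcinoma", "necrosis_in_negative"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        w, h = self.slide_size
        if self.tile_size <= 0:
            raise InvalidSpecError("tile_size must be positive")
        if w < self.tile_size or h < self.tile_size:
            raise InvalidSpecError(
                f"slide_size {self.slide_size} smaller than tile_size {self.tile_size}"
            )


@dataclass
class SyntheticSlide:
    """One generated slide: image, vector annotations, label and truth mask."""

    slide_id: str
    image: np.ndarray  # (H, W, 3) uint8
    regions: list[tuple[Polygon, str]] = field(default_factory=list)
    slide_label: str = LABEL_NON_NEOPLASTIC
    truth_mask: np.ndarray | None = None  # (H, W) uint8, constants.MASK_*


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def carcinoma_indices(spec: SyntheticCohortSpec) -> set[int]:
    """Deterministic assignment of slide indices to the carcinoma class.

    The first ``round_half_up(n_slides * carcinoma_fraction)`` indices of a
    seeded permutation are carcinoma.
    """
    m = round_half_up(spec.n_slides * spec.carcinoma_fraction)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(spec.n_slides)
    return set(int(i) for i in perm[:m])


def _convex_blob(rng: np.random.Generator, center: tuple[float, float], target_area: float) -> Polygon:
    """A random convex polygon of exactly ``target_area`` around ``center``."""
    n_pts = 12
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_pts))
    base_r = math.sqrt(target_area / math.pi)
    radii = base_r * rng.uniform(0.7, 1.3, n_pts)
    pts = np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    scale = math.sqrt(target_area / hull.area)
    return affinity.scale(hull, xfact=scale, yfact=scale, origin="centroid")


def _bandpass_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    bp = gaussian_filter(white, constants.TEXTURE_SIGMA_FINE) - gaussian_filter(
        white, constants.TEXTURE_SIGMA_COARSE
    )
    s = bp.std()
    if s > 0:
        bp = bp / s
    return bp * sd


def _rasterize(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the polygon.

    Pixel (row r, col c) is represented by the point (c + 0.5, r + 0.5), so
    the raster agrees exactly with a point-in-polygon query at centres.
    """
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, int(minx) - 1), min(w, int(maxx) + 2)
    r0, r1 = max(0, int(miny) - 1), min(h, int(maxy) + 2)
    mask = np.zeros(shape, dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return mask
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = shapely.contains_xy(poly, xx.ravel() + 0.5, yy.ravel() + 0.5)
    mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    return mask


def _blob_field_threshold(
    rng: np.random.Generator,
    region_mask: np.ndarray,
    fraction: float,
    sigma: float = CONFOUNDER_FIELD_SIGMA,
) -> np.ndarray:
    """Select a ``fraction`` of ``region_mask`` pixels as contiguous blobs.

    A smoothed random field restricted to the region is thresholded at the
    (1 - fraction) quantile, giving coherent patches covering the requested
    area up to pixel rounding.
    """
    if fraction <= 0.0:
        return np.zeros_like(region_mask)
    fld = gaussian_filter(rng.standard_normal(region_mask.shape), sigma)
    vals = fld[region_mask]
    if vals.size == 0:
        return np.zeros_like(region_mask)
    thr = np.quantile(vals, 1.0 - fraction)
    return region_mask & (fld >= thr)


def generate_slide(
    spec: SyntheticCohortSpec, slide_index: int, rng: np.random.Generator | None = None
) -> SyntheticSlide:
    """Generate one slide deterministically from (spec.seed, slide_index)."""
    if not 0 <= slide_index < max(spec.n_slides, 1):
        raise InvalidSpecError(f"slide_index {slide_index} out of range for n_slides={spec.n_slides}")
    if rng is None:
        rng = np.random.default_rng([spec.seed, 1 + slide_index])
    w, h = spec.slide_size
    is_carcinoma = slide_index in carcinoma_indices(spec)

    slide_area = float(w * h)
    bounds = box(2, 2, w - 2, h - 2)

    carcinoma_poly = None
    if is_carcinoma:
        # Small normal blob at the left margin, large carcinoma blob
        # centre-right; redraw the carcinoma blob if the two touch.
        normal_area = rng.uniform(*SMALL_NORMAL_AREA_RANGE) * slide_area
        normal_center = (0.15 * w, (0.35 + rng.uniform(0.0, 0.3)) * h)
        normal_poly = _convex_blob(rng, normal_center, normal_area).intersection(bounds)
        if rng.uniform() < SMALL_LESION_FRACTION:
            carc_area = rng.uniform(*SMALL_LESION_AREA_TILE_RANGE) * spec.tile_size**2
        else:
            carc_area = rng.uniform(*LESION_AREA_RANGE) * slide_area
        r_est = math.sqrt(carc_area / math.pi)
        for _ in range(20):
            carc_center = (
                max(0.58 * w, normal_poly.bounds[2] + 1.05 * r_est + 8),
                (0.44 + rng.uniform(0.0, 0.12)) * h,
            )
            candidate = _convex_blob(rng, carc_center, carc_area).intersection(bounds)
            if candidate.distance(normal_poly) > 4.0:
                carcinoma_poly = candidate
                break
        if carcinoma_poly is None:
            # final fallback: carve the overlap away (still a simple polygon)
            parts = candidate.difference(normal_poly.buffer(6))
            if parts.geom_type == "MultiPolygon":
                parts = max(parts.geoms, key=lambda g: g.area)
            carcinoma_poly = parts
    else:
        normal_area = rng.uniform(*LESION_AREA_RANGE) * slide_area
        normal_center = (0.5 * w, 0.5 * h)
        normal_poly = _convex_blob(rng, normal_center, normal_area).intersection(bounds)

    mask = np.zeros((h, w), dtype=np.uint8)
    normal_mask = _rasterize(normal_poly, (h, w))
    mask[normal_mask] = constants.MASK_NORMAL

    if carcinoma_poly is not None:
        carc_mask = _rasterize(carcinoma_poly, (h, w))
        mask[carc_mask] = constants.MASK_CARCINOMA
        if carc_mask.sum() >= NECROSIS_MIN_LESION_TILES * spec.tile_size**2:
            conf_in_carc = _blob_field_threshold(rng, carc_mask, spec.necrosis_in_carcinoma)
            mask[conf_in_carc] = constants.MASK_CONFOUNDER
    elif rng.uniform() < spec.necrosis_in_negative:
        conf_in_norm = _blob_field_threshold(rng, normal_mask, NEG_CONFOUNDER_FRACTION)
        mask[conf_in_norm] = constants.MASK_CONFOUNDER

    # Render: flat background plus per-class mean colour + band-pass noise.
    img = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        img[:, :, c] = constants.BACKGROUND_COLOUR[c]
    img += rng.standard_normal((h, w, 3)) * 2.0  # faint scanner noise

    # Per-slide tumour shade: mix the carcinoma colour toward normal tissue
    # by a slide-specific fraction (drawn on every slide to keep the rng
    # stream aligned across classes).
    small_lesion = carcinoma_poly is not None and carcinoma_poly.area < spec.tile_size**2 * SMALL_LESION_AREA_TILE_RANGE[1] * 1.01
    if small_lesion:
        shade = rng.uniform(*SMALL_LESION_SHADE_RANGE)
    else:
        shade = rng.uniform(*constants.CARCINOMA_SHADE_RANGE)
    carc_colour = tuple(
        (1.0 - shade) * c + shade * n
        for c, n in zip(constants.CARCINOMA_COLOUR, constants.NORMAL_COLOUR)
    )
    # One stain offset per slide, shared by all tissue classes.
    stain = rng.normal(0.0, constants.STAIN_JITTER_SD, 3)
    conf_jitter = rng.normal(0.0, constants.CONFOUNDER_JITTER_SD, 3)
    class_colours = {
        constants.MASK_NORMAL: tuple(c + s for c, s in zip(constants.NORMAL_COLOUR, stain)),
        constants.MASK_CARCINOMA: tuple(c + s for c, s in zip(carc_colour, stain)),
        constants.MASK_CONFOUNDER: tuple(
            c + s + j for c, s, j in zip(constants.CONFOUNDER_COLOUR, stain, conf_jitter)
        ),
    }
    for code, colour in class_colours.items():
        sel = mask == code
        noise = np.stack(
            [_bandpass_noise(rng, (h, w), spec.texture_noise_sd) for _ in range(3)], axis=-1
        )
        if sel.any():
            for c in range(3):
                img[:, :, c][sel] = colour[c] + noise[:, :, c][sel]

    img = np.clip(img, 0, 255).astype(np.uint8)

    regions: list[tuple[Polygon, str]] = [(normal_poly, LABEL_NON_NEOPLASTIC)]
    slide_label = LABEL_NON_NEOPLASTIC
    if carcinoma_poly is not None:
        regions.append((carcinoma_poly, LABEL_CARCINOMA))
        slide_label = LABEL_CARCINOMA

    return SyntheticSlide(
        slide_id=f"slide_{slide_index:04d}",
        image=img,
        regions=regions,
        slide_label=slide_label,
        truth_mask=mask,
    )


def generate_records(spec: SyntheticCohortSpec):
    """Generate the cohort directly as in-memory :class:`SlideRecord` objects."""
    from milwsi.annotations import RegionAnnotation, SlideRecord
    from milwsi.wsi import SlideImage

    records = []
    for i in range(spec.n_slides):
        s = generate_slide(spec, i)
        slide = SlideImage(s.slide_id, s.image)
        regions = [RegionAnnotation(polygon=p, label=lab) for p, lab in s.regions]
        records.append(SlideRecord(slide=slide, regions=regions, slide_label=s.slide_label))
    return records


def _regions_to_geojson(regions: list[tuple[Polygon, str]]) -> dict:
    features = []
    for poly, label in regions:
        features.append(
            {"type": "Feature", "properties": {"label": label}, "geometry": mapping(poly)}
        )
    return {"type": "FeatureCollection", "features": features}


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> Path:
    """Write a full cohort (images, GeoJSON annotations, truth masks, manifest).

    Returns the path to the TSV manifest.  The number of carcinoma slides is
    ``round_half_up(n_slides * carcinoma_fraction)``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    rows = []
    for i in range(spec.n_slides):
        slide = generate_slide(spec, i)
        img_path = out / f"{slide.slide_id}.png"
        ann_path = out / f"{slide.slide_id}.geojson"
        mask_path = out / f"{slide.slide_id}_mask.png"
        try:
            Image.fromarray(slide.image).save(img_path)
            Image.fromarray(slide.truth_mask).save(mask_path)
            ann_path.write_text(json.dumps(_regions_to_geojson(slide.regions), indent=None, sort_keys=True))
        except OSError as exc:
            raise OSError(f"failed writing slide artifacts under {out}: {exc}") from exc
        rows.append((slide.slide_id, img_path.name, ann_path.name, slide.slide_label))

    manifest = out / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("slide_id\timage_path\tannotation_path\tslide_label\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return manifest
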