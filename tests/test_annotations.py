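"""Annotation parsing, tile label assignment, slide-label priority rule."""

from __future__ import annotations

import json

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon, box

from milwsi.annotations import (
    LABEL_UNLABELLED,
    RegionAnnotation,
    SlideRecord,
    assign_tile_label,
    build_supervised_dataset,
    derive_slide_label,
    read_annotations,
)
from milwsi.wsi import TileSpec
from tests.conftest import constant_slide


def square(x0, y0, side, label):
    return RegionAnnotation(polygon=box(x0, y0, x0 + side, y0 + side), label=label)


def rasterized_coverage(tile: TileSpec, poly: Polygon) -> float:
    """Pixel-counting oracle: fraction of tile pixel centres inside the polygon."""
    ys, xs = np.mgrid[tile.y : tile.y + tile.size, tile.x : tile.x + tile.size]
    return shapely.contains_xy(poly, xs.ravel() + 0.5, ys.ravel() + 0.5).mean()


class TestReadAnnotations:
    def test_roundtrip_from_cohort(self, cohort_dir):
        rows = (cohort_dir / "manifest.tsv").read_text().splitlines()[1:]
        for row in rows:
            _, _, ann, label = row.split("\t")
            regions = read_annotations(cohort_dir / ann)
            assert regions
            assert derive_slide_label(regions) == label

    def test_empty_feature_collection(self, tmp_path):
        p = tmp_path / "e.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": []}))
        assert read_annotations(p) == []

    def test_unknown_label_rejected(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"label": "adenocarcinoma"},
                    "geometry": {"type": "Polygon", "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 0]]]},
                }
            ],
        }
        p = tmp_path / "bad.geojson"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="adenocarcinoma"):
            read_annotations(p)

    def test_malformed_json(self, tmp_path):
        p = tmp_path / "junk.geojson"
        p.write_text("{not json")
        with pytest.raises(ValueError):
            read_annotations(p)

    def test_scaling_on_load(self, tmp_path):
        doc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"label": "carcinoma"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [100, 0], [100, 100], [0, 100], [0, 0]]],
                    },
                }
            ],
        }
        p = tmp_path / "s.geojson"
        p.write_text(json.dumps(doc))
        regions = read_annotations(p, scale=0.5)
        assert regions[0].polygon.area == pytest.approx(2500)


class TestAssignTileLabel:
    def test_tile_fully_inside_carcinoma(self):
        regions = [square(0, 0, 200, "carcinoma")]
        assert assign_tile_label(TileSpec(10, 10, 64, 0, 0), regions) == "carcinoma"

    def test_tile_outside_all_regions(self):
        regions = [square(500, 500, 50, "carcinoma")]
        assert assign_tile_label(TileSpec(0, 0, 64, 0, 0), regions) == LABEL_UNLABELLED

    def test_majority_coverage_with_tie_toward_carcinoma(self):
        # tile [0,100)^2: carcinoma covers the left 60 columns, benign the rest
        regions = [
            RegionAnnotation(box(0, 0, 60, 100), "carcinoma"),
            RegionAnnotation(box(60, 0, 100, 100), "non_neoplastic"),
        ]
        tile = TileSpec(0, 0, 100, 0, 0)
        assert assign_tile_label(tile, regions, 0.5) == "carcinoma"
        carc_cov = rasterized_coverage(tile, regions[0].polygon)
        assert carc_cov == pytest.approx(0.6, abs=0.02)

    def test_exact_tie_goes_to_carcinoma(self):
        regions = [
            RegionAnnotation(box(0, 0, 50, 100), "carcinoma"),
            RegionAnnotation(box(50, 0, 100, 100), "non_neoplastic"),
        ]
        assert assign_tile_label(TileSpec(0, 0, 100, 0, 0), regions, 0.5) == "carcinoma"

    def test_min_overlap_bounds(self):
        with pytest.raises(ValueError):
            assign_tile_label(TileSpec(0, 0, 64, 0, 0), [], min_overlap=0.0)

    def test_agrees_with_rasterized_oracle_on_random_polygons(self, rng):
        """Geometric coverage matches pixel counting within 2%; labels agree
        away from the decision boundary."""
        from milwsi.annotations import _coverage_by_class
        from milwsi.synthetic import _convex_blob

        disagreements = 0
        for _ in range(120):
            poly = _convex_blob(rng, rng.uniform(10, 54, 2), rng.uniform(300, 2500))
            label = "carcinoma" if rng.uniform() < 0.5 else "non_neoplastic"
            regions = [RegionAnnotation(poly, label)]
            tile = TileSpec(int(rng.integers(0, 32)), int(rng.integers(0, 32)), 32, 0, 0)
            cov = _coverage_by_class(tile, regions)[label]
            oracle_cov = rasterized_coverage(tile, poly)
            assert cov == pytest.approx(oracle_cov, abs=0.02)
            if abs(oracle_cov - 0.5) > 0.02:
                expected = label if oracle_cov >= 0.5 else LABEL_UNLABELLED
                if assign_tile_label(tile, regions, 0.5) != expected:
                    disagreements += 1
        assert disagreements == 0


class TestDeriveSlideLabel:
    def test_carcinoma_priority(self):
        regions = [square(0, 0, 10, "carcinoma"), square(20, 20, 10, "non_neoplastic")]
        assert derive_slide_label(regions) == "carcinoma"

    def test_all_benign(self):
        regions = [square(0, 0, 10, "non_neoplastic"), square(20, 20, 10, "non_neoplastic")]
        assert derive_slide_label(regions) == "non_neoplastic"

    def test_empty_regions_error(self):
        with pytest.raises(ValueError):
            derive_slide_label([])

    def test_monotone_in_carcinoma_regions(self, tiny_records):
        for rec in tiny_records:
            before = derive_slide_label(rec.regions)
            extended = rec.regions + [square(0, 0, 5, "carcinoma")]
            assert derive_slide_label(extended) == "carcinoma"
            if before == "carcinoma":
                assert derive_slide_label(extended) == before


class TestBuildSupervisedDataset:
    def test_fully_covered_slide_yields_full_grid(self):
        slide = constant_slide((180, 120, 150), size=128, slide_id="full")
        regions = [square(-1, -1, 200, "carcinoma")]
        record = SlideRecord(slide=slide, regions=regions, slide_label="carcinoma")
        tiles = build_supervised_dataset([record], tile_size=64, stride=64)
        assert len(tiles) == 4
        assert all(t.label == "carcinoma" for t in tiles)

    def test_annotations_covering_nothing_warns_and_skips(self, caplog):
        slide = constant_slide((180, 120, 150), size=128, slide_id="empty-ann")
        regions = [square(500, 500, 40, "carcinoma")]
        record = SlideRecord(slide=slide, regions=regions, slide_label="carcinoma")
        with caplog.at_level("WARNING"):
            tiles = build_supervised_dataset([record], tile_size=64, stride=64)
        assert tiles == []
        assert any("no labelled tiles" in m for m in caplog.messages)

    def test_deterministic_order(self, tiny_records):
        a = build_supervised_dataset(tiny_records, 64, 64)
        b = build_supervised_dataset(tiny_records, 64, 64)
        assert a == b

    def test_confounder_tiles_inherit_region_label(self, tiny_spec):
        """Tiles that are mostly confounder texture inside a carcinoma polygon
        are labelled carcinoma — the label-noise mechanism under study."""
        from milwsi import constants as C
        from milwsi.synthetic import SyntheticCohortSpec, carcinoma_indices, generate_records, generate_slide

        spec = SyntheticCohortSpec(n_slides=10, necrosis_in_carcinoma=0.4, seed=29)
        records = generate_records(spec)
        dataset = build_supervised_dataset(records, 64, 64)
        by_slide = {}
        for t in dataset:
            by_slide.setdefault(t.slide_id, {})[(t.tile.y, t.tile.x)] = t.label
        noisy = 0
        for i in carcinoma_indices(spec):
            s = generate_slide(spec, i)
            for (y, x), label in by_slide.get(s.slide_id, {}).items():
                window = s.truth_mask[y : y + 64, x : x + 64]
                if (window == C.MASK_CONFOUNDER).mean() > 0.6:
                    assert label == "carcinoma"
                    noisy += 1
        assert noisy > 0
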