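"""Shared fixtures: small in-memory cohorts and an on-disk cohort directory."""

from __future__ import annotations

import numpy as np
import pytest

from milwsi.synthetic import SyntheticCohortSpec, generate_cohort, generate_records
from milwsi.wsi import SlideImage


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticCohortSpec:
    """8 slides of 256 px, tile 64 — enough structure, fast to generate."""
    return SyntheticCohortSpec(
        n_slides=8, carcinoma_fraction=0.5, slide_size=(256, 256), tile_size=64, seed=11
    )


@pytest.fixture(scope="session")
def tiny_records(tiny_spec):
    return generate_records(tiny_spec)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, tiny_spec):
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(tiny_spec, out)
    return manifest.parent


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def constant_slide(value: tuple[int, int, int], size: int = 128, slide_id: str = "const") -> SlideImage:
    pixels = np.empty((size, size, 3), dtype=np.uint8)
    pixels[:] = value
    return SlideImage(slide_id, pixels)


class StubModel:
    """Duck-typed tile classifier: deterministic scores, counted train steps.

    ``score_fn`` maps a tile pixel array to a probability; default scores by
    the mean of the red channel scaled to [0, 1].
    """

    def __init__(self, input_size: int = 16, score_fn=None):
        self.input_size = input_size
        self.score_fn = score_fn or (lambda t: float(t[..., 0].mean()) / 255.0)
        self.train_calls: list[tuple[int, float]] = []  # (batch size, lr)
        self.trained_labels: list[np.ndarray] = []
        self.trained_tiles: list[np.ndarray] = []

    def predict_proba(self, tiles):
        tiles = np.asarray(tiles)
        if tiles.size == 0:
            return np.zeros(0)
        return np.array([self.score_fn(t) for t in tiles])

    def train_step(self, tiles, labels, lr):
        self.train_calls.append((len(tiles), lr))
        self.trained_labels.append(np.asarray(labels).copy())
        self.trained_tiles.append(np.asarray(tiles).copy())
        return 0.5

    def get_state(self):
        return {"n": np.array(len(self.train_calls))}

    def set_state(self, state):
        pass
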