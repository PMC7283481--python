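"""Training regimes: schedules, top-k selection, buffer mechanics, MIL loop."""

from __future__ import annotations

import numpy as np
import pytest

from milwsi.annotations import SlideRecord
from milwsi.tile_model import AugmentationConfig, SmallCNN
from milwsi.training import (
    EarlyStopper,
    FsConfig,
    MilConfig,
    TileBuffer,
    _tissue_tiles,
    fs_train,
    k_schedule,
    mil_epoch,
    mil_train,
    select_top_k,
    warm_phase,
)
from milwsi.wsi import SlideImage
from tests.conftest import StubModel

NO_AUG = AugmentationConfig(
    flip_horizontal=False, flip_vertical=False, max_translation=0, colour_shift_range=0.0
)


def stub_records(n_slides: int, tile: int = 16, tiles_per_slide: int = 9) -> list[SlideRecord]:
    """Tiny constant-colour slides; red channel encodes the slide index."""
    width = (tiles_per_slide - 1) * (tile // 2) + tile
    records = []
    for i in range(n_slides):
        pixels = np.empty((tile, width, 3), dtype=np.uint8)
        pixels[:] = (i % 200 + 1, 100, 100)
        label = "carcinoma" if i % 2 == 0 else "non_neoplastic"
        records.append(
            SlideRecord(slide=SlideImage(f"s{i:03d}", pixels), regions=[], slide_label=label)
        )
    return records


class TestKSchedule:
    def test_linear_decay_five_to_one(self):
        cfg = MilConfig(k_start=5, k_end=1, mil_epochs=5)
        assert [k_schedule(e, cfg) for e in range(1, 6)] == [5, 4, 3, 2, 1]

    def test_constant_schedule(self):
        cfg = MilConfig(k_start=3, k_end=3, mil_epochs=4)
        assert [k_schedule(e, cfg) for e in range(1, 5)] == [3, 3, 3, 3]

    def test_single_epoch_uses_k_start(self):
        cfg = MilConfig(mil_epochs=1)
        assert k_schedule(1, cfg) == 5

    def test_out_of_range_epoch(self):
        cfg = MilConfig(mil_epochs=5)
        with pytest.raises(ValueError):
            k_schedule(6, cfg)

    def test_longer_horizon_still_spans_range(self):
        cfg = MilConfig(k_start=5, k_end=1, mil_epochs=10)
        ks = [k_schedule(e, cfg) for e in range(1, 11)]
        assert ks[0] == 5 and ks[-1] == 1
        assert all(a >= b for a, b in zip(ks, ks[1:]))


class TestSelectTopK:
    def test_descending_with_stable_ties(self):
        assert select_top_k([0.2, 0.9, 0.5, 0.9], 2) == [1, 3]

    def test_k_one_is_argmax(self):
        assert select_top_k([0.1, 0.8, 0.3], 1) == [1]

    def test_k_exceeding_length_returns_all(self):
        assert select_top_k([0.3, 0.1, 0.2], 10) == [0, 2, 1]

    def test_empty_input(self):
        assert select_top_k([], 3) == []

    def test_constant_scores_select_lowest_indices(self):
        assert select_top_k([0.0] * 6, 3) == [0, 1, 2]

    def test_matches_sort_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 40))
            probs = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)  # many ties
            k = int(rng.integers(1, n + 2))
            oracle = sorted(range(n), key=lambda i: (-probs[i], i))[:k]
            assert select_top_k(probs, k) == oracle


class TestTileBuffer:
    def test_flushes_exactly_at_capacity_then_empties(self):
        buf = TileBuffer(4)
        tile = np.zeros((2, 2, 3), dtype=np.uint8)
        for i in range(3):
            assert buf.add(tile, i % 2) is None
        flushed = buf.add(tile, 1)
        assert flushed is not None
        tiles, labels = flushed
        assert len(tiles) == 4 and len(labels) == 4
        assert len(buf) == 0

    def test_capacity_positive(self):
        with pytest.raises(ValueError):
            TileBuffer(0)


class TestEarlyStopper:
    def test_stops_after_patience_and_keeps_best_state(self):
        stopper = EarlyStopper(patience=2)
        stops = [stopper.update(v, f"state{e}", e) for e, v in enumerate([0.9, 0.5, 0.6, 0.7], start=1)]
        assert stops == [False, False, False, True]
        assert stopper.best_epoch == 2
        assert stopper.best_state == "state2"

    def test_never_stops_on_monotone_improvement(self):
        stopper = EarlyStopper(patience=1)
        assert not any(stopper.update(1.0 / e, e, e) for e in range(1, 20))


class TestWarmPhase:
    def test_zero_warm_epochs_leaves_parameters_unchanged(self, tiny_records):
        model = SmallCNN(input_size=64, channels=(4, 4), seed=0)
        before = model.get_state()
        cfg = MilConfig(warm_epochs=0, tile_size=64)
        warm_phase(tiny_records, cfg, model, np.random.default_rng(0))
        after = model.get_state()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_tile_draw_budget(self, tiny_records):
        """Per warm epoch, each slide contributes at most warm_k draws."""
        from milwsi.annotations import LABEL_UNLABELLED, assign_tile_label

        cfg = MilConfig(warm_k=32, warm_epochs=2, tile_size=64, augmentation=NO_AUG)
        stub = StubModel(input_size=64)
        warm_phase(tiny_records, cfg, stub, np.random.default_rng(0))
        total_trained = sum(n for n, _ in stub.train_calls)
        expected = 0
        for rec in tiny_records:
            tiles = _tissue_tiles(rec, 64, 64, cfg.tissue_threshold)
            labelable = [
                t for t in tiles if assign_tile_label(t, rec.regions, 0.5) != LABEL_UNLABELLED
            ]
            expected += min(32, len(labelable))
        assert total_trained == 2 * expected
        assert total_trained <= len(tiny_records) * 32 * 2


class TestMilEpoch:
    def test_buffer_arithmetic_200_slides_k5(self):
        """200 slides at k=5 fill a 512-buffer once: 8 batch-64 steps, 488 left."""
        records = stub_records(200)
        stub = StubModel(input_size=16, score_fn=lambda t: 0.5)
        cfg = MilConfig(buffer_n=512, tile_size=16, augmentation=NO_AUG)
        buf = TileBuffer(cfg.buffer_n)
        stats = mil_epoch(records, stub, 5, cfg, np.random.default_rng(0), buf)
        assert stats["tiles_selected"] == 1000
        assert stats["flushes"] == 1
        assert stats["optimizer_steps"] == 8
        assert all(n == 64 for n, _ in stub.train_calls)
        assert stats["buffer_remainder"] == 488

    def test_constant_scores_select_lowest_index_tiles(self):
        records = stub_records(1)
        stub = StubModel(input_size=16, score_fn=lambda t: 0.0)
        cfg = MilConfig(buffer_n=64, tile_size=16, augmentation=NO_AUG)
        buf = TileBuffer(10**6)
        mil_epoch(records, stub, 1, cfg, np.random.default_rng(0), buf)
        assert len(buf) == 1  # top-1 of a constant list exists

    def test_buffered_labels_are_slide_labels(self):
        """Label provenance: every buffered tile carries its slide's label."""
        records = stub_records(40)
        stub = StubModel(input_size=16, score_fn=lambda t: float(t[0, 0, 0]) / 255.0)
        cfg = MilConfig(buffer_n=64, tile_size=16, augmentation=NO_AUG)
        buf = TileBuffer(cfg.buffer_n)
        mil_epoch(records, stub, 2, cfg, np.random.default_rng(1), buf, lr=1e-3)
        slide_label = {i % 200 + 1: 1 if i % 2 == 0 else 0 for i in range(40)}
        seen = 0
        for tiles, labels in zip(stub.trained_tiles, stub.trained_labels):
            for tile, label in zip(tiles, labels):
                red = tile[0, 0, 0]
                key = int(round(float(red) * 255)) if np.issubdtype(tile.dtype, np.floating) else int(red)
                assert label == slide_label[key]
                seen += 1
        for tile, label in zip(buf._tiles, buf._labels):
            assert label == slide_label[int(tile[0, 0, 0])]
            seen += 1
        assert seen == 80

    def test_selected_negative_tiles_are_the_hardest(self, rng):
        """With a frozen model, selected tiles on negative slides have the
        maximal scores among that slide's tiles (hard-negative mining)."""
        records = []
        for i in range(6):
            pixels = rng.integers(1, 230, size=(16, 80, 3), dtype=np.uint8)
            records.append(
                SlideRecord(SlideImage(f"n{i}", pixels), [], "non_neoplastic")
            )
        stub = StubModel(input_size=16)
        cfg = MilConfig(buffer_n=64, tile_size=16, augmentation=NO_AUG)
        buf = TileBuffer(10**6)
        mil_epoch(records, stub, 2, cfg, np.random.default_rng(3), buf)
        # oracle: recompute every slide's tile scores and its top-2 set
        from milwsi.wsi import extract_tile

        expected = []
        for rec in records:
            tiles = _tissue_tiles(rec, 16, 8, cfg.tissue_threshold)
            scores = [stub.score_fn(extract_tile(rec.slide, t)) for t in tiles]
            top = sorted(range(len(tiles)), key=lambda j: (-scores[j], j))[:2]
            expected.extend(extract_tile(rec.slide, tiles[j]).tobytes() for j in top)
        got = [t.tobytes() for t in buf._tiles]
        assert sorted(got) == sorted(expected)

    def test_fixed_seed_reproduces_selection(self):
        records = stub_records(10)
        cfg = MilConfig(buffer_n=64, tile_size=16, augmentation=NO_AUG)
        picks = []
        for _ in range(2):
            stub = StubModel(input_size=16)
            buf = TileBuffer(10**6)
            mil_epoch(records, stub, 3, cfg, np.random.default_rng(9), buf)
            picks.append([t.tobytes() for t in buf._tiles])
        assert picks[0] == picks[1]

    def test_slide_without_tissue_skipped_with_warning(self, caplog):
        pixels = np.full((16, 80, 3), 255, dtype=np.uint8)  # all background
        records = stub_records(2) + [SlideRecord(SlideImage("blank", pixels), [], "non_neoplastic")]
        stub = StubModel(input_size=16)
        cfg = MilConfig(buffer_n=64, tile_size=16, augmentation=NO_AUG)
        with caplog.at_level("WARNING"):
            stats = mil_epoch(records, stub, 1, cfg, np.random.default_rng(0), TileBuffer(64))
        assert stats["tiles_selected"] == 2
        assert any("no tissue tiles" in m for m in caplog.messages)


class TestTrainers:
    def test_fs_train_rejects_single_class_dataset(self, tiny_records):
        from milwsi.annotations import build_supervised_dataset

        dataset = [
            t for t in build_supervised_dataset(tiny_records, 64, 64) if t.label == "carcinoma"
        ]
        slides = {r.slide_id: r.slide for r in tiny_records}
        with pytest.raises(ValueError, match="both classes"):
            fs_train(dataset, slides, tiny_records, FsConfig(max_epochs=2, patience=1))

    def test_mil_train_bookkeeping_and_zero_epochs(self, tiny_records):
        cfg = MilConfig(
            warm_epochs=1, mil_epochs=2, buffer_n=64, tile_size=64,
            channels=(4, 4), seed=0,
        )
        model, history = mil_train(tiny_records, tiny_records[:6], cfg)
        assert len(history) == cfg.warm_epochs + cfg.mil_epochs
        assert [h.phase for h in history] == ["warm", "mil", "mil"]
        assert [h.k for h in history] == [None, 5, 1]

        warm_only = MilConfig(
            warm_epochs=1, mil_epochs=0, buffer_n=64, tile_size=64,
            channels=(4, 4), seed=0,
        )
        model0, history0 = mil_train(tiny_records, tiny_records[:6], warm_only)
        assert len(history0) == 1
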