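"""The two training regimes: fully-supervised baseline and the MIL loop.

Fully-supervised (FS): tiles inherit the label of the annotation region
they fall in, the network trains with Adam under a warm-start/decay
learning-rate schedule, and the parameter state with the lowest validation
loss is kept (early stopping on patience).

Weakly-supervised (WS/MIL): after a short warm phase on randomly sampled
annotated tiles (k = 32 per slide, 2 epochs), training switches to
multiple-instance learning.  Each MIL epoch visits the slides in random
order, scores all tissue tiles of a slide with the frozen model, selects
the top-k tiles by carcinoma probability (k decays linearly across epochs,
5 -> 1 by default), labels them with the *slide* diagnosis, and pushes them
into an accumulation buffer.  Whenever the buffer reaches capacity
(n = 512 by default) it is shuffled and consumed in optimizer steps of
batch 64, then emptied.  On carcinoma slides the selected tiles act as the
most-confident positives; on non-neoplastic slides they are hard negatives
— exactly the tiles the model currently overcalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from milwsi.annotations import (
    LABEL_CARCINOMA,
    LABEL_UNLABELLED,
    LabelledTile,
    SlideRecord,
    assign_tile_label,
)
from milwsi.inference import aggregate_slide, score_slide
from milwsi.synthetic import round_half_up
from milwsi.tile_model import (
    BACKBONE_SMALL_CNN,
    AugmentationConfig,
    OptimizerConfig,
    SmallCNN,
    augment,
    build_backbone,
    fs_lr_schedule,
)
from milwsi.wsi import SlideImage, extract_tile, tile_grid, tissue_mask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FsConfig:
    """Fully-supervised training hyperparameters."""

    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    max_epochs: int = 22
    patience: int = 10
    backbone: str = BACKBONE_SMALL_CNN
    channels: tuple[int, ...] | None = None
    tissue_threshold: float = 0.1
    min_overlap: float = 0.5
    val_stride: int | None = None  # None -> tile size (non-overlapping)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass(frozen=True)
class MilConfig:
    """Weakly-supervised (MIL) training hyperparameters."""

    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    warm_k: int = 32
    warm_epochs: int = 2
    warm_lr: float = 0.001  # the MIL loop's starting rate also serves the warm phase
    k_start: int = 5
    k_end: int = 1
    mil_epochs: int = 5
    buffer_n: int = 512
    initial_lr: float = 0.001
    lr_decay_per_epoch: float = 0.9
    min_overlap: float = 0.5
    tissue_threshold: float = 0.1
    tile_size: int = 64
    mil_stride: int | None = None  # None -> tile_size // 2 (overlapping sliding window)
    val_stride: int | None = None
    backbone: str = BACKBONE_SMALL_CNN
    channels: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_end > self.k_start:
            raise ValueError("k_end must not exceed k_start")
        if self.buffer_n % self.optimizer.batch_size != 0:
            raise ValueError("buffer_n must be a multiple of the batch size")


@dataclass
class EpochStats:
    epoch: int
    phase: str  # "fs" | "warm" | "mil"
    train_loss: float
    val_loss: float
    val_auc: float
    lr: float
    k: int | None = None


TrainHistory = list[EpochStats]


def history_to_tsv(history: TrainHistory, path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tphase\ttrain_loss\tval_loss\tval_auc\tlr\tk\n")
        for h in history:
            k = "" if h.k is None else str(h.k)
            fh.write(
                f"{h.epoch}\t{h.phase}\t{h.train_loss:.6f}\t{h.val_loss:.6f}\t"
                f"{h.val_auc:.6f}\t{h.lr:.6g}\t{k}\n"
            )


class EarlyStopper:
    """Minimum-validation-loss tracking with patience.

    ``update`` records one epoch's validation loss and the associated
    parameter state; it returns True when training should stop (no
    improvement for ``patience`` consecutive epochs past the best).
    """

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best_loss = np.inf
        self.best_state = None
        self.best_epoch: int | None = None
        self._since_best = 0

    def update(self, val_loss: float, state, epoch: int) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_state = state
            self.best_epoch = epoch
            self._since_best = 0
            return False
        self._since_best += 1
        return self._since_best >= self.patience


# ---------------------------------------------------------------------------
# shared helpers


def _label_to_int(label: str) -> int:
    return 1 if label == LABEL_CARCINOMA else 0


def _validate_on_slides(
    model, val: list[SlideRecord], tile_size: int, stride: int, tissue_threshold: float
) -> tuple[float, float]:
    """Slide-level (max-aggregated) log loss and AUC on a validation set."""
    from milwsi.evaluation import log_loss, roc_auc

    probs, labels = [], []
    for rec in val:
        pmap = score_slide(model, rec.slide, tile_size, stride, tissue_threshold)
        probs.append(aggregate_slide(pmap).probability)
        labels.append(_label_to_int(rec.slide_label))
    labels_arr = np.asarray(labels)
    probs_arr = np.asarray(probs)
    loss = log_loss(labels_arr, probs_arr)
    auc = roc_auc(labels_arr, probs_arr) if len(set(labels)) == 2 else float("nan")
    return loss, auc


def _augment_batch(
    tiles: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    floats = tiles.astype(np.float32) / 255.0
    return np.stack([augment(t, cfg, rng) for t in floats])


def _tissue_tiles(rec: SlideRecord, tile_size: int, stride: int, tissue_threshold: float):
    mask = tissue_mask(rec.slide)
    return [
        t
        for t in tile_grid(rec.slide.width, rec.slide.height, tile_size, stride)
        if mask.tissue_fraction(t) >= tissue_threshold
    ]


# ---------------------------------------------------------------------------
# fully-supervised baseline


def fs_train(
    dataset: list[LabelledTile],
    slides: dict[str, SlideImage],
    val: list[SlideRecord],
    cfg: FsConfig,
) -> tuple[SmallCNN, TrainHistory]:
    """Train on region-labelled tiles; return the lowest-validation-loss state.

    Validation loss is tile-level BCE on the region-labelled tiles of the
    validation slides — the fully-supervised regime assumes tile labels
    exist, so model selection uses them too.  Slide-level (max-aggregated)
    AUC on the validation slides is recorded in the history for monitoring.
    """
    from milwsi.annotations import build_supervised_dataset
    from milwsi.evaluation import log_loss

    labels = np.array([_label_to_int(t.label) for t in dataset])
    if len(set(labels.tolist())) < 2:
        raise ValueError("fully-supervised training needs tiles of both classes")
    tile_size = dataset[0].tile.size
    pixels = np.stack([extract_tile(slides[t.slide_id], t.tile) for t in dataset])

    val_tiles = build_supervised_dataset(
        val, tile_size, stride=tile_size, min_overlap=cfg.min_overlap,
        tissue_threshold=cfg.tissue_threshold,
    )
    val_slides = {r.slide_id: r.slide for r in val}
    val_pixels = np.stack([extract_tile(val_slides[t.slide_id], t.tile) for t in val_tiles])
    val_labels = np.array([_label_to_int(t.label) for t in val_tiles])

    model = build_backbone(cfg.backbone, tile_size, seed=cfg.seed, channels=cfg.channels)
    model.optimizer = cfg.optimizer
    shuffle_rng = np.random.default_rng([cfg.seed, 11])
    aug_rng = np.random.default_rng([cfg.seed, 12])

    bs = cfg.optimizer.batch_size
    n = len(dataset)
    iters = (n + bs - 1) // bs
    val_stride = cfg.val_stride or tile_size

    history: TrainHistory = []
    stopper = EarlyStopper(cfg.patience)
    for epoch in range(1, cfg.max_epochs + 1):
        perm = shuffle_rng.permutation(n)
        losses = []
        lr = 0.0
        for it in range(iters):
            idx = perm[it * bs : (it + 1) * bs]
            lr = fs_lr_schedule(epoch, it, iters)
            batch = _augment_batch(pixels[idx], cfg.augmentation, aug_rng)
            losses.append(model.train_step(batch, labels[idx], lr))
        val_loss = log_loss(val_labels, model.predict_proba(val_pixels))
        _, val_auc = _validate_on_slides(
            model, val, tile_size, val_stride, cfg.tissue_threshold
        )
        history.append(
            EpochStats(epoch, "fs", float(np.mean(losses)), val_loss, val_auc, lr)
        )
        if stopper.update(val_loss, model.get_state(), epoch):
            break
    model.set_state(stopper.best_state)
    return model, history


# ---------------------------------------------------------------------------
# MIL components


def k_schedule(mil_epoch: int, cfg: MilConfig) -> int:
    """Linear decay of the per-slide selection count across MIL epochs."""
    if not 1 <= mil_epoch <= cfg.mil_epochs:
        raise ValueError(f"mil_epoch {mil_epoch} outside 1..{cfg.mil_epochs}")
    if cfg.mil_epochs == 1:
        return cfg.k_start
    frac = (mil_epoch - 1) / (cfg.mil_epochs - 1)
    return round_half_up(cfg.k_start + (cfg.k_end - cfg.k_start) * frac)


def select_top_k(probabilities, k: int) -> list[int]:
    """Indices of the k largest probabilities, descending, ties to smaller index."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        return []
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort(-p, kind="stable")
    return [int(i) for i in order[: min(k, p.size)]]


class TileBuffer:
    """Accumulates (tile, label) pairs; hands back its contents exactly at capacity."""

    def __init__(self, capacity: int) -> None:
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._tiles: list[np.ndarray] = []
        self._labels: list[int] = []

    def __len__(self) -> int:
        return len(self._tiles)

    def add(self, tile: np.ndarray, label: int) -> tuple[np.ndarray, np.ndarray] | None:
        self._tiles.append(tile)
        self._labels.append(label)
        if len(self._tiles) >= self.capacity:
            tiles = np.stack(self._tiles)
            labels = np.asarray(self._labels)
            self._tiles.clear()
            self._labels.clear()
            return tiles, labels
        return None


def _train_on_flush(
    model,
    tiles: np.ndarray,
    labels: np.ndarray,
    lr: float,
    cfg: MilConfig,
    rng: np.random.Generator,
) -> list[float]:
    perm = rng.permutation(len(tiles))
    bs = cfg.optimizer.batch_size
    losses = []
    for start in range(0, len(tiles), bs):
        idx = perm[start : start + bs]
        batch = _augment_batch(tiles[idx], cfg.augmentation, rng)
        losses.append(model.train_step(batch, labels[idx], lr))
    return losses


def _warm_epoch(
    records: list[SlideRecord],
    cfg: MilConfig,
    model,
    rng: np.random.Generator,
    tile_cache: dict | None = None,
) -> float:
    """One warm pass: sample warm_k annotated tiles per slide, train in batches."""
    tile_size = model.input_size
    stride = cfg.mil_stride or tile_size
    pending_t: list[np.ndarray] = []
    pending_y: list[int] = []
    losses: list[float] = []
    bs = cfg.optimizer.batch_size

    for si in rng.permutation(len(records)):
        rec = records[si]
        tiles = _tissue_tiles(rec, tile_size, stride, cfg.tissue_threshold)
        labelled = [
            (t, assign_tile_label(t, rec.regions, cfg.min_overlap))
            for t in tiles
        ]
        labelled = [(t, lab) for t, lab in labelled if lab != LABEL_UNLABELLED]
        if not labelled:
            logger.warning("warm phase: slide %s has no labelable tiles; skipped", rec.slide_id)
            continue
        n_draw = min(cfg.warm_k, len(labelled))
        for j in rng.choice(len(labelled), size=n_draw, replace=False):
            t, lab = labelled[j]
            pending_t.append(extract_tile(rec.slide, t))
            pending_y.append(_label_to_int(lab))
            if len(pending_t) == bs:
                batch = _augment_batch(np.stack(pending_t), cfg.augmentation, rng)
                losses.append(model.train_step(batch, np.asarray(pending_y), cfg.warm_lr))
                pending_t.clear()
                pending_y.clear()
    if pending_t:
        batch = _augment_batch(np.stack(pending_t), cfg.augmentation, rng)
        losses.append(model.train_step(batch, np.asarray(pending_y), cfg.warm_lr))
    return float(np.mean(losses)) if losses else float("nan")


def warm_phase(
    records: list[SlideRecord], cfg: MilConfig, model, rng: np.random.Generator
):
    """Initial supervised phase on randomly sampled annotated tiles."""
    for _ in range(cfg.warm_epochs):
        _warm_epoch(records, cfg, model, rng)
    return model


def mil_epoch(
    records: list[SlideRecord],
    model,
    k: int,
    cfg: MilConfig,
    rng: np.random.Generator,
    buffer: TileBuffer | None = None,
    lr: float | None = None,
    tile_cache: dict | None = None,
) -> dict:
    """One MIL epoch: score, select top-k per slide, buffer under slide labels.

    Returns counters: tiles selected, flushes performed, buffer size at epoch
    end, and the mean training loss over flushes (NaN when none occurred).
    """
    if buffer is None:
        buffer = TileBuffer(cfg.buffer_n)
    if lr is None:
        lr = cfg.initial_lr
    tile_size = model.input_size
    stride = cfg.mil_stride or max(1, tile_size // 2)

    n_selected = 0
    n_flushes = 0
    losses: list[float] = []
    for si in rng.permutation(len(records)):
        rec = records[si]
        if tile_cache is not None and rec.slide_id in tile_cache:
            pixels = tile_cache[rec.slide_id]
        else:
            tiles = _tissue_tiles(rec, tile_size, stride, cfg.tissue_threshold)
            if not tiles:
                logger.warning("MIL: slide %s has no tissue tiles; skipped", rec.slide_id)
                continue
            pixels = np.stack([extract_tile(rec.slide, t) for t in tiles])
            if tile_cache is not None:
                tile_cache[rec.slide_id] = pixels
        if len(pixels) == 0:
            logger.warning("MIL: slide %s has no tissue tiles; skipped", rec.slide_id)
            continue
        probs = model.predict_proba(pixels)
        slide_y = _label_to_int(rec.slide_label)
        for idx in select_top_k(probs, k):
            flushed = buffer.add(pixels[idx], slide_y)
            n_selected += 1
            if flushed is not None:
                n_flushes += 1
                losses.extend(_train_on_flush(model, *flushed, lr, cfg, rng))
    return {
        "tiles_selected": n_selected,
        "flushes": n_flushes,
        "buffer_remainder": len(buffer),
        "train_loss": float(np.mean(losses)) if losses else float("nan"),
        "optimizer_steps": len(losses),
    }


def mil_train(
    records: list[SlideRecord],
    val: list[SlideRecord],
    cfg: MilConfig,
    model=None,
) -> tuple[SmallCNN, TrainHistory]:
    """Warm phase then MIL epochs; returns the lowest-validation-loss state.

    Validation scores whole slides by max aggregation (slide-level log
    loss), since the MIL regime assumes no tile labels on validation data.
    The returned state is the lowest-validation-loss epoch *after* the
    switch to MIL: the warm phase is initialization for the MIL loop, not a
    candidate final model (with ``mil_epochs=0`` the warm model is
    returned).  The partial buffer left at the end of training is
    discarded.
    """
    if model is None:
        model = build_backbone(cfg.backbone, cfg.tile_size, seed=cfg.seed, channels=cfg.channels)
    model.optimizer = cfg.optimizer
    warm_rng = np.random.default_rng([cfg.seed, 21])
    epoch_rng = np.random.default_rng([cfg.seed, 22])
    tile_size = model.input_size
    val_stride = cfg.val_stride or tile_size

    history: TrainHistory = []
    best_loss = np.inf
    best_state = model.get_state()

    def _validate(epoch: int, phase: str, train_loss: float, lr: float, k: int | None) -> None:
        nonlocal best_loss, best_state
        val_loss, val_auc = _validate_on_slides(
            model, val, tile_size, val_stride, cfg.tissue_threshold
        )
        history.append(EpochStats(epoch, phase, train_loss, val_loss, val_auc, lr, k))
        # warm epochs only seed the MIL loop; they never become the final state
        eligible = phase == "mil" or cfg.mil_epochs == 0
        if eligible and val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()

    tile_cache: dict = {}
    for e in range(1, cfg.warm_epochs + 1):
        train_loss = _warm_epoch(records, cfg, model, warm_rng)
        _validate(e, "warm", train_loss, cfg.warm_lr, None)

    buffer = TileBuffer(cfg.buffer_n)
    for e in range(1, cfg.mil_epochs + 1):
        k = k_schedule(e, cfg)
        lr = cfg.initial_lr * cfg.lr_decay_per_epoch ** (e - 1)
        stats = mil_epoch(records, model, k, cfg, epoch_rng, buffer, lr, tile_cache)
        _validate(cfg.warm_epochs + e, "mil", stats["train_loss"], lr, k)

    model.set_state(best_state)
    return model, history
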