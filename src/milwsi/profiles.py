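"""Desk-scale study profile: one place for the small-cohort operating point.

The library defaults (FsConfig / MilConfig / config.DEFAULTS) carry the
reference operating point for clinical-scale cohorts: 22 FS epochs with
patience 10, a 2-sweep warm phase, a 512-tile accumulation buffer.  Those
counts presuppose thousands of slides.  The desk profile is the package's
operating point for synthetic cohorts of tens of slides with 64 px tiles
on 512 px slides: epoch counts are raised so each phase sees a comparable
number of optimizer steps relative to its job, and the buffer shrinks to
two batches so it flushes several times per epoch.  The methods note
discusses the scaling rationale.
"""

from __future__ import annotations

import numpy as np

from milwsi.annotations import SlideRecord, build_supervised_dataset
from milwsi.evaluation import roc_auc
from milwsi.inference import aggregate_slide, score_slide
from milwsi.synthetic import SyntheticCohortSpec, generate_records
from milwsi.training import FsConfig, MilConfig, fs_train, mil_train

DESK_TILE_SIZE = 64
DESK_SLIDE_SIZE = (512, 512)
DESK_INFERENCE_STRIDE = 32  # half-tile overlap, mirroring the reference stride ratio
DESK_TISSUE_THRESHOLD = 0.1


def desk_cohort_spec(n_slides: int, seed: int, confounded: bool = True) -> SyntheticCohortSpec:
    """Study-condition cohort: 50/50 classes, necrosis 0.3 / 0.5 (or none)."""
    return SyntheticCohortSpec(
        n_slides=n_slides,
        carcinoma_fraction=0.5,
        slide_size=DESK_SLIDE_SIZE,
        tile_size=DESK_TILE_SIZE,
        necrosis_in_carcinoma=0.3 if confounded else 0.0,
        necrosis_in_negative=0.5 if confounded else 0.0,
        seed=seed,
    )


def desk_fs_config(seed: int) -> FsConfig:
    return FsConfig(max_epochs=10, patience=5, seed=seed)


def desk_mil_config(seed: int) -> MilConfig:
    return MilConfig(
        warm_epochs=6,
        mil_epochs=10,
        buffer_n=128,
        tile_size=DESK_TILE_SIZE,
        seed=seed,
    )


def score_records(model, records: list[SlideRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Max-aggregated slide probabilities and 0/1 labels for a record list."""
    probs, labels = [], []
    for rec in records:
        pmap = score_slide(
            model, rec.slide, DESK_TILE_SIZE, DESK_INFERENCE_STRIDE, DESK_TISSUE_THRESHOLD
        )
        probs.append(aggregate_slide(pmap).probability)
        labels.append(1 if rec.slide_label == "carcinoma" else 0)
    return np.asarray(labels), np.asarray(probs)


def desk_comparison(
    seed: int,
    confounded: bool = True,
    n_train: int = 80,
    n_val: int = 24,
    n_test: int = 40,
) -> dict:
    """Train both regimes on one seeded cohort and report held-out slide AUCs.

    Train, validation and test cohorts are generated from disjoint seed
    offsets of the master seed.  Returns ``{"fs_auc": ..., "ws_auc": ...}``.
    """
    train = generate_records(desk_cohort_spec(n_train, seed, confounded))
    val = generate_records(desk_cohort_spec(n_val, seed + 1000, confounded))
    test = generate_records(desk_cohort_spec(n_test, seed + 2000, confounded))

    dataset = build_supervised_dataset(
        train, DESK_TILE_SIZE, stride=DESK_TILE_SIZE, tissue_threshold=DESK_TISSUE_THRESHOLD
    )
    slides = {r.slide_id: r.slide for r in train}
    fs_model, _ = fs_train(dataset, slides, val, desk_fs_config(seed))
    labels, fs_probs = score_records(fs_model, test)
    ws_model, _ = mil_train(train, val, desk_mil_config(seed))
    _, ws_probs = score_records(ws_model, test)
    return {
        "fs_auc": roc_auc(labels, fs_probs),
        "ws_auc": roc_auc(labels, ws_probs),
        "labels": labels,
        "fs_probs": fs_probs,
        "ws_probs": ws_probs,
    }
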