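"""Pipeline stages wired over the library, plus provenance metadata.

Each stage reads/writes plain artifacts (PNG slides, GeoJSON annotations,
TSV manifests and predictions, JSON reports) under a working directory, so
stages can be run separately or end-to-end.  Every output directory gets a
``provenance.json`` with the config hash, master seed and package version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import milwsi
from milwsi.annotations import SlideRecord, build_supervised_dataset, read_annotations
from milwsi.config import RunConfig
from milwsi.evaluation import evaluate_predictions
from milwsi.inference import aggregate_slide, render_heatmap, save_heatmap_png, score_slide
from milwsi.synthetic import SyntheticCohortSpec, generate_cohort
from milwsi.tile_model import SmallCNN
from milwsi.training import fs_train, history_to_tsv, mil_train
from milwsi.wsi import load_slide

logger = logging.getLogger(__name__)

STAGES = ("synthesize", "train-fs", "train-ws", "predict", "evaluate")


def _write_provenance(out_dir: Path, config: RunConfig) -> None:
    doc = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "milwsi_version": milwsi.__version__,
        "config": config.raw,
    }
    (out_dir / "provenance.json").write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_records(manifest_path: str | Path, working_magnification: float = 10.0) -> list[SlideRecord]:
    """Load slides + annotations listed in a TSV manifest.

    An optional ``base_magnification`` column overrides file metadata; the
    ``slide_label`` column is authoritative for the slide diagnosis.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype={"slide_id": str})
    records = []
    root = manifest_path.parent
    for _, row in df.iterrows():
        base = float(row["base_magnification"]) if "base_magnification" in df.columns else None
        slide = load_slide(
            root / row["image_path"],
            target_magnification=working_magnification,
            base_magnification=base,
            slide_id=row["slide_id"],
        )
        scale = 1.0 if base is None else working_magnification / base
        regions = read_annotations(root / row["annotation_path"], scale=scale)
        records.append(SlideRecord(slide=slide, regions=regions, slide_label=row["slide_label"]))
    return records


def _split_validation(records: list[SlideRecord], val_fraction: float, seed: int):
    """Deterministic stratified-ish train/validation split at slide level."""
    rng = np.random.default_rng([seed, 31])
    idx = rng.permutation(len(records))
    n_val = max(2, int(round(len(records) * val_fraction)))
    val_idx = set(int(i) for i in idx[:n_val])
    labels_val = {records[i].slide_label for i in val_idx}
    if len(labels_val) < 2:  # force one slide of each class into validation
        for i in idx[n_val:]:
            if records[int(i)].slide_label not in labels_val:
                val_idx.add(int(i))
                labels_val.add(records[int(i)].slide_label)
            if len(labels_val) == 2:
                break
    train = [r for i, r in enumerate(records) if i not in val_idx]
    val = [r for i, r in enumerate(records) if i in val_idx]
    return train, val


def stage_synthesize(config: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    syn = config.synthesize
    spec = SyntheticCohortSpec(
        n_slides=syn["n_slides"],
        carcinoma_fraction=syn["carcinoma_fraction"],
        slide_size=tuple(syn["slide_size"]),
        tile_size=syn["tile_size"],
        necrosis_in_carcinoma=syn["necrosis_in_carcinoma"],
        necrosis_in_negative=syn["necrosis_in_negative"],
        texture_noise_sd=syn["texture_noise_sd"],
        seed=config.seed,
    )
    manifest = generate_cohort(spec, out)
    _write_provenance(out, config)
    return manifest


def stage_train_fs(config: RunConfig, manifest: str | Path, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = load_records(manifest, config.working_magnification)
    train, val = _split_validation(records, config.train_fs["val_fraction"], config.seed)
    dataset = build_supervised_dataset(
        train,
        tile_size=config.train_fs["tile_size"],
        stride=config.train_fs["stride"],
        min_overlap=config.train_fs["min_overlap"],
        tissue_threshold=config.train_fs["tissue_threshold"],
    )
    slides = {r.slide_id: r.slide for r in train}
    model, history = fs_train(dataset, slides, val, config.fs_config())
    ckpt = out / "fs_model.npz"
    model.save(ckpt)
    history_to_tsv(history, out / "fs_history.tsv")
    _write_provenance(out, config)
    return ckpt


def stage_train_ws(config: RunConfig, manifest: str | Path, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = load_records(manifest, config.working_magnification)
    train, val = _split_validation(records, config.train_ws["val_fraction"], config.seed)
    model, history = mil_train(train, val, config.mil_config())
    ckpt = out / "ws_model.npz"
    model.save(ckpt)
    history_to_tsv(history, out / "ws_history.tsv")
    _write_provenance(out, config)
    return ckpt


def stage_predict(
    config: RunConfig,
    checkpoint: str | Path,
    manifest: str | Path,
    out_dir: str | Path,
    heatmap_dir: str | Path | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ckpt = Path(checkpoint)
    if not ckpt.exists():
        raise FileNotFoundError(f"predict requires a checkpoint; {ckpt} not found")
    model = SmallCNN.load(ckpt)
    records = load_records(manifest, config.working_magnification)
    pc = config.predict
    # The tile size is fixed by the checkpoint's input size; the configured
    # stride is rescaled to preserve its ratio to the configured tile size
    # (e.g. 256/512 stays a half-tile overlap at any model scale).
    tile_size = model.input_size
    stride = max(1, round(pc["stride"] * tile_size / pc["tile_size"]))
    if tile_size != pc["tile_size"]:
        logger.info(
            "predict: model input size %d overrides configured tile size %d (stride %d)",
            tile_size, pc["tile_size"], stride,
        )
    rows = []
    for rec in records:
        pmap = score_slide(model, rec.slide, tile_size, stride, pc["tissue_threshold"])
        pred = aggregate_slide(pmap, threshold=pc["threshold"])
        rows.append(pred)
        if heatmap_dir is not None:
            hd = Path(heatmap_dir)
            hd.mkdir(parents=True, exist_ok=True)
            thumb = rec.slide.thumbnail()
            save_heatmap_png(render_heatmap(pmap, thumb), hd / f"{rec.slide_id}_heatmap.png")
    pred_path = out / "predictions.tsv"
    with open(pred_path, "w") as fh:
        fh.write("slide_id\tprobability\tpredicted_label\tn_tiles\n")
        for p in rows:
            fh.write(f"{p.slide_id}\t{p.probability:.6f}\t{p.predicted_label}\t{p.n_tiles_scored}\n")
    _write_provenance(out, config)
    return pred_path


def stage_evaluate(
    config: RunConfig, predictions: str | Path, manifest: str | Path, out_dir: str | Path
):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    predictions = Path(predictions)
    if not predictions.exists():
        raise FileNotFoundError(f"evaluate requires predictions; {predictions} not found")
    result = evaluate_predictions(
        predictions,
        manifest,
        n_iterations=config.evaluate["bootstrap_iterations"],
        seed=config.seed,
        out_json=out / "report.json",
        roc_plot=out / "roc.png",
    )
    _write_provenance(out, config)
    return result


def run_pipeline(
    config: RunConfig,
    workdir: str | Path,
    stages: tuple[str, ...] = STAGES,
    trainer: str = "train-ws",
) -> int:
    """Run an ordered subset of stages under one working directory.

    ``predict`` uses the checkpoint of ``trainer`` (train-ws by default);
    missing stage dependencies fail before any work is done.
    """
    workdir = Path(workdir)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    cohort = workdir / "cohort"
    manifest = cohort / "manifest.tsv"
    ckpt_name = "ws_model.npz" if trainer == "train-ws" else "fs_model.npz"
    ckpt = workdir / "models" / ckpt_name
    preds = workdir / "predictions" / "predictions.tsv"

    # dependency checks up front
    if ("train-fs" in stages or "train-ws" in stages or "predict" in stages) and (
        "synthesize" not in stages and not manifest.exists()
    ):
        raise FileNotFoundError(f"training/prediction needs a cohort manifest at {manifest}")
    if "predict" in stages and trainer not in stages and not ckpt.exists():
        raise FileNotFoundError(f"predict needs a checkpoint at {ckpt}")
    if "evaluate" in stages and "predict" not in stages and not preds.exists():
        raise FileNotFoundError(f"evaluate needs predictions at {preds}")

    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("stage %s starting", stage)
        if stage == "synthesize":
            stage_synthesize(config, cohort)
        elif stage == "train-fs":
            stage_train_fs(config, manifest, workdir / "models")
        elif stage == "train-ws":
            stage_train_ws(config, manifest, workdir / "models")
        elif stage == "predict":
            heat = workdir / "heatmaps" if config.predict.get("heatmaps") else None
            stage_predict(config, ckpt, manifest, workdir / "predictions", heat)
        elif stage == "evaluate":
            stage_evaluate(config, preds, manifest, workdir / "evaluation")
    return 0
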