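"""Slide-level ROC AUC, log loss, and percentile-bootstrap confidence intervals.

AUC follows the Mann-Whitney formulation (probability that a random
positive outscores a random negative, ties counting one half), computed via
scikit-learn.  The 95% CI is the percentile interval of the AUC over 1000
bootstrap resamples of slides; resamples that lose a class are redrawn.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

LOG_LOSS_EPS = 1e-15


@dataclass
class EvalResult:
    auc: float
    ci_low: float
    ci_high: float
    log_loss: float
    n_pos: int
    n_neg: int
    n_bootstrap: int
    seed: int


def _check_two_class(labels: np.ndarray) -> None:
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("both classes must be present to compute ROC AUC")


def roc_auc(labels, scores) -> float:
    """Tie-aware ROC AUC (Mann-Whitney)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    _check_two_class(labels)
    return float(roc_auc_score(labels, scores))


def log_loss(labels, probabilities) -> float:
    """Mean negative log-likelihood with probabilities clipped away from 0/1."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    p = np.clip(p, LOG_LOSS_EPS, 1.0 - LOG_LOSS_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _rank_auc_rows(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Vectorized tie-aware AUC for a matrix of resamples (rows)."""
    ranks = rankdata(scores, axis=1)
    n_pos = labels.sum(axis=1)
    n_neg = labels.shape[1] - n_pos
    pos_rank_sum = (ranks * labels).sum(axis=1)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def bootstrap_ci(
    labels,
    scores,
    n_iterations: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the ROC AUC over slide resamples.

    Slides are resampled with replacement; resamples missing a class are
    redrawn, up to 10 * n_iterations total draws.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_two_class(labels)
    n = labels.size
    rng = np.random.default_rng(seed)
    max_attempts = 10 * n_iterations
    aucs: list[np.ndarray] = []
    collected = 0
    attempts = 0
    while collected < n_iterations:
        budget = min(n_iterations - collected, max_attempts - attempts)
        if budget <= 0:
            raise RuntimeError(
                "could not draw enough two-class bootstrap resamples "
                f"({collected}/{n_iterations} after {attempts} attempts)"
            )
        idx = rng.integers(0, n, size=(budget, n))
        attempts += budget
        lab = labels[idx]
        valid = (lab.sum(axis=1) > 0) & (lab.sum(axis=1) < n)
        if valid.any():
            aucs.append(_rank_auc_rows(lab[valid], scores[idx][valid]))
            collected += int(valid.sum())
    all_aucs = np.concatenate(aucs)[:n_iterations]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(all_aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"slide_id": str})


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"slide_id": str})


def evaluate_predictions(
    predictions_path: str | Path,
    manifest_path: str | Path,
    n_iterations: int = 1000,
    seed: int = 0,
    out_json: str | Path | None = None,
    roc_plot: str | Path | None = None,
) -> EvalResult:
    """Join predictions with the manifest and compute AUC, log loss and CI."""
    preds = read_predictions(predictions_path)
    manifest = read_manifest(manifest_path)
    missing = set(preds["slide_id"]) - set(manifest["slide_id"])
    if missing:
        raise ValueError(f"prediction slide_ids absent from manifest: {sorted(missing)}")
    joined = preds.merge(manifest[["slide_id", "slide_label"]], on="slide_id", how="left")
    labels = (joined["slide_label"] == "carcinoma").to_numpy().astype(int)
    scores = joined["probability"].to_numpy(dtype=float)

    auc = roc_auc(labels, scores)
    ll = log_loss(labels, scores)
    lo, hi = bootstrap_ci(labels, scores, n_iterations=n_iterations, seed=seed)
    result = EvalResult(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        log_loss=ll,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
        n_bootstrap=n_iterations,
        seed=seed,
    )
    if out_json is not None:
        Path(out_json).write_text(json.dumps(asdict(result), indent=2, sort_keys=True) + "\n")
    if roc_plot is not None:
        fpr, tpr, _ = roc_curve(labels, scores)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(fpr, tpr, label=f"AUC = {auc:.3f} ({lo:.3f}-{hi:.3f})")
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right", frameon=False)
        fig.tight_layout()
        fig.savefig(roc_plot, dpi=120)
        plt.close(fig)
    return result
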