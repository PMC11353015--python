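"""Evaluation surfaces for the particle-count classifier.

Produces the standard report set: a row-normalized 11x11 confusion matrix,
per-class accuracy curves as a function of particle number under each noise
condition, and a non-learned baseline that counts particles by smoothing
the image and finding intensity peaks (the classical alternative to a
trained counter; it degrades quickly once parabolic tails overlap).
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .dataset import (
    N_CLASSES, OTHERS_LABEL, DatasetConfig, class_label, make_sample_m1,
    reference_signal_power, derive_seed,
)
from .degrade import NOISE_FREE, NoiseSpec, blur, disk_kernel
from .optics import OpticalParams
from .classifier import TrainedModel, predict_labels

__all__ = [
    "ConfusionMatrix", "AccuracyCurve", "EvalResult",
    "confusion_matrix", "accuracy_by_class", "noise_sweep",
    "peak_count_baseline", "bootstrap_compare", "generate_test_cell",
    "save_confusion_csv", "save_curves_csv", "plot_confusion", "plot_curves",
]


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion rates with raw counts and per-row support."""

    counts: np.ndarray            # (11, 11) ints, rows = true class
    rates: np.ndarray             # rows sum to 1 (zero-support rows all-zero)
    support: np.ndarray           # (11,) row sums of counts
    empty_rows: tuple[int, ...]   # rows with zero support, flagged not scaled


@dataclass
class AccuracyCurve:
    """Noise condition -> per-class accuracy over classes 0..10."""

    condition: str
    accuracy: np.ndarray          # (11,) in [0, 1]
    support: np.ndarray


@dataclass
class EvalResult:
    """One evaluation run: matrix, curves, metadata and timing."""

    cm: ConfusionMatrix
    per_class_accuracy: np.ndarray
    condition: str = "mixed"
    profile: str = "desk"
    mean_inference_ms: float | None = None
    extra: dict = field(default_factory=dict)


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count-based confusion matrix, then row normalization by row support."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    for v in (t, p):
        if v.size and (v.min() < 0 or v.max() >= N_CLASSES):
            raise ValueError("labels must lie in 0..10")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (t, p), 1)
    support = counts.sum(axis=1)
    rates = np.zeros_like(counts, dtype=float)
    nz = support > 0
    rates[nz] = counts[nz] / support[nz, None]
    empty = tuple(int(i) for i in np.nonzero(~nz)[0])
    return ConfusionMatrix(counts=counts, rates=rates, support=support,
                           empty_rows=empty)


def accuracy_by_class(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class accuracies: the diagonal of the row-normalized matrix."""
    return cm.rates.diagonal().copy()


def generate_test_cell(
    label: int,
    snr_db: float,
    n_images: int,
    config: DatasetConfig,
    seed: int,
    blank_power: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fresh Method-1 test images for one (class, noise condition) cell."""
    if blank_power is None:
        blank_power = reference_signal_power(
            config.optics, config.blur_radius, config.amplitude_range,
            seed=derive_seed(seed, 103))
    lo, hi = config.others_range
    images, ns = [], []
    for i in range(n_images):
        s = derive_seed(seed, 201, label, i)
        n = label if label < OTHERS_LABEL else int(
            np.random.default_rng(s).integers(lo, hi + 1))
        override = blank_power if (n == 0 and snr_db != NOISE_FREE) else None
        spec = NoiseSpec(snr_db=snr_db, blur_radius=config.blur_radius,
                         signal_power=override)
        sample = make_sample_m1(n, spec, config.optics, s,
                                config.position_margin, config.amplitude_range)
        images.append(sample.image)
        ns.append(n)
    return np.stack(images), np.array(ns)


def noise_sweep(
    model: TrainedModel,
    optics: OpticalParams | None = None,
    noise_grid: tuple[float, ...] | None = None,
    n_per_cell: int = 50,
    seed: int = 0,
    config: DatasetConfig | None = None,
) -> dict[str, AccuracyCurve]:
    """Per-class accuracy under each noise condition plus the mixed pool.

    Fresh Method-1 test images are generated for every (class, condition)
    cell; the "mixed" curve pools predictions over all conditions.
    """
    if config is None:
        config = DatasetConfig(optics=optics or OpticalParams())
    if noise_grid is None:
        noise_grid = config.noise_grid
    blank_power = reference_signal_power(
        config.optics, config.blur_radius, config.amplitude_range,
        seed=derive_seed(seed, 103))
    curves: dict[str, AccuracyCurve] = {}
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for cond_idx, snr in enumerate(noise_grid):
        name = "noise_free" if snr == NOISE_FREE else f"{snr:g}dB"
        acc = np.zeros(N_CLASSES)
        sup = np.zeros(N_CLASSES, dtype=int)
        for label in range(N_CLASSES):
            images, _ = generate_test_cell(
                label, snr, n_per_cell, config,
                seed=derive_seed(seed, 202, cond_idx), blank_power=blank_power)
            pred = predict_labels(model, images)
            acc[label] = float((pred == label).mean())
            sup[label] = n_per_cell
            pooled_true.append(np.full(n_per_cell, label))
            pooled_pred.append(pred)
        curves[name] = AccuracyCurve(condition=name, accuracy=acc, support=sup)
    cm = confusion_matrix(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    curves["mixed"] = AccuracyCurve(condition="mixed",
                                    accuracy=accuracy_by_class(cm),
                                    support=cm.support.copy())
    return curves


def peak_count_baseline(
    image: np.ndarray,
    kernel_radius: float = 1.0,
    threshold_k: float = 6.0,
    min_separation: int = 4,
) -> int:
    """Count particles by smoothed local-maxima detection (non-learned).

    The image is disk-smoothed, the median subtracted, and local maxima
    exceeding ``threshold_k`` median absolute deviations (MAD) are counted,
    with ``min_separation`` pixels minimum peak spacing.
    """
    image = np.asarray(image, dtype=float)
    smooth = blur(image, disk_kernel(kernel_radius))
    med = np.median(smooth)
    dev = smooth - med
    mad = float(np.median(np.abs(dev)))
    thr = max(threshold_k * mad, 1e-9 * max(abs(med), 1.0))
    peaks = peak_local_max(dev, min_distance=min_separation, threshold_abs=thr)
    return int(len(peaks))


def bootstrap_compare(
    correct_a: np.ndarray,
    correct_b: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Paired bootstrap of accuracy(a) - accuracy(b) on the same test images.

    Returns the observed difference, the one-sided lower confidence bound at
    ``level``, and whether a >= b holds at that level (bound >= 0).
    """
    a = np.asarray(correct_a, dtype=float)
    b = np.asarray(correct_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    rng = np.random.default_rng(seed)
    n = len(a)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        diffs[i] = a[idx].mean() - b[idx].mean()
    lower = float(np.quantile(diffs, 1.0 - level))
    return {"observed_diff": float(a.mean() - b.mean()),
            "lower_bound": lower,
            "level": level,
            "n": n,
            "n_boot": n_boot,
            "a_ge_b": bool(lower >= 0.0)}


def timed_predict(model: TrainedModel, images: np.ndarray) -> tuple[np.ndarray, float]:
    """Predictions plus mean wall-clock inference time per image (ms)."""
    t0 = time.perf_counter()
    pred = predict_labels(model, images)
    dt = time.perf_counter() - t0
    return pred, 1000.0 * dt / max(len(pred), 1)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def save_confusion_csv(cm: ConfusionMatrix, path: str | Path) -> None:
    labels = [str(i) for i in range(OTHERS_LABEL)] + ["others"]
    df = pd.DataFrame(cm.rates, index=labels, columns=labels)
    df["support"] = cm.support
    df.to_csv(path)


def save_curves_csv(curves: dict[str, AccuracyCurve], path: str | Path) -> None:
    rows = {name: c.accuracy for name, c in curves.items()}
    df = pd.DataFrame(rows, index=range(N_CLASSES))
    df.index.name = "n_particles"
    df.to_csv(path)


def plot_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.rates, vmin=0, vmax=1, cmap="Blues")
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    ticks = list(range(N_CLASSES))
    names = [str(i) for i in range(OTHERS_LABEL)] + ["others"]
    ax.set_xticks(ticks, names, rotation=45)
    ax.set_yticks(ticks, names)
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            if cm.rates[i, j] >= 0.005:
                ax.text(j, i, f"{100 * cm.rates[i, j]:.0f}",
                        ha="center", va="center", fontsize=7,
                        color="white" if cm.rates[i, j] > 0.5 else "black")
    fig.colorbar(im, ax=ax, label="row-normalized rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_curves(curves: dict[str, AccuracyCurve], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.plot(range(N_CLASSES), curve.accuracy, marker="o", label=name)
    ax.set_xlabel("number of particles")
    ax.set_ylabel("accuracy")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
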