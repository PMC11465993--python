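"""Quantitative assessment of counting and localization quality.

Implements the confusion-matrix metrics (recall TP/(TP+FN), precision
TP/(TP+FP), accuracy (TP+TN)/total), the per-spot localization RMS

    RMS = sqrt( sum_i [(x_i - xbar_i)^2 + (y_i - ybar_i)^2] / (2 I) )

with minimum-cost emitter matching, distance-binned RMS summaries,
displacement heatmaps, and the spike-rendering / Gaussian-convolution /
SSIM harness used to compare coordinate predictions with image-generating
reconstruction methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "classification_metrics",
    "match_emitters",
    "rms_error",
    "midpoint_baseline_rms",
    "bin_rms_by_distance",
    "displacement_heatmap",
    "render_spikes",
    "heatmap_from_spikes",
    "ssim",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_EDGES_NM = (0.0, 60.0, 120.0, 180.0, 240.0)


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with the two-emitter class as "positive"."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, true_counts, pred_counts, positive: int = 2) -> "ConfusionMatrix":
        t = np.asarray(true_counts) == positive
        p = np.asarray(pred_counts) == positive
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            fn=int(np.sum(t & ~p)),
            tn=int(np.sum(~t & ~p)),
        )


def classification_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(precision, recall, accuracy); undefined ratios are NaN with a warning."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.tp + cm.fp == 0:
        warnings.warn("precision undefined: no positive predictions", stacklevel=2)
        precision = float("nan")
    else:
        precision = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        warnings.warn("recall undefined: no positive ground truths", stacklevel=2)
        recall = float("nan")
    else:
        recall = cm.tp / (cm.tp + cm.fn)
    accuracy = (cm.tp + cm.tn) / cm.total
    return precision, recall, accuracy


def match_emitters(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Minimum-total-squared-distance bijection between two coordinate lists.

    Returns ``assign`` such that ``pred[i]`` pairs with ``truth[assign[i]]``.
    Any other pairing would inflate the localization error artifactually,
    since emitters carry no identity.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal lengths")
    cost = ((pred[:, None, :] - truth[None, :, :]) ** 2).sum(axis=-1)
    rows, cols = linear_sum_assignment(cost)
    assign = np.empty(len(pred), dtype=int)
    assign[rows] = cols
    return assign


def rms_error(pred: np.ndarray, truth: np.ndarray, match: bool = True) -> float:
    """Per-spot localization RMS in nm (emitters matched first by default)."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.size == 0 or truth.size == 0:
        raise ValueError("empty coordinate lists")
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal lengths")
    if match:
        truth = truth[match_emitters(pred, truth)]
    i = len(pred)
    return float(np.sqrt(np.sum((pred - truth) ** 2) / (2 * i)))


def midpoint_baseline_rms(distance_nm: float) -> float:
    """RMS of predicting both emitters of a pair at their midpoint: d/(2*sqrt(2)).

    The trivial lower bar any two-emitter localizer must beat at resolvable
    separations.
    """
    return distance_nm / (2.0 * np.sqrt(2.0))


@dataclass
class EvalReport:
    """Aggregate evaluation of a two-stage prediction run."""

    precision: float
    recall: float
    accuracy: float
    rms_values_nm: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_rms_nm: float = float("nan")
    per_bin: pd.DataFrame | None = None
    n_count_mismatch: int = 0
    ssim_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        for frac in (self.precision, self.recall, self.accuracy):
            if np.isfinite(frac) and not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if np.any(np.asarray(self.rms_values_nm) < 0):
            raise ValueError("RMS must be >= 0")


def bin_rms_by_distance(
    records: pd.DataFrame,
    edges=DEFAULT_BIN_EDGES_NM,
) -> pd.DataFrame:
    """Per-separation-bin RMS summaries.

    ``records`` needs columns ``distance_nm`` and ``rms_nm``; the default
    edges give the four groups 0-60, 60-120, 120-180, 180-240 nm. Records
    outside all bins are excluded (logged).
    """
    edges = np.asarray(edges, dtype=float)
    d = records["distance_nm"].to_numpy()
    r = records["rms_nm"].to_numpy()
    outside = (d < edges[0]) | (d > edges[-1]) | ~np.isfinite(d)
    if outside.any():
        log.info("excluding %d records outside the distance bins", int(outside.sum()))
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi) & ~outside
        vals = r[sel]
        rows.append(
            {
                "bin_lo_nm": lo,
                "bin_hi_nm": hi,
                "n": int(sel.sum()),
                "mean_rms_nm": float(vals.mean()) if vals.size else float("nan"),
                "median_rms_nm": float(np.median(vals)) if vals.size else float("nan"),
                "q25_rms_nm": float(np.percentile(vals, 25)) if vals.size else float("nan"),
                "q75_rms_nm": float(np.percentile(vals, 75)) if vals.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def displacement_heatmap(
    displacements_nm: np.ndarray,
    grid_nm: float = 2.0,
    extent_nm: float = 60.0,
    bandwidth_nm: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """2D histogram of (prediction - truth) displacement vectors at the origin.

    Returns ``(density, bin_edges)``; total mass equals the number of
    emitters inside the extent. Optionally kernel-smoothed.
    """
    disp = np.atleast_2d(np.asarray(displacements_nm, dtype=float))
    edges = np.arange(-extent_nm, extent_nm + grid_nm / 2, grid_nm)
    hist, _, _ = np.histogram2d(disp[:, 1], disp[:, 0], bins=(edges, edges))
    if bandwidth_nm > 0:
        hist = ndimage.gaussian_filter(hist, bandwidth_nm / grid_nm)
    return hist, edges


def render_spikes(
    coords_nm: np.ndarray,
    upsampling: int = 8,
    canvas_px: tuple[int, int] = (15, 15),
    pixel_size_nm: float = 160.0,
) -> np.ndarray:
    """Unit impulses at emitter positions on an upsampled canvas.

    Each coordinate contributes 1 to the high-resolution pixel containing
    it (coincident coordinates accumulate), so the image sum equals the
    number of coordinates.
    """
    coords = np.atleast_2d(np.asarray(coords_nm, dtype=float))
    h, w = canvas_px
    out = np.zeros((h * upsampling, w * upsampling))
    if coords.size == 0:
        return out
    sub = pixel_size_nm / upsampling
    cols = np.floor(coords[:, 0] / sub).astype(int)
    rows = np.floor(coords[:, 1] / sub).astype(int)
    if np.any((cols < 0) | (cols >= w * upsampling) | (rows < 0) | (rows >= h * upsampling)):
        raise ValueError("coordinate outside the canvas")
    np.add.at(out, (rows, cols), 1.0)
    return out


def heatmap_from_spikes(spikes: np.ndarray, kernel_sigma_px: float = 1.0) -> np.ndarray:
    """Convolve a spike image with a Gaussian kernel (zero-padded edges)."""
    if kernel_sigma_px <= 0:
        raise ValueError("kernel sigma must be > 0")
    return ndimage.gaussian_filter(np.asarray(spikes, dtype=float), kernel_sigma_px,
                                   mode="constant")


def ssim(
    image_a: np.ndarray,
    image_b: np.ndarray,
    win_size: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Structural similarity index between two equally-shaped images.

    Uniform ``win_size`` x ``win_size`` windows, sample (unbiased)
    covariance normalization, stabilization constants ``C1=(k1 L)^2`` and
    ``C2=(k2 L)^2`` with L the data range; the mean is taken over windows
    fully inside the image. Identical images give 1.0.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if a.ndim != 2 or min(a.shape) < win_size:
        raise ValueError("images must be 2D and at least the window size")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo
        if data_range == 0:
            return 1.0

    ns = win_size**2
    cov_norm = ns / (ns - 1.0)

    def f(img):
        return ndimage.uniform_filter(img, size=win_size)

    ua, ub = f(a), f(b)
    uaa, ubb, uab = f(a * a), f(b * b), f(a * b)
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    vab = cov_norm * (uab - ua * ub)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def evaluate_predictions(
    true_counts: np.ndarray,
    pred_counts: np.ndarray,
    true_coords: list,
    pred_coords: list,
    distances_nm: np.ndarray | None = None,
    positive: int = 2,
) -> EvalReport:
    """Full report: counting metrics + RMS restricted to count-matched spots.

    Spots whose predicted count differs from the truth are excluded from
    the RMS statistics and tallied in ``n_count_mismatch`` (the regression
    error is only defined when the coordinate lists have equal length).
    """
    true_counts = np.asarray(true_counts)
    pred_counts = np.asarray(pred_counts)
    cm = ConfusionMatrix.from_labels(true_counts, pred_counts, positive=positive)
    precision, recall, accuracy = classification_metrics(cm)
    rms_vals, dists = [], []
    n_mismatch = 0
    for i in range(len(true_counts)):
        if pred_counts[i] != true_counts[i]:
            n_mismatch += 1
            continue
        rms_vals.append(rms_error(pred_coords[i], true_coords[i]))
        if distances_nm is not None:
            dists.append(distances_nm[i])
    rms_vals = np.asarray(rms_vals)
    per_bin = None
    if distances_nm is not None and rms_vals.size:
        per_bin = bin_rms_by_distance(
            pd.DataFrame({"distance_nm": dists, "rms_nm": rms_vals})
        )
    return EvalReport(
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        rms_values_nm=rms_vals,
        mean_rms_nm=float(rms_vals.mean()) if rms_vals.size else float("nan"),
        per_bin=per_bin,
        n_count_mismatch=n_mismatch,
    )
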