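"""Desk-scale benchmark experiments for the two-stage spot pipeline.

These routines reproduce, on synthetic spot libraries, the headline
experiments of the method: one-vs-two emitter classification quality,
two-emitter localization RMS (overall, distance-binned, and at a fixed
30 +- 2 nm separation), and cross-batch generalization to an independently
generated library with a perturbed photon distribution. They are used both
by the acceptance machinery and as ready-made example workloads.

Default problem sizes are desk-scale (tens of thousands of spots, tens of
epochs, one CPU); the statistical protocol — balanced classes, disjoint
source molecules between train and test, distances uniform in the 240 nm
disk — matches the full-scale recipe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import stage_seed
from .datasets import LabeledDataset, build_dataset
from .evaluation import (
    ConfusionMatrix,
    bin_rms_by_distance,
    classification_metrics,
    rms_error,
)
from .library import SpotLibrary
from .models import TrainConfig, TrainedModel, build_model, train
from .synthetic import CameraModel, PhotonDistribution, PsfModel, build_synthetic_library

__all__ = [
    "BenchmarkConfig",
    "make_library",
    "split_library",
    "run_classification_benchmark",
    "run_generalization_benchmark",
    "run_localization_benchmark",
]

log = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    """Problem sizes for the desk-scale benchmark experiments."""

    n_molecules: int = 3000
    n_per_class: int = 10000  # classification: per class, train+test
    n_pairs_train: int = 24000  # localization training pairs
    n_eval_overall: int = 3000
    n_eval_close: int = 1200  # pairs conditioned on separation < 60 nm
    n_eval_fixed: int = 1200  # pairs at 30 +- 2 nm
    n_batch_b: int = 5000  # generalization: per class
    classifier_epochs: int = 40
    localizer_epochs: int = 60
    batch_b_median_scale: float = 1.1  # +10% photon-median perturbation

    camera: CameraModel = field(default_factory=CameraModel)
    psf: PsfModel = field(default_factory=PsfModel)
    photons: PhotonDistribution = field(default_factory=PhotonDistribution)


def make_library(cfg: BenchmarkConfig, seed: int,
                 photon_dist: PhotonDistribution | None = None,
                 n_molecules: int | None = None) -> SpotLibrary:
    return build_synthetic_library(
        n_molecules or cfg.n_molecules,
        cfg.psf,
        cfg.camera,
        photon_dist or cfg.photons,
        rng=seed,
    )


def split_library(library: SpotLibrary, test_fraction: float, seed: int):
    """Molecule-disjoint train/test library split."""
    rng = np.random.default_rng(seed)
    ids = library.molecule_ids()
    rng.shuffle(ids)
    n_test = max(1, int(round(test_fraction * len(ids))))
    return library.subset(ids[n_test:]), library.subset(ids[:n_test])


def run_classification_benchmark(seed: int, cfg: BenchmarkConfig | None = None):
    """Train the one-vs-two classifier and measure held-out quality.

    Returns a dict with ``accuracy``, ``precision``, ``recall`` (two-emitter
    class as positive, fractions in [0, 1]), the trained classifier, and the
    library (for reuse by the other benchmarks).
    """
    cfg = cfg or BenchmarkConfig()
    library = make_library(cfg, stage_seed(seed, "library"))
    ds = build_dataset(
        library, cfg.n_per_class, (1, 2),
        rng=stage_seed(seed, "dataset"), test_fraction=0.1,
    )
    tcfg = TrainConfig(epochs=cfg.classifier_epochs, seed=stage_seed(seed, "train"))
    clf = build_model("classify", 2, tcfg)
    train(clf, ds, tcfg)
    test = ds.test()
    pred = clf.predict_count(test.images)
    cm = ConfusionMatrix.from_labels(test.counts, pred, positive=2)
    precision, recall, accuracy = classification_metrics(cm)
    log.info("classification: acc=%.4f prec=%.4f rec=%.4f (n=%d)",
             accuracy, precision, recall, len(test))
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "n_test": len(test),
        "classifier": clf,
        "library": library,
        "config": cfg,
    }


def run_generalization_benchmark(
    classifier: TrainedModel,
    seed: int,
    cfg: BenchmarkConfig | None = None,
):
    """Apply a trained classifier to an independently generated batch B.

    Batch B uses a fresh seed and a photon distribution whose median is
    shifted by the configured factor (default +10%), emulating a second
    experiment with slightly different illumination/labeling conditions.
    """
    cfg = cfg or BenchmarkConfig()
    photons_b = PhotonDistribution(
        family=cfg.photons.family,
        median=cfg.photons.median * cfg.batch_b_median_scale,
        geometric_sd=cfg.photons.geometric_sd,
        lo=cfg.photons.lo,
        hi=cfg.photons.hi,
    )
    library_b = make_library(cfg, stage_seed(seed, "batch_b"), photon_dist=photons_b,
                             n_molecules=max(1000, cfg.n_molecules // 2))
    ds_b = build_dataset(
        library_b, cfg.n_batch_b, (1, 2),
        rng=stage_seed(seed, "batch_b") + 1, test_fraction=0.0,
    )
    pred = classifier.predict_count(ds_b.images)
    cm = ConfusionMatrix.from_labels(ds_b.counts, pred, positive=2)
    precision, recall, accuracy = classification_metrics(cm)
    log.info("generalization: acc=%.4f (n=%d)", accuracy, len(ds_b))
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "n_test": len(ds_b),
    }


def _eval_rms(localizer: TrainedModel, ds: LabeledDataset) -> pd.DataFrame:
    p = ds.pixel_size_nm
    center = np.array([15 * p / 2.0, 15 * p / 2.0])
    pred = localizer.predict_coords(ds.images) + center
    rms = np.array([rms_error(pred[i], ds.coords_nm[i]) for i in range(len(ds))])
    return pd.DataFrame({"distance_nm": ds.pair_distance_nm, "rms_nm": rms})


def run_localization_benchmark(
    seed: int,
    cfg: BenchmarkConfig | None = None,
    library: SpotLibrary | None = None,
):
    """Train the two-emitter localizer and measure RMS on held-out spots.

    Evaluation sets use source molecules disjoint from training:
    ``overall`` draws separations from the natural disk-uniform
    distribution, ``close`` conditions that distribution on separations
    below 60 nm, and ``fixed30`` uses the constrained-pair sampler with the
    30 +- 2 nm interval. Returns mean RMS values in nm plus the per-bin
    table for the overall set.
    """
    cfg = cfg or BenchmarkConfig()
    if library is None:
        library = make_library(cfg, stage_seed(seed, "library"))
    lib_train, lib_eval = split_library(library, 0.1, stage_seed(seed, "dataset") + 17)

    ds_train = build_dataset(
        lib_train, cfg.n_pairs_train, (2,),
        rng=stage_seed(seed, "dataset") + 29, test_fraction=0.0,
    )
    tcfg = TrainConfig(epochs=cfg.localizer_epochs, seed=stage_seed(seed, "train") + 3)
    loc = build_model("localize", 2, tcfg)
    train(loc, ds_train, tcfg)

    eval_seed = stage_seed(seed, "eval")
    ds_overall = build_dataset(lib_eval, cfg.n_eval_overall, (2,), rng=eval_seed,
                               test_fraction=0.0)
    ds_close = build_dataset(lib_eval, cfg.n_eval_close, (2,), rng=eval_seed + 1,
                             test_fraction=0.0, distance_range_nm=(0.0, 60.0))
    ds_fixed = build_dataset(lib_eval, cfg.n_eval_fixed, (2,), rng=eval_seed + 2,
                             test_fraction=0.0, distance_interval_nm=(28.0, 32.0))

    overall = _eval_rms(loc, ds_overall)
    close = _eval_rms(loc, ds_close)
    fixed = _eval_rms(loc, ds_fixed)
    result = {
        "mean_rms_nm": float(overall["rms_nm"].mean()),
        "mean_rms_below_60_nm": float(close["rms_nm"].mean()),
        "mean_rms_at_30_nm": float(fixed["rms_nm"].mean()),
        "per_bin": bin_rms_by_distance(overall),
        "n_overall": len(overall),
        "n_close": len(close),
        "n_fixed": len(fixed),
        "localizer": loc,
    }
    log.info(
        "localization: overall=%.2f nm, <60nm=%.2f nm, 30nm=%.2f nm",
        result["mean_rms_nm"], result["mean_rms_below_60_nm"], result["mean_rms_at_30_nm"],
    )
    return result
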