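"""Classification and localization networks: losses, training, persistence.

The pipeline is two-stage: a classification network predicts the emitter
count of a 15x15 spot crop, then a count-specific localization network
regresses the 2*count emitter coordinates. Training follows the reference
recipe — Adam, batch size 64, cosine-annealed learning rate, L2 weight
penalty — with a desk-scale profile (compact backbone, tens of epochs,
larger initial learning rate) as the default and a ``paper_scale`` profile
preserving the full recipe (400 epochs, lr 1e-5 -> 1e-8, L2 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._nn import AdamState, ResidualMLP, cosine_lr, softmax
from .datasets import LabeledDataset

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "ModelBundle",
    "classification_loss",
    "localization_loss",
    "build_model",
    "train",
    "train_bundle",
]

log = logging.getLogger(__name__)

#: fixed global intensity scale (photons) used to normalize network inputs;
#: dividing by a constant rather than the per-image max keeps the absolute
#: photon count available to the network as a physical cue.
INTENSITY_SCALE = 1000.0
#: coordinate scale (nm) for regression targets relative to the crop center.
COORD_SCALE = 100.0


@dataclass
class TrainConfig:
    """Hyperparameters for one network.

    The ``compact`` backbone is a fully-connected residual network (input
    projection + ``n_blocks`` skip-connected blocks) sized for 15x15
    single-channel crops. ``loss_variant`` selects plain MSE on canonically
    ordered coordinates (default, matching the plain per-coordinate MSE
    loss) or the permutation-invariant minimum over emitter orderings.
    """

    backbone: str = "compact"
    hidden: int = 256
    n_blocks: int = 2
    epochs: int = 60
    batch_size: int = 64
    lr_initial: float = 1e-3
    lr_final: float = 1e-5
    weight_decay: float = 1e-4
    loss_variant: str = "canonical-mse"
    validation_fraction: float = 0.0
    seed: int = 0
    paper_scale: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.lr_final <= self.lr_initial):
            raise ValueError("need 0 < lr_final <= lr_initial")
        if self.loss_variant not in ("canonical-mse", "permutation-min-mse"):
            raise ValueError(f"unknown loss variant {self.loss_variant!r}")
        if self.paper_scale:
            # full reference recipe
            self.epochs = 400
            self.lr_initial, self.lr_final = 1e-5, 1e-8
            self.weight_decay = 0.01


def classification_loss(predicted_probs: np.ndarray, true_onehot: np.ndarray) -> float:
    """Cross-entropy ``-sum p(x) log q(x)`` averaged over samples.

    Returned non-negative; a zero predicted probability on the true class
    is clipped at machine epsilon (and logged) rather than returning inf.
    """
    q = np.atleast_2d(np.asarray(predicted_probs, dtype=float))
    p = np.atleast_2d(np.asarray(true_onehot, dtype=float))
    if q.shape != p.shape:
        raise ValueError("shape mismatch between prediction and truth")
    if np.any(np.abs(q.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("predicted probabilities must sum to 1")
    if np.any((q <= 0) & (p > 0)):
        import warnings

        warnings.warn("zero predicted probability on a true class; clipping",
                      stacklevel=2)
    q = np.clip(q, np.finfo(float).eps, None)
    return float(-(p * np.log(q)).sum(axis=-1).mean())


def _pair_mse(pred: np.ndarray, true: np.ndarray) -> float:
    # 1/(2I) sum_i (dx_i^2 + dy_i^2) == mean over the 2I coordinates
    return float(np.mean((pred - true) ** 2))


def localization_loss(
    pred_coords: np.ndarray,
    true_coords: np.ndarray,
    variant: str = "canonical-mse",
) -> float:
    """Coordinate-regression loss ``1/(2I) sum_i [(dx_i)^2 + (dy_i)^2]``.

    With ``variant="permutation-min-mse"`` the minimum over all emitter
    orderings of the prediction is returned (coordinates are interchangeable
    labels; the canonical variant relies on a fixed sort instead).
    """
    pred = np.atleast_2d(np.asarray(pred_coords, dtype=float))
    true = np.atleast_2d(np.asarray(true_coords, dtype=float))
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    if variant == "canonical-mse":
        return _pair_mse(pred, true)
    from itertools import permutations

    n = len(pred)
    return min(_pair_mse(pred[list(perm)], true) for perm in permutations(range(n)))


@dataclass
class TrainedModel:
    """A trained network plus the preprocessing constants it expects."""

    net: ResidualMLP
    task: str  # "classify" | "localize"
    classes: tuple[int, ...] = ()  # classifier: emitter counts, ascending
    n_emitters: int = 0  # localizer
    intensity_scale: float = INTENSITY_SCALE
    coord_scale: float = COORD_SCALE
    config: TrainConfig | None = None
    history: list[dict] = field(default_factory=list)

    def _features(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        return x.reshape(len(x), -1) / np.float32(self.intensity_scale)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities (a valid simplex) for each image."""
        if self.task != "classify":
            raise ValueError("not a classifier")
        return softmax(self.forward(images))

    def predict_count(self, images: np.ndarray) -> np.ndarray:
        """Predicted emitter count; ties break toward the lower count."""
        probs = self.predict_proba(images)
        return np.asarray(self.classes)[np.argmax(probs, axis=-1)]

    def predict_coords(self, images: np.ndarray) -> np.ndarray:
        """(N, n_emitters, 2) coordinates in nm relative to the crop center."""
        if self.task != "localize":
            raise ValueError("not a localizer")
        out = self.forward(images) * self.coord_scale
        return out.reshape(len(out), self.n_emitters, 2)

    def forward(self, images: np.ndarray) -> np.ndarray:
        return self.net.forward(self._features(images))


def build_model(task: str, n_classes_or_emitters: int, cfg: TrainConfig) -> TrainedModel:
    """Instantiate an untrained network for a task.

    Classifier head: fully-connected layer + softmax over counts.
    Localizer head: fully-connected layer emitting 2n coordinates.
    """
    if task not in ("classify", "localize"):
        raise ValueError(f"unknown task {task!r}")
    if cfg.backbone != "compact":
        raise ValueError(
            f"backbone {cfg.backbone!r} is not available in this build; "
            "only the 'compact' residual backbone is provided"
        )
    n = int(n_classes_or_emitters)
    if n < 1:
        raise ValueError("need at least one class/emitter")
    in_dim = 15 * 15
    out_dim = n if task == "classify" else 2 * n
    net = ResidualMLP(in_dim, out_dim, hidden=cfg.hidden, n_blocks=cfg.n_blocks,
                      seed=cfg.seed)
    return TrainedModel(
        net=net,
        task=task,
        classes=tuple(range(1, n + 1)) if task == "classify" else (),
        n_emitters=n if task == "localize" else 0,
        config=cfg,
    )


def _class_targets(model: TrainedModel, counts: np.ndarray) -> np.ndarray:
    classes = np.asarray(model.classes)
    idx = np.searchsorted(classes, counts)
    if np.any(classes[idx] != counts):
        raise ValueError("dataset contains counts outside the classifier's classes")
    onehot = np.zeros((len(counts), len(classes)), dtype=np.float32)
    onehot[np.arange(len(counts)), idx] = 1.0
    return onehot


def _coord_targets(model: TrainedModel, dataset: LabeledDataset) -> np.ndarray:
    k = model.n_emitters
    coords = dataset.coords_nm[:, :k, :]
    if np.any(np.isnan(coords)):
        raise ValueError("dataset contains spots with fewer emitters than the localizer expects")
    p = dataset.pixel_size_nm
    center = np.array([15 * p / 2.0, 15 * p / 2.0], dtype=np.float32)
    rel = (coords - center) / model.coord_scale
    return rel.reshape(len(coords), 2 * k).astype(np.float32)


def _perm_best_targets(pred: np.ndarray, tgt: np.ndarray, k: int) -> np.ndarray:
    """Reorder each sample's target emitters to minimize the MSE vs pred."""
    from itertools import permutations

    perms = list(permutations(range(k)))
    predr = pred.reshape(-1, k, 2)
    tgtr = tgt.reshape(-1, k, 2)
    costs = np.stack(
        [((predr - tgtr[:, perm, :]) ** 2).sum(axis=(1, 2)) for perm in perms], axis=1
    )
    best = np.argmin(costs, axis=1)
    out = np.empty_like(tgtr)
    for j, perm in enumerate(perms):
        sel = best == j
        out[sel] = tgtr[sel][:, perm, :]
    return out.reshape(len(tgt), 2 * k)


def train(
    model: TrainedModel,
    dataset: LabeledDataset,
    cfg: TrainConfig | None = None,
    val_dataset: LabeledDataset | None = None,
) -> TrainedModel:
    """Train a model in place on a dataset's train split.

    Minibatch Adam with cosine annealing; history records per-epoch train
    loss (and validation loss when a validation set is supplied). Divergence
    (non-finite loss) aborts with diagnostics.
    """
    cfg = cfg or model.config or TrainConfig()
    ds = dataset.train() if np.any(dataset.split == "train") else dataset
    x = model._features(ds.images)
    if model.task == "classify":
        y = _class_targets(model, ds.counts)
    else:
        ds = ds.subset(ds.counts == model.n_emitters)
        x = model._features(ds.images)
        y = _coord_targets(model, ds)
    if len(x) == 0:
        raise ValueError("no training samples for this task")

    rng = np.random.default_rng(cfg.seed + 7919)
    if val_dataset is None and cfg.validation_fraction > 0:
        n_val = int(round(cfg.validation_fraction * len(x)))
        perm = rng.permutation(len(x))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        xv, yv = x[val_idx], y[val_idx]
        x, y = x[tr_idx], y[tr_idx]
    elif val_dataset is not None:
        vds = val_dataset
        if model.task == "localize":
            vds = vds.subset(vds.counts == model.n_emitters)
        xv = model._features(vds.images)
        yv = _class_targets(model, vds.counts) if model.task == "classify" else _coord_targets(model, vds)
    else:
        xv = yv = None

    opt = AdamState(model.net.params)
    n = len(x)
    k = model.n_emitters
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr_initial, cfg.lr_final)
        perm = rng.permutation(n)
        total = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo: lo + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            cache: dict = {}
            out = model.net.forward(xb, cache)
            if model.task == "classify":
                probs = softmax(out)
                eps = np.finfo(np.float32).tiny
                loss = float(-(yb * np.log(np.clip(probs, eps, None))).sum() / len(xb))
                dout = (probs - yb) / np.float32(len(xb))
            else:
                if cfg.loss_variant == "permutation-min-mse" and k > 1:
                    yb = _perm_best_targets(out, yb, k)
                diff = out - yb
                loss = float(np.mean(diff**2))
                dout = (2.0 * diff / diff.size).astype(np.float32)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "reduce the learning rate"
                )
            grads = model.net.backward(cache, dout)
            opt.step(model.net.params, grads, lr, cfg.weight_decay)
            total += loss * len(xb)
        entry = {"epoch": epoch, "lr": lr, "train_loss": total / n}
        if xv is not None and len(xv):
            vout = model.net.forward(xv)
            if model.task == "classify":
                vp = softmax(vout)
                entry["val_loss"] = classification_loss(vp, yv)
                entry["val_accuracy"] = float(
                    (np.argmax(vp, axis=1) == np.argmax(yv, axis=1)).mean()
                )
            else:
                entry["val_loss"] = float(np.mean((vout - yv) ** 2))
        model.history.append(entry)
        log.debug("epoch %d: %s", epoch, entry)
    model.config = cfg
    return model


@dataclass
class ModelBundle:
    """The trained two-stage pipeline: one classifier + per-count localizers."""

    classifier: TrainedModel
    localizers: dict[int, TrainedModel]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for count, mdl in self.localizers.items():
            if mdl.net.out_dim != 2 * count:
                raise ValueError(
                    f"localizer for count {count} has output dim {mdl.net.out_dim},"
                    f" expected {2 * count}"
                )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "classifier.npz", **self.classifier.net.state_dict())
        for count, mdl in self.localizers.items():
            np.savez(path / f"localizer_{count}.npz", **mdl.net.state_dict())
        meta = {
            "classes": [int(c) for c in self.classifier.classes],
            "localizer_counts": [int(c) for c in sorted(self.localizers)],
            "intensity_scale": self.classifier.intensity_scale,
            "coord_scale": COORD_SCALE,
            "config": self.config,
            "classifier_config": asdict(self.classifier.config) if self.classifier.config else None,
        }
        (path / "bundle.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        path = Path(path)
        meta = yaml.safe_load((path / "bundle.yaml").read_text())
        cstate = dict(np.load(path / "classifier.npz"))
        classifier = TrainedModel(
            net=ResidualMLP.from_state_dict(cstate),
            task="classify",
            classes=tuple(meta["classes"]),
            intensity_scale=float(meta["intensity_scale"]),
        )
        localizers = {}
        for count in meta["localizer_counts"]:
            state = dict(np.load(path / f"localizer_{count}.npz"))
            localizers[count] = TrainedModel(
                net=ResidualMLP.from_state_dict(state),
                task="localize",
                n_emitters=int(count),
                intensity_scale=float(meta["intensity_scale"]),
                coord_scale=float(meta.get("coord_scale", COORD_SCALE)),
            )
        return cls(classifier=classifier, localizers=localizers, config=meta.get("config", {}))


def train_bundle(
    dataset: LabeledDataset,
    cfg: TrainConfig | None = None,
    localizer_cfg: TrainConfig | None = None,
    counts: tuple[int, ...] | None = None,
) -> ModelBundle:
    """Train the full two-stage pipeline on one labeled dataset."""
    cfg = cfg or TrainConfig()
    counts = counts or tuple(int(c) for c in sorted(np.unique(dataset.counts)))
    classifier = build_model("classify", max(counts), cfg)
    classifier.classes = tuple(counts)
    classifier.net = ResidualMLP(15 * 15, len(counts), cfg.hidden, cfg.n_blocks, cfg.seed)
    train(classifier, dataset, cfg)
    localizers = {}
    lcfg = localizer_cfg or cfg
    for count in counts:
        mdl = build_model("localize", count, lcfg)
        train(mdl, dataset, lcfg)
        localizers[count] = mdl
    return ModelBundle(classifier=classifier, localizers=localizers,
                       config={"counts": list(counts)})
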