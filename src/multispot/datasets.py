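"""Multi-emitter labeled dataset construction.

Sub-diffraction-limited multi-emitter spots are derived by superimposing
single-emitter library spots: each library crop is translated (sub-pixel,
Fourier shift by default) so that its Gaussian-fitted emitter position
lands on a target coordinate drawn inside a 240 nm disk, then the crops
are summed pixel-wise. The target coordinates become the ground-truth
labels, so labels are available without any extra information — exactly
the property that makes library-derived training data possible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .library import SpotLibrary, SpotRecord
from .synthetic import SpotImage, _as_rng

__all__ = [
    "LabeledSpot",
    "LabeledDataset",
    "sample_emitter_coordinates",
    "sample_constrained_pair",
    "translate_record",
    "merge_spots",
    "pad_to_input",
    "build_dataset",
    "DEFAULT_DIAMETER_NM",
]

log = logging.getLogger(__name__)

DEFAULT_DIAMETER_NM = 240.0  # Abbe limit for AF647 at NA 1.4, 160 nm pixels
INPUT_SHAPE = (15, 15)


@dataclass
class LabeledSpot:
    """A 15x15 spot image with ground-truth emitter count and coordinates.

    ``coords_nm`` are in the crop frame (nm from the crop's top-left
    corner), canonically ordered (sorted by x, ties by y).
    """

    image: SpotImage
    count: int
    coords_nm: np.ndarray  # (count, 2) as (x, y)
    pair_distance_nm: float = float("nan")  # max pairwise distance, NaN for singles
    source_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.coords_nm = np.atleast_2d(np.asarray(self.coords_nm, dtype=float))
        if self.count != len(self.coords_nm):
            raise ValueError("count must equal number of coordinates")
        if not (1 <= self.count <= 4):
            raise ValueError("emitter count must be in {1,2,3,4}")
        h, w = self.image.shape
        p = self.image.pixel_size_nm
        if np.any(self.coords_nm < 0) or np.any(
            self.coords_nm > [w * p, h * p]
        ):
            raise ValueError("emitter coordinates must lie inside the crop")


@dataclass
class LabeledDataset:
    """Array-backed labeled spot collection with a train/test split.

    ``coords_nm`` is (N, max_count, 2), NaN-padded beyond each spot's count.
    """

    images: np.ndarray  # (N, 15, 15) float32
    counts: np.ndarray  # (N,) int
    coords_nm: np.ndarray  # (N, K, 2)
    pair_distance_nm: np.ndarray  # (N,)
    split: np.ndarray  # (N,) of "train"/"test"
    pixel_size_nm: float = 160.0
    seed: int | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.counts) == len(self.coords_nm) == len(self.split) == n):
            raise ValueError("inconsistent dataset arrays")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, mask) -> "LabeledDataset":
        mask = np.asarray(mask)
        return LabeledDataset(
            images=self.images[mask],
            counts=self.counts[mask],
            coords_nm=self.coords_nm[mask],
            pair_distance_nm=self.pair_distance_nm[mask],
            split=self.split[mask],
            pixel_size_nm=self.pixel_size_nm,
            seed=self.seed,
            config=dict(self.config),
        )

    def train(self) -> "LabeledDataset":
        return self.subset(self.split == "train")

    def test(self) -> "LabeledDataset":
        return self.subset(self.split == "test")

    def content_hash(self) -> str:
        hsh = hashlib.sha256()
        hsh.update(np.ascontiguousarray(self.images).tobytes())
        hsh.update(np.ascontiguousarray(self.counts).tobytes())
        hsh.update(np.ascontiguousarray(self.coords_nm).tobytes())
        return hsh.hexdigest()


def _snap_to_grid(pts: np.ndarray, grid_nm: float) -> np.ndarray:
    return np.round(pts / grid_nm) * grid_nm


def sample_emitter_coordinates(
    n_emitters: int,
    diameter_nm: float = DEFAULT_DIAMETER_NM,
    grid_nm: float = 1.0,
    rng=None,
) -> np.ndarray:
    """Uniform points inside a sub-diffraction disk, snapped to a 1 nm grid.

    Points uniform in a disk of the given diameter are automatically within
    ``diameter_nm`` of each other, so every pairwise distance stays below
    the diffraction limit. Returns an (n, 2) array centered on the origin.
    """
    if n_emitters < 2:
        raise ValueError("n_emitters must be >= 2 (singles need no placement)")
    if diameter_nm <= 0 or grid_nm <= 0:
        raise ValueError("diameter and grid must be > 0")
    rng = _as_rng(rng)
    radius = diameter_nm / 2.0
    out = np.empty((n_emitters, 2))
    filled = 0
    while filled < n_emitters:
        cand = rng.uniform(-radius, radius, size=(2 * (n_emitters - filled) + 4, 2))
        cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= radius]
        take = min(len(cand), n_emitters - filled)
        out[filled: filled + take] = cand[:take]
        filled += take
    out = _snap_to_grid(out, grid_nm)
    # grid snapping can push a pair marginally past the diameter; redraw then
    if n_emitters >= 2:
        d = np.linalg.norm(out[:, None, :] - out[None, :, :], axis=-1)
        if d.max() > diameter_nm:
            return sample_emitter_coordinates(n_emitters, diameter_nm, grid_nm, rng)
    return out


def sample_constrained_pair(
    distance_nm: tuple[float, float],
    rng=None,
    grid_nm: float = 1.0,
) -> np.ndarray:
    """Two points at a controlled separation with random orientation.

    The separation is uniform in ``distance_nm = (lo, hi)`` (use
    ``(30, 30)`` or ``(28, 32)`` for fixed-distance evaluation subsets) and
    the orientation uniform on [0, 2pi). Grid snapping perturbs the realized
    distance by at most sqrt(2) nm.
    """
    lo, hi = float(distance_nm[0]), float(distance_nm[1])
    if not (0.0 < lo <= hi <= DEFAULT_DIAMETER_NM):
        raise ValueError("distance interval must lie within (0, 240]")
    rng = _as_rng(rng)
    d = rng.uniform(lo, hi)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    half = 0.5 * d * np.array([np.cos(theta), np.sin(theta)])
    return _snap_to_grid(np.stack([-half, half]), grid_nm)


def _fourier_shift(img: np.ndarray, shift_rc: tuple[float, float]) -> np.ndarray:
    """Sub-pixel shift via the Fourier shift theorem, zero-padded 3x.

    Returns the full padded array (input at its center block): keeping the
    interpolation tails preserves total flux exactly (the DC component is
    untouched by a phase ramp); the caller accounts for the margin.
    """
    h, w = img.shape
    padded = np.zeros((3 * h, 3 * w))
    padded[h: 2 * h, w: 2 * w] = img
    f = np.fft.fft2(padded)
    f = ndimage.fourier_shift(f, shift_rc)
    return np.fft.ifft2(f).real


def translate_record(
    record: SpotRecord,
    target_xy_nm: tuple[float, float],
    canvas: np.ndarray,
    pixel_size_nm: float,
    method: str = "fourier",
) -> None:
    """Add a record's image into ``canvas`` so its fitted emitter position
    lands on ``target_xy_nm`` (canvas-frame nm). Modifies ``canvas`` in place.
    """
    if record.fit is None:
        raise ValueError("record must carry a Gaussian fit to be used as an anchor")
    p = pixel_size_nm
    img = record.image.pixels
    # emitter position in the record's local crop frame
    qx = record.fit.x0_nm - record.image.offset_nm[0]
    qy = record.fit.y0_nm - record.image.offset_nm[1]
    sx = (target_xy_nm[0] - qx) / p  # shift in pixels, x = columns
    sy = (target_xy_nm[1] - qy) / p
    kx, ky = int(np.round(sx)), int(np.round(sy))
    fx, fy = sx - kx, sy - ky
    h, w = img.shape
    if method == "fourier":
        shifted = _fourier_shift(img, (fy, fx))
        ky -= h  # the shifted array carries a (h, w) padding margin
        kx -= w
        h, w = shifted.shape
    elif method == "bilinear":
        shifted = ndimage.shift(img, (fy, fx), order=1, mode="constant")
    else:
        raise ValueError(f"unknown translation method {method!r}")
    H, W = canvas.shape
    rlo, rhi = ky, ky + h
    clo, chi = kx, kx + w
    src_rlo, src_clo = max(0, -rlo), max(0, -clo)
    rlo, clo = max(0, rlo), max(0, clo)
    rhi, chi = min(H, rhi), min(W, chi)
    if rhi <= rlo or chi <= clo:
        raise ValueError("translated spot falls entirely outside the canvas")
    canvas[rlo:rhi, clo:chi] += shifted[
        src_rlo: src_rlo + (rhi - rlo), src_clo: src_clo + (chi - clo)
    ]


def _canonical_order(coords: np.ndarray) -> np.ndarray:
    order = np.lexsort((coords[:, 1], coords[:, 0]))  # by x, ties by y
    return coords[order]


def merge_spots(
    records: list[SpotRecord],
    target_coords_nm: np.ndarray,
    out_shape_px: tuple[int, int] = INPUT_SHAPE,
    method: str = "fourier",
) -> LabeledSpot:
    """Superimpose library spots at target coordinates on one canvas.

    One record per target; each record is translated so its fitted anchor
    position coincides with its target, then all images are summed. The
    targets (canonically ordered) become the spot's ground-truth label.
    """
    target_coords_nm = np.atleast_2d(np.asarray(target_coords_nm, dtype=float))
    if len(records) != len(target_coords_nm):
        raise ValueError("need exactly one record per target coordinate")
    if not records:
        raise ValueError("need at least one record")
    p = records[0].image.pixel_size_nm
    h, w = out_shape_px
    if np.any(target_coords_nm < 0) or np.any(target_coords_nm > [w * p, h * p]):
        raise ValueError("target coordinates must lie inside the output crop")
    canvas = np.zeros(out_shape_px)
    for rec, tgt in zip(records, target_coords_nm):
        translate_record(rec, tgt, canvas, p, method=method)
    coords = _canonical_order(target_coords_nm)
    n = len(coords)
    dist = float("nan")
    if n >= 2:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        dist = float(d.max())
    return LabeledSpot(
        image=SpotImage(canvas, offset_nm=(0.0, 0.0), pixel_size_nm=p),
        count=n,
        coords_nm=coords,
        pair_distance_nm=dist,
        source_ids=tuple(r.molecule_id for r in records),
    )


def pad_to_input(image: SpotImage, target_px: tuple[int, int] = INPUT_SHAPE) -> SpotImage:
    """Zero-pad an image to the network input shape, centered.

    The crop offset is updated so any global coordinate keeps its meaning
    after padding (round-trip safe). Input larger than target is an error.
    """
    h, w = image.shape
    H, W = target_px
    if h > H or w > W:
        raise ValueError(f"input {image.shape} larger than target {target_px}")
    top, left = (H - h) // 2, (W - w) // 2
    out = np.zeros((H, W))
    out[top: top + h, left: left + w] = image.pixels
    p = image.pixel_size_nm
    return SpotImage(
        out,
        offset_nm=(image.offset_nm[0] - left * p, image.offset_nm[1] - top * p),
        pixel_size_nm=p,
    )


def build_dataset(
    library: SpotLibrary,
    n_per_class: int,
    classes: tuple[int, ...] = (1, 2),
    rng=None,
    diameter_nm: float = DEFAULT_DIAMETER_NM,
    test_fraction: float = 0.1,
    jitter_px: float = 0.5,
    method: str = "fourier",
    distance_interval_nm: tuple[float, float] | None = None,
    distance_range_nm: tuple[float, float] | None = None,
) -> LabeledDataset:
    """Build a balanced labeled train/test dataset from a spot library.

    Emitter coordinates are sampled uniformly in the 240 nm disk (or with
    ``distance_interval_nm`` via the constrained-pair sampler, classes must
    then be pairs only), placed on a 15x15 canvas whose center carries the
    coordinate centroid plus a +-``jitter_px`` uniform jitter, and library
    records (sampled with replacement) are merged at those targets. Source
    molecules are split disjointly between train and test to prevent
    leakage through reused spots.

    ``distance_interval_nm`` switches pair placement to the constrained-pair
    sampler (separation uniform in the interval); ``distance_range_nm``
    instead keeps the natural disk-uniform placement but rejection-samples
    until the pair distance falls in the range (i.e. the conditional
    distribution of the full generator).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    rng = _as_rng(rng)
    if distance_interval_nm is not None and any(c != 2 for c in classes):
        raise ValueError("distance_interval_nm only applies to two-emitter classes")
    p = library.camera.pixel_size_nm
    H, W = INPUT_SHAPE
    center = np.array([W * p / 2.0, H * p / 2.0])

    mol_ids = library.molecule_ids()
    rng.shuffle(mol_ids)
    n_test_mol = max(1, int(round(test_fraction * len(mol_ids)))) if test_fraction > 0 else 0
    pools = {
        "test": library.subset(mol_ids[:n_test_mol]) if n_test_mol else None,
        "train": library.subset(mol_ids[n_test_mol:]),
    }

    images, counts, coords_all, dists, split = [], [], [], [], []
    max_k = max(classes)
    for cls in classes:
        for part in ("train", "test"):
            pool = pools[part]
            if pool is None:
                continue
            n_part = int(round(n_per_class * (test_fraction if part == "test" else 1 - test_fraction)))
            recs = pool.records
            for _ in range(n_part):
                if cls == 1:
                    rel = np.zeros((1, 2))
                elif distance_interval_nm is not None:
                    rel = sample_constrained_pair(distance_interval_nm, rng)
                else:
                    while True:
                        rel = sample_emitter_coordinates(cls, diameter_nm, rng=rng)
                        if distance_range_nm is None:
                            break
                        dmax = np.linalg.norm(rel[:, None] - rel[None, :], axis=-1).max()
                        if distance_range_nm[0] < dmax <= distance_range_nm[1]:
                            break
                jitter = rng.uniform(-jitter_px, jitter_px, size=2) * p
                targets = rel - rel.mean(axis=0) + center + jitter
                chosen = [recs[i] for i in rng.integers(0, len(recs), size=cls)]
                spot = merge_spots(chosen, targets, method=method)
                images.append(spot.image.pixels.astype(np.float32))
                counts.append(spot.count)
                cpad = np.full((max_k, 2), np.nan)
                cpad[: spot.count] = spot.coords_nm
                coords_all.append(cpad)
                dists.append(spot.pair_distance_nm)
                split.append(part)

    order = rng.permutation(len(images))
    return LabeledDataset(
        images=np.stack(images)[order],
        counts=np.asarray(counts)[order],
        coords_nm=np.stack(coords_all)[order],
        pair_distance_nm=np.asarray(dists)[order],
        split=np.asarray(split, dtype=object)[order],
        pixel_size_nm=p,
        config={
            "classes": list(classes),
            "n_per_class": n_per_class,
            "diameter_nm": diameter_nm,
            "test_fraction": test_fraction,
            "jitter_px": jitter_px,
            "method": method,
            "distance_interval_nm": distance_interval_nm,
        },
    )
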