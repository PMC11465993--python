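"""Two-stage frame-level inference.

For each camera frame: detect candidate spots, refine each center with a
single 2D Gaussian fit (for a multi-emitter spot this gives only an
approximate center — which is all the crop placement needs), cut an 11x11
crop around the fitted center, zero-pad it to the 15x15 network input,
classify the emitter count, route the crop to the count-matched
localization network, and map the predicted coordinates back to the
global frame in nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import pad_to_input
from .io import LocalizationTable
from .library import DetectConfig, GaussianFitError, crop_spot, detect_spot_centers, fit_gaussian_2d
from .models import ModelBundle
from .synthetic import CameraModel, SpotImage

__all__ = ["PredictionRecord", "preprocess_crop", "predict_spot", "process_frame", "process_stack"]

log = logging.getLogger(__name__)

INFERENCE_RADIUS_PX = 5  # 11x11 crops around the fitted center


@dataclass
class PredictionRecord:
    """Prediction for one detected spot."""

    frame_index: int
    crop_offset_nm: tuple[float, float]
    count: int
    confidence: np.ndarray  # class-probability simplex
    coords_nm: np.ndarray  # (count, 2) global-frame positions
    photons: float = float("nan")
    border_clipped: bool = False

    def __post_init__(self) -> None:
        self.coords_nm = np.atleast_2d(np.asarray(self.coords_nm, dtype=float))
        if len(self.coords_nm) != self.count:
            raise ValueError("number of coordinates must equal predicted count")
        total = float(np.sum(self.confidence))
        if not np.isclose(total, 1.0, atol=1e-5):
            raise ValueError("confidence must sum to 1")


def preprocess_crop(
    frame: np.ndarray,
    center_px: tuple[int, int],
    camera: CameraModel = CameraModel(),
) -> SpotImage:
    """11x11 crop around a center pixel, zero-padded to 15x15 with offset."""
    crop = crop_spot(frame, center_px, INFERENCE_RADIUS_PX, camera=camera)
    return pad_to_input(crop)


def predict_spot(bundle: ModelBundle, crop: SpotImage, frame_index: int = 0) -> PredictionRecord:
    """Classify a 15x15 crop and regress its emitter coordinates.

    Ties in class probability resolve to the lower count (conservative).
    The localizer for the predicted count must exist in the bundle.
    """
    probs = bundle.classifier.predict_proba(crop.pixels)[0]
    classes = np.asarray(bundle.classifier.classes)
    count = int(classes[np.argmax(probs)])  # argmax returns first max -> lower count
    if count not in bundle.localizers:
        raise KeyError(f"bundle has no localizer for predicted count {count}")
    rel = bundle.localizers[count].predict_coords(crop.pixels)[0]
    cx, cy = crop.center_nm()
    coords = rel + np.array([cx, cy])
    return PredictionRecord(
        frame_index=frame_index,
        crop_offset_nm=crop.offset_nm,
        count=count,
        confidence=probs,
        coords_nm=coords,
        photons=float(crop.pixels.sum()),
    )


def _merge_close_centers(centers: list[tuple[int, int]], min_px: float = 2.0) -> list[tuple[int, int]]:
    kept: list[tuple[int, int]] = []
    for r, c in centers:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_px**2 for kr, kc in kept):
            kept.append((r, c))
    return kept


def process_frame(
    frame: np.ndarray,
    bundle: ModelBundle,
    camera: CameraModel = CameraModel(),
    detect_cfg: DetectConfig = DetectConfig(),
    frame_index: int = 0,
) -> list[PredictionRecord]:
    """Detect, crop, classify, and localize every spot in one frame."""
    frame = np.asarray(frame, dtype=float)
    records: list[PredictionRecord] = []
    centers = _merge_close_centers(detect_spot_centers(frame, detect_cfg))
    h, w = frame.shape
    for r, c in centers:
        # refine the crop center with a single-Gaussian fit on a 7x7 crop
        try:
            small = crop_spot(frame, (r, c), 3, camera=camera)
            fit = fit_gaussian_2d(small)
            rc = int(fit.y0_nm // camera.pixel_size_nm)
            cc = int(fit.x0_nm // camera.pixel_size_nm)
            rc, cc = min(max(rc, 0), h - 1), min(max(cc, 0), w - 1)
        except GaussianFitError:
            rc, cc = r, c
        crop = preprocess_crop(frame, (rc, cc), camera)
        rec = predict_spot(bundle, crop, frame_index=frame_index)
        rec.border_clipped = not (
            INFERENCE_RADIUS_PX <= rc < h - INFERENCE_RADIUS_PX
            and INFERENCE_RADIUS_PX <= cc < w - INFERENCE_RADIUS_PX
        )
        records.append(rec)
    return records


def process_stack(
    stack,
    bundle: ModelBundle,
    camera: CameraModel = CameraModel(),
    detect_cfg: DetectConfig = DetectConfig(),
    progress: bool = False,
) -> LocalizationTable:
    """Run frame-level inference over an image sequence.

    Unreadable frames are skipped with a logged error; the resulting table
    concatenates all per-frame predictions with their frame indices.
    """
    rows = []
    n_errors = 0
    frames = enumerate(stack)
    if progress:
        from tqdm import tqdm

        frames = tqdm(list(frames), desc="frames")
    for idx, frame in frames:
        try:
            records = process_frame(frame, bundle, camera, detect_cfg, frame_index=idx)
        except Exception:
            n_errors += 1
            log.exception("failed to process frame %d; skipping", idx)
            continue
        for spot_id, rec in enumerate(records):
            conf = float(np.max(rec.confidence))
            for x, y in rec.coords_nm:
                rows.append(
                    {
                        "frame": idx,
                        "spot": spot_id,
                        "x_nm": float(x),
                        "y_nm": float(y),
                        "photons": rec.photons,
                        "count": rec.count,
                        "confidence": conf,
                        "border_clipped": rec.border_clipped,
                        "source": "prediction",
                    }
                )
    if n_errors:
        log.warning("%d frame(s) failed during processing", n_errors)
    return LocalizationTable.from_rows(rows)
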