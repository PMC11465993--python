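"""Single-molecule spot detection, cropping, and 2D Gaussian fitting.

Builds the single-emitter spot library: detect candidate spots in camera
frames, cut small crops around them, least-squares fit a pixel-integrated
2D Gaussian to each crop, and compute the per-spot summary statistics
(photon count, relative area ``2*sigma_x * 2*sigma_y``, ellipticity
``sigma_x / sigma_y``) used to show that one- and two-emitter spots are
morphologically indistinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .synthetic import CameraModel, SpotImage, _axis_mass

__all__ = [
    "GaussianFit",
    "GaussianFitError",
    "SpotRecord",
    "SpotLibrary",
    "DetectConfig",
    "detect_spot_centers",
    "crop_spot",
    "fit_gaussian_2d",
    "spot_photons",
    "relative_area",
    "ellipticity",
]

log = logging.getLogger(__name__)


class GaussianFitError(RuntimeError):
    """Raised when a spot cannot be fitted (flat input or non-convergence)."""


@dataclass(frozen=True)
class GaussianFit:
    """Result of a 2D Gaussian least-squares fit.

    ``x0_nm, y0_nm`` are in the global frame. ``height`` is the peak
    intensity of the continuous Gaussian profile expressed in photons per
    pixel area; ``amplitude_photons`` is the fitted total photon flux.
    ``sigma_x_nm``/``sigma_y_nm`` are the Gaussian standard deviations
    (equal to the fitted widths w_x, w_y of the elliptical form).
    """

    amplitude_photons: float
    x0_nm: float
    y0_nm: float
    sigma_x_nm: float
    sigma_y_nm: float
    offset: float = 0.0
    residual_ss: float = float("nan")

    def __post_init__(self) -> None:
        if self.sigma_x_nm <= 0 or self.sigma_y_nm <= 0:
            raise ValueError("fitted widths must be > 0")

    @property
    def height(self) -> float:
        return self.amplitude_photons / (2.0 * np.pi * self.sigma_x_nm * self.sigma_y_nm)

    @property
    def center_nm(self) -> tuple[float, float]:
        return (self.x0_nm, self.y0_nm)


@dataclass
class SpotRecord:
    """One library entry: a spot crop plus its fit and provenance."""

    image: SpotImage
    fit: GaussianFit | None
    photons: float
    frame_index: int = 0
    molecule_id: int = -1
    true_xy_nm: tuple[float, float] | None = None
    true_photons: float | None = None


@dataclass
class SpotLibrary:
    """Collection of single-emitter spot records sharing one camera model."""

    records: list[SpotRecord]
    camera: CameraModel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("SpotLibrary must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> SpotRecord:
        return self.records[i]

    def molecule_ids(self) -> np.ndarray:
        return np.array(sorted({r.molecule_id for r in self.records}))

    def subset(self, molecule_ids) -> "SpotLibrary":
        ids = set(int(m) for m in np.asarray(molecule_ids).ravel())
        recs = [r for r in self.records if r.molecule_id in ids]
        return SpotLibrary(records=recs, camera=self.camera, meta=dict(self.meta))


@dataclass(frozen=True)
class DetectConfig:
    """Spot-detection settings: difference-of-Gaussians band-pass + maxima.

    The band-pass filter (sigma_small=1 px, sigma_large=3 px) suppresses
    pixel noise for detection only; the raw pixels are what gets cropped
    and fitted.
    """

    sigma_small_px: float = 1.0
    sigma_large_px: float = 3.0
    threshold_k: float = 5.0  # multiples of the robust background SD
    min_separation_px: int = 4


def detect_spot_centers(frame: np.ndarray, cfg: DetectConfig = DetectConfig()) -> list[tuple[int, int]]:
    """Local maxima of the band-pass-filtered frame above a robust threshold.

    Returns pixel centers as ``(row, col)`` tuples, at most one per spot
    footprint (maxima closer than ``min_separation_px`` are merged, keeping
    the brighter one). An empty or featureless frame yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    if frame.size == 0 or not np.any(frame != frame.flat[0]):
        return []
    dog = ndimage.gaussian_filter(frame, cfg.sigma_small_px) - ndimage.gaussian_filter(
        frame, cfg.sigma_large_px
    )
    med = np.median(dog)
    mad = np.median(np.abs(dog - med))
    thr = med + cfg.threshold_k * 1.4826 * mad
    size = 2 * cfg.min_separation_px + 1
    is_max = (dog == ndimage.maximum_filter(dog, size=size)) & (dog > thr) & (dog > 0)
    peaks = np.argwhere(is_max)
    if peaks.size == 0:
        return []
    # greedy non-maximum suppression, brightest first
    order = np.argsort(-dog[peaks[:, 0], peaks[:, 1]])
    kept: list[tuple[int, int]] = []
    for idx in order:
        r, c = int(peaks[idx, 0]), int(peaks[idx, 1])
        if all((r - kr) ** 2 + (c - kc) ** 2 >= cfg.min_separation_px**2 for kr, kc in kept):
            kept.append((r, c))
    return kept


def crop_spot(
    frame: np.ndarray,
    center_px: tuple[int, int],
    radius_px: int,
    camera: CameraModel = CameraModel(),
    frame_offset_nm: tuple[float, float] = (0.0, 0.0),
) -> SpotImage:
    """Cut a ``(2r+1) x (2r+1)`` crop around a pixel center.

    Radius 3 gives the 7x7 library crop; radius 5 the 11x11 inference crop.
    Pixels outside the frame are zero-filled; the crop's global offset is
    recorded so coordinates survive the round trip.
    """
    frame = np.asarray(frame, dtype=float)
    r0, c0 = int(center_px[0]), int(center_px[1])
    h, w = frame.shape
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise IndexError(f"center {center_px} outside frame of shape {frame.shape}")
    r = int(radius_px)
    out = np.zeros((2 * r + 1, 2 * r + 1))
    rlo, rhi = max(0, r0 - r), min(h, r0 + r + 1)
    clo, chi = max(0, c0 - r), min(w, c0 + r + 1)
    out[rlo - (r0 - r): rlo - (r0 - r) + (rhi - rlo),
        clo - (c0 - r): clo - (c0 - r) + (chi - clo)] = frame[rlo:rhi, clo:chi]
    p = camera.pixel_size_nm
    offset = (frame_offset_nm[0] + (c0 - r) * p, frame_offset_nm[1] + (r0 - r) * p)
    return SpotImage(out, offset_nm=offset, pixel_size_nm=p)


def _model_image(params, n_px, pixel_nm, isotropic):
    if isotropic:
        amp, x0, y0, sx, b = params
        sy = sx
    else:
        amp, x0, y0, sx, sy, b = params
    h, w = n_px
    mx = _axis_mass(x0, sx, w, pixel_nm, 0.0)
    my = _axis_mass(y0, sy, h, pixel_nm, 0.0)
    return amp * np.outer(my, mx) + b


def fit_gaussian_2d(
    spot: SpotImage,
    isotropic: bool = False,
    fit_background: bool = True,
) -> GaussianFit:
    """Least-squares fit of a pixel-integrated 2D Gaussian to one crop.

    The model integrates the Gaussian over each pixel's area (consistent
    with the renderer). Initialization: center at the photon centroid,
    sigma = 1 pixel, amplitude = background-subtracted sum; a bounded
    trust-region solver keeps the center inside the crop.
    """
    img = spot.pixels
    p = spot.pixel_size_nm
    h, w = img.shape
    total = img.sum()
    if total <= 0 or np.ptp(img) == 0:
        raise GaussianFitError("flat or empty spot, nothing to fit")

    b0 = float(np.median(np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])))
    pos = np.clip(img - b0, 0, None)
    psum = pos.sum()
    if psum <= 0:
        raise GaussianFitError("no signal above background")
    ys, xs = np.mgrid[0:h, 0:w]
    x0 = float((pos * (xs + 0.5)).sum() / psum) * p
    y0 = float((pos * (ys + 0.5)).sum() / psum) * p

    if isotropic:
        init = [psum, x0, y0, p, b0]
        lo = [0.0, 0.0, 0.0, 0.2 * p, -np.inf]
        hi = [np.inf, w * p, h * p, 5.0 * p, np.inf]
    else:
        init = [psum, x0, y0, p, p, b0]
        lo = [0.0, 0.0, 0.0, 0.2 * p, 0.2 * p, -np.inf]
        hi = [np.inf, w * p, h * p, 5.0 * p, 5.0 * p, np.inf]
    if not fit_background:
        init, lo, hi = init[:-1], lo[:-1], hi[:-1]

        def resid(q):
            return (_model_image(np.r_[q, 0.0], (h, w), p, isotropic) - img).ravel()
    else:

        def resid(q):
            return (_model_image(q, (h, w), p, isotropic) - img).ravel()

    init = np.clip(init, lo, hi)
    try:
        res = least_squares(resid, init, bounds=(lo, hi), method="trf",
                            xtol=1e-10, ftol=1e-10)
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise GaussianFitError(f"optimizer failure: {exc}") from exc
    if not res.success and res.status <= 0:
        raise GaussianFitError(f"fit did not converge: {res.message}")
    q = res.x
    if isotropic:
        amp, fx, fy, fsx = q[0], q[1], q[2], q[3]
        fsy = fsx
        b = q[4] if fit_background else 0.0
    else:
        amp, fx, fy, fsx, fsy = q[0], q[1], q[2], q[3], q[4]
        b = q[5] if fit_background else 0.0
    return GaussianFit(
        amplitude_photons=float(amp),
        x0_nm=float(fx) + spot.offset_nm[0],
        y0_nm=float(fy) + spot.offset_nm[1],
        sigma_x_nm=float(fsx),
        sigma_y_nm=float(fsy),
        offset=float(b),
        residual_ss=float(np.sum(res.fun**2)),
    )


def spot_photons(spot: SpotImage) -> float:
    """Photon count of a spot: the plain sum over all crop pixels."""
    return float(np.asarray(spot.pixels).sum())


def relative_area(fit: GaussianFit) -> float:
    """Relative spot area ``2 sigma_x * 2 sigma_y`` in nm^2."""
    return 4.0 * fit.sigma_x_nm * fit.sigma_y_nm


def ellipticity(fit: GaussianFit) -> float:
    """Spot ellipticity: the width ratio ``sigma_x / sigma_y``."""
    if fit.sigma_y_nm == 0:
        raise ValueError("sigma_y must be nonzero")
    return fit.sigma_x_nm / fit.sigma_y_nm
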