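"""Synthetic single-emitter spot generation.

This module emulates an experimental STORM single-fluorophore (AF647-like)
spot library so every downstream stage — Gaussian fitting, multi-emitter
dataset construction, network training, frame simulation — can be exercised
without microscope data.

Conventions
-----------
The global frame has its origin at the top-left corner of pixel ``(0, 0)``,
x increasing rightward (columns), y increasing downward (rows). Pixel
``(row i, col j)`` covers the half-open square
``[j*p, (j+1)*p) x [i*p, (i+1)*p)`` nm where ``p`` is the pixel size.
Emitter coordinates are continuous and expressed in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "CameraModel",
    "PsfModel",
    "PhotonDistribution",
    "BlinkKinetics",
    "BlinkTrace",
    "SpotImage",
    "abbe_limit",
    "render_psf",
    "add_camera_noise",
    "sample_blink_trace",
    "build_synthetic_library",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def abbe_limit(wavelength_nm: float = 670.0, na: float = 1.4) -> float:
    """Abbe diffraction limit ``lambda / (2 NA)`` in nm.

    Defaults correspond to AF647 emission (~670 nm) imaged at NA 1.4,
    giving ~240 nm — the sub-diffraction threshold used throughout.
    """
    if wavelength_nm <= 0 or na <= 0:
        raise ValueError("wavelength and NA must be positive")
    return wavelength_nm / (2.0 * na)


@dataclass(frozen=True)
class CameraModel:
    """Idealized sCMOS/EMCCD camera: unit gain, Poisson photons.

    Parameters
    ----------
    pixel_size_nm : back-projected pixel size (nm).
    read_noise_e : Gaussian read noise RMS in electrons (= photons at unit
        gain).
    background_photons_per_px : mean background photons per pixel per frame.
    """

    pixel_size_nm: float = 160.0
    read_noise_e: float = 1.5
    background_photons_per_px: float = 10.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.read_noise_e < 0 or self.background_photons_per_px < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class PsfModel:
    """2D Gaussian PSF; isotropic by default, optionally anisotropic."""

    sigma_nm: float = 102.0
    sigma_x_nm: float | None = None
    sigma_y_nm: float | None = None

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("PSF sigma must be > 0")

    @property
    def sx(self) -> float:
        return self.sigma_nm if self.sigma_x_nm is None else self.sigma_x_nm

    @property
    def sy(self) -> float:
        return self.sigma_nm if self.sigma_y_nm is None else self.sigma_y_nm


@dataclass(frozen=True)
class PhotonDistribution:
    """Per-blink photon count distribution.

    The default is a broad truncated lognormal (median 5000, geometric SD
    1.8, truncated to [500, 50000]) emulating the wide experimental
    photon-count spread of single AF647 switching events. ``family`` may be
    ``"lognormal"`` or ``"constant"`` (the latter mainly for tests).
    """

    family: str = "lognormal"
    median: float = 5000.0
    geometric_sd: float = 1.8
    lo: float = 500.0
    hi: float = 50000.0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "constant"):
            raise ValueError(f"unknown photon distribution family {self.family!r}")
        if self.median <= 0 or self.lo < 0 or self.hi <= self.lo:
            raise ValueError("invalid photon distribution parameters")
        if self.family == "lognormal" and self.geometric_sd <= 1.0:
            raise ValueError("geometric_sd must be > 1")

    def sample(self, rng, size: int | tuple = 1) -> np.ndarray:
        rng = _as_rng(rng)
        if self.family == "constant":
            return np.full(size, float(self.median))
        mu, s = np.log(self.median), np.log(self.geometric_sd)
        out = rng.lognormal(mu, s, size=size)
        bad = (out < self.lo) | (out > self.hi)
        while np.any(bad):  # truncation by resampling
            out[bad] = rng.lognormal(mu, s, size=int(bad.sum()))
            bad = (out < self.lo) | (out > self.hi)
        return out

    def quantile(self, q) -> np.ndarray:
        """Quantiles of the truncated distribution (for checks/reports)."""
        from scipy.stats import lognorm

        if self.family == "constant":
            return np.full_like(np.asarray(q, dtype=float), self.median)
        mu, s = np.log(self.median), np.log(self.geometric_sd)
        dist = lognorm(s=s, scale=np.exp(mu))
        plo, phi = dist.cdf(self.lo), dist.cdf(self.hi)
        return dist.ppf(plo + np.asarray(q, dtype=float) * (phi - plo))


@dataclass(frozen=True)
class BlinkKinetics:
    """Two-state (on/off) Markov blinking, per-frame transition probabilities.

    ``p_on`` is P(off -> on) per frame; ``p_off`` is P(on -> off) per frame,
    so the mean on-duration is ``1 / p_off`` frames and the stationary
    on-fraction is ``p_on / (p_on + p_off)``.
    """

    p_on: float = 1e-3
    p_off: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.p_on, self.p_off):
            if not (0.0 <= p <= 1.0):
                raise ValueError("transition probabilities must be in [0, 1]")

    @property
    def stationary_on_fraction(self) -> float:
        if self.p_on == 0.0:
            return 0.0
        return self.p_on / (self.p_on + self.p_off)


@dataclass
class BlinkTrace:
    """Per-frame photon emission of one molecule over an image sequence."""

    molecule_id: int
    photons: np.ndarray  # shape (n_frames,), >= 0, zero when off

    def __post_init__(self) -> None:
        self.photons = np.asarray(self.photons, dtype=float)
        if np.any(self.photons < 0):
            raise ValueError("photon counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(self.photons.size)

    @property
    def on_frames(self) -> np.ndarray:
        return np.flatnonzero(self.photons > 0)

    def on_segments(self) -> list[tuple[int, int]]:
        """Contiguous on-state runs as (start, stop) half-open frame spans."""
        on = self.photons > 0
        edges = np.flatnonzero(np.diff(np.r_[0, on.astype(int), 0]))
        return [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]


@dataclass
class SpotImage:
    """A small photon-count raster with its offset in the global frame.

    ``offset_nm = (x, y)`` of the crop's top-left corner; may be negative
    for crops clipped at a frame border.
    """

    pixels: np.ndarray
    offset_nm: tuple[float, float] = (0.0, 0.0)
    pixel_size_nm: float = 160.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("SpotImage pixels must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def center_nm(self) -> tuple[float, float]:
        """Global nm coordinates of the geometric crop center."""
        h, w = self.pixels.shape
        return (
            self.offset_nm[0] + 0.5 * w * self.pixel_size_nm,
            self.offset_nm[1] + 0.5 * h * self.pixel_size_nm,
        )

    def copy(self) -> "SpotImage":
        return replace(self, pixels=self.pixels.copy())


def _axis_mass(coord_nm: float, sigma_nm: float, n_px: int, pixel_nm: float,
               origin_nm: float) -> np.ndarray:
    """Gaussian probability mass per pixel along one axis (analytic erf)."""
    edges = origin_nm + np.arange(n_px + 1) * pixel_nm
    z = (edges - coord_nm) / (np.sqrt(2.0) * sigma_nm)
    c = 0.5 * (1.0 + erf(z))
    return np.diff(c)


def render_psf(
    emitter_xy_nm,
    photons: float,
    psf: PsfModel,
    camera: CameraModel,
    shape_px: tuple[int, int] = (7, 7),
    offset_nm: tuple[float, float] = (0.0, 0.0),
) -> SpotImage:
    """Expected (noiseless) photon image of one emitter.

    The 2D Gaussian intensity profile is integrated analytically over each
    pixel's area (error-function integration, not center-point sampling),
    so the sum over an arbitrarily large crop converges to ``photons``.
    """
    if photons < 0:
        raise ValueError("photons must be >= 0")
    x, y = float(emitter_xy_nm[0]), float(emitter_xy_nm[1])
    h, w = int(shape_px[0]), int(shape_px[1])
    p = camera.pixel_size_nm
    mx = _axis_mass(x, psf.sx, w, p, offset_nm[0])
    my = _axis_mass(y, psf.sy, h, p, offset_nm[1])
    img = photons * np.outer(my, mx)
    return SpotImage(img, offset_nm=tuple(offset_nm), pixel_size_nm=p)


def add_camera_noise(image: SpotImage, camera: CameraModel, rng) -> SpotImage:
    """Poisson shot noise on signal + background, plus Gaussian read noise."""
    rng = _as_rng(rng)
    if np.any(image.pixels < 0):
        raise ValueError("expected image must be non-negative")
    lam = image.pixels + camera.background_photons_per_px
    out = rng.poisson(lam).astype(float)
    if camera.read_noise_e > 0:
        out += rng.normal(0.0, camera.read_noise_e, size=out.shape)
    return replace(image, pixels=out)


def sample_blink_trace(
    n_frames: int,
    kinetics: BlinkKinetics,
    photon_dist: PhotonDistribution,
    rng,
    molecule_id: int = 0,
    start_stationary: bool = True,
) -> BlinkTrace:
    """Simulate one molecule's on/off Markov chain and per-frame photons."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _as_rng(rng)
    u = rng.random(n_frames)
    state = np.empty(n_frames, dtype=bool)
    if start_stationary:
        prev = rng.random() < kinetics.stationary_on_fraction
    else:
        prev = False
    for t in range(n_frames):
        prev = (u[t] < kinetics.p_on) if not prev else (u[t] >= kinetics.p_off)
        state[t] = prev
    photons = np.zeros(n_frames)
    n_on = int(state.sum())
    if n_on:
        photons[state] = photon_dist.sample(rng, n_on)
    return BlinkTrace(molecule_id=molecule_id, photons=photons)


def build_synthetic_library(
    n_molecules: int,
    psf: PsfModel = PsfModel(),
    camera: CameraModel = CameraModel(),
    photon_dist: PhotonDistribution = PhotonDistribution(),
    rng=None,
    shape_px: tuple[int, int] = (7, 7),
    fit: bool = True,
    noise: bool = True,
):
    """Generate a noisy single-emitter spot library with known ground truth.

    Each record is a ``shape_px`` crop whose emitter lies uniformly within
    the crop's central pixel (mimicking detection-centered experimental
    crops), with photons drawn from ``photon_dist`` and camera noise applied.
    When ``fit`` is true each spot is immediately Gaussian-fitted so its
    fitted emitter position can serve as a merge anchor; ``noise=False``
    yields expectation images (useful as round-trip oracles).

    Returns a :class:`multispot.library.SpotLibrary`.
    """
    from .library import SpotLibrary, SpotRecord, fit_gaussian_2d

    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = _as_rng(rng)
    p = camera.pixel_size_nm
    h, w = shape_px
    cx, cy = (w // 2), (h // 2)  # central pixel indices
    records: list[SpotRecord] = []
    for mol in range(n_molecules):
        pos = (
            (cx + rng.random()) * p,
            (cy + rng.random()) * p,
        )
        nphot = float(photon_dist.sample(rng, 1)[0])
        clean = render_psf(pos, nphot, psf, camera, shape_px=shape_px)
        noisy = add_camera_noise(clean, camera, rng) if noise else clean
        gfit = fit_gaussian_2d(noisy) if fit else None
        records.append(
            SpotRecord(
                image=noisy,
                fit=gfit,
                photons=float(noisy.pixels.sum()),
                frame_index=0,
                molecule_id=mol,
                true_xy_nm=pos,
                true_photons=nphot,
            )
        )
    return SpotLibrary(records=records, camera=camera,
                       meta={"psf_sigma_nm": (psf.sx, psf.sy),
                             "photon_dist": photon_dist.family,
                             "n_molecules": n_molecules})
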