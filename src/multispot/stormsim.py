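"""STORM-imaging simulation of dense sub-diffraction ultrastructures.

Lays out molecules inside a 240 nm structure with a center-weighted radial
density, drives each molecule with a two-state blinking trace, renders every
frame of the sequence (PSF render + camera noise, or pasted library spots),
and keeps exact per-frame ground truth of which molecules were co-active.
Reconstruction compares three coordinate sources: ground truth, the
two-stage pipeline's predictions, and a plain single-Gaussian fit that —
by construction — treats every spot as a single molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import heatmap_from_spikes, render_spikes, ssim
from .io import LocalizationTable
from .library import DetectConfig, GaussianFitError, crop_spot, detect_spot_centers, fit_gaussian_2d
from .synthetic import (
    BlinkKinetics,
    CameraModel,
    PhotonDistribution,
    PsfModel,
    add_camera_noise,
    render_psf,
    sample_blink_trace,
    SpotImage,
    _as_rng,
)

__all__ = [
    "UltrastructureSpec",
    "SimulatedSequence",
    "layout_ultrastructure",
    "simulate_sequence",
    "gaussian_fit_baseline",
    "reconstruct_superres",
    "ssim_vs_density",
    "DEFAULT_DENSITIES",
]

log = logging.getLogger(__name__)

DEFAULT_DENSITIES = (50, 150, 250, 350, 450, 550)


@dataclass(frozen=True)
class UltrastructureSpec:
    """Geometry and occupancy of one simulated sub-diffraction structure.

    The radial density profile is a Gaussian with sigma = diameter/4
    (denser center than periphery), rejection-sampled inside the disk.
    """

    diameter_nm: float = 240.0
    n_molecules: int = 250
    center_nm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be > 0")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


def layout_ultrastructure(spec: UltrastructureSpec, rng=None) -> np.ndarray:
    """Molecule coordinates (n, 2) in nm, center-weighted inside the disk."""
    rng = _as_rng(rng)
    radius = spec.diameter_nm / 2.0
    sigma = spec.diameter_nm / 4.0
    pts = np.empty((spec.n_molecules, 2))
    filled = 0
    while filled < spec.n_molecules:
        cand = rng.normal(0.0, sigma, size=(2 * (spec.n_molecules - filled) + 8, 2))
        cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= radius]
        take = min(len(cand), spec.n_molecules - filled)
        pts[filled: filled + take] = cand[:take]
        filled += take
    return pts + np.asarray(spec.center_nm)


def _group_spots(coords: np.ndarray, linkage_nm: float = 240.0) -> list[np.ndarray]:
    """Single-linkage clustering of co-active molecules into apparent spots."""
    n = len(coords)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(coords[i] - coords[j])) <= linkage_nm:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.array(v) for v in groups.values()]


@dataclass
class SimulatedSequence:
    """Rendered frame stack plus exact per-frame ground truth."""

    frames: np.ndarray  # (n_frames, h, w)
    truth: pd.DataFrame  # frame, molecule, x_nm, y_nm, photons, spot
    layout_nm: np.ndarray  # (n_molecules, 2)
    camera: CameraModel
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def truth_table(self) -> LocalizationTable:
        df = self.truth.rename(columns={"molecule": "spot_molecule"})
        df = df.assign(source="ground_truth")
        return LocalizationTable(df[["frame", "x_nm", "y_nm", "photons", "source"]])


def simulate_sequence(
    layout_nm: np.ndarray,
    n_frames: int,
    camera: CameraModel = CameraModel(),
    psf: PsfModel = PsfModel(),
    photon_dist: PhotonDistribution = PhotonDistribution(),
    kinetics: BlinkKinetics = BlinkKinetics(),
    rng=None,
    frame_px: tuple[int, int] = (28, 28),
    library=None,
) -> SimulatedSequence:
    """Simulate a STORM acquisition of one molecule layout.

    Each molecule follows its own blinking trace; in frames where it is on
    it is rendered at its layout position (direct PSF render by default, or
    a translated library spot when ``library`` is given) and camera noise is
    applied to the whole frame. The ground-truth table records every
    emission event and the spot group (single-linkage at 240 nm) it belongs
    to, so every rendered spot decomposes exactly into its contributors.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _as_rng(rng)
    layout = np.atleast_2d(np.asarray(layout_nm, dtype=float))
    n_mol = len(layout)
    h, w = frame_px
    p = camera.pixel_size_nm
    # center the structure in the frame
    shift = np.array([w * p / 2.0, h * p / 2.0]) - layout.mean(axis=0)
    layout = layout + shift

    traces = [
        sample_blink_trace(n_frames, kinetics, photon_dist, rng, molecule_id=m)
        for m in range(n_mol)
    ]
    photon_matrix = np.stack([t.photons for t in traces], axis=1)  # (n_frames, n_mol)

    frames = np.empty((n_frames, h, w))
    rows = []
    for t in range(n_frames):
        active = np.flatnonzero(photon_matrix[t] > 0)
        clean = np.zeros((h, w))
        for m in active:
            if library is not None:
                from .datasets import translate_record

                rec = library.records[int(rng.integers(0, len(library)))]
                translate_record(rec, tuple(layout[m]), clean, p)
            else:
                clean += render_psf(layout[m], photon_matrix[t, m], psf, camera,
                                    shape_px=(h, w)).pixels
        noisy = add_camera_noise(SpotImage(clean, pixel_size_nm=p), camera, rng)
        frames[t] = noisy.pixels
        groups = _group_spots(layout[active])
        spot_of = {}
        for g_idx, grp in enumerate(groups):
            for k in grp:
                spot_of[int(active[k])] = g_idx
        for m in active:
            rows.append(
                {
                    "frame": t,
                    "molecule": int(m),
                    "x_nm": layout[m, 0],
                    "y_nm": layout[m, 1],
                    "photons": float(photon_matrix[t, m]),
                    "spot": spot_of[int(m)],
                }
            )
    truth = pd.DataFrame(rows, columns=["frame", "molecule", "x_nm", "y_nm", "photons", "spot"])
    return SimulatedSequence(
        frames=frames, truth=truth, layout_nm=layout, camera=camera,
        meta={"n_frames": n_frames, "kinetics": (kinetics.p_on, kinetics.p_off)},
    )


def gaussian_fit_baseline(
    seq: SimulatedSequence,
    detect_cfg: DetectConfig = DetectConfig(),
) -> LocalizationTable:
    """Classical single-molecule fitting: one localization per detected spot.

    Every spot — even one formed by co-active molecules — is fitted with a
    single Gaussian and treated as one molecule, so the number of rows is
    at most the number of true emission events, with equality only when no
    co-activations occur.
    """
    rows = []
    for idx, frame in enumerate(seq.frames):
        for r, c in detect_spot_centers(frame, detect_cfg):
            try:
                crop = crop_spot(frame, (r, c), 3, camera=seq.camera)
                fit = fit_gaussian_2d(crop)
            except GaussianFitError:
                continue
            rows.append(
                {
                    "frame": idx,
                    "x_nm": fit.x0_nm,
                    "y_nm": fit.y0_nm,
                    "photons": fit.amplitude_photons,
                    "source": "gaussian_fit",
                }
            )
    return LocalizationTable.from_rows(rows)


def reconstruct_superres(
    table: LocalizationTable,
    canvas_px: tuple[int, int] = (28, 28),
    pixel_size_nm: float = 160.0,
    upsampling: int = 8,
    kernel_sigma_px: float = 1.0,
    drop_outside: bool = True,
) -> np.ndarray:
    """Spike-render all localizations and convolve with a Gaussian kernel."""
    if len(table) == 0:
        h, w = canvas_px
        return np.zeros((h * upsampling, w * upsampling))
    coords = table.coords()
    if drop_outside:
        h, w = canvas_px
        ok = (
            (coords[:, 0] >= 0) & (coords[:, 0] < w * pixel_size_nm)
            & (coords[:, 1] >= 0) & (coords[:, 1] < h * pixel_size_nm)
        )
        dropped = int((~ok).sum())
        if dropped:
            log.info("dropping %d localizations outside the canvas", dropped)
        coords = coords[ok]
    spikes = render_spikes(coords, upsampling=upsampling, canvas_px=canvas_px,
                           pixel_size_nm=pixel_size_nm)
    return heatmap_from_spikes(spikes, kernel_sigma_px)


def ssim_vs_density(
    specs,
    bundle,
    n_frames: int = 2000,
    camera: CameraModel = CameraModel(),
    psf: PsfModel = PsfModel(),
    photon_dist: PhotonDistribution = PhotonDistribution(),
    kinetics: BlinkKinetics = BlinkKinetics(),
    rng=None,
    frame_px: tuple[int, int] = (28, 28),
) -> pd.DataFrame:
    """SSIM of pipeline vs Gaussian-fit reconstructions against ground truth.

    For each structure density, simulates a sequence, reconstructs
    super-resolution images from (a) ground-truth coordinates, (b) the
    two-stage pipeline's predictions, and (c) the single-Gaussian-fit
    baseline, and reports SSIM(a,b) and SSIM(a,c).
    """
    from .inference import process_stack

    rng = _as_rng(rng)
    rows = []
    for spec in specs:
        layout = layout_ultrastructure(spec, rng)
        seq = simulate_sequence(layout, n_frames, camera, psf, photon_dist,
                                kinetics, rng, frame_px=frame_px)
        gt_img = reconstruct_superres(seq.truth_table(), frame_px, camera.pixel_size_nm)
        pred = process_stack(seq.frames, bundle, camera)
        pred_img = reconstruct_superres(pred, frame_px, camera.pixel_size_nm)
        fit = gaussian_fit_baseline(seq)
        fit_img = reconstruct_superres(fit, frame_px, camera.pixel_size_nm)
        rows.append(
            {
                "n_molecules": spec.n_molecules,
                "ssim_pipeline": ssim(gt_img, pred_img),
                "ssim_gaussian_fit": ssim(gt_img, fit_img),
                "n_events": len(seq.truth),
                "n_pred": len(pred),
                "n_fit": len(fit),
            }
        )
    return pd.DataFrame(rows)
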