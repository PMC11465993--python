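"""Run configuration: nested, validated, profile-aware.

A single YAML file mirrors the module structure (camera, psf, photons,
blinking, dataset, training, detection, simulation). Unknown keys are
rejected. One global seed fans out to per-stage seeds by fixed offsets so
stages are reproducible yet use decorrelated streams.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict

from .synthetic import BlinkKinetics, CameraModel, PhotonDistribution, PsfModel
from .models import TrainConfig

__all__ = ["RunConfig", "stage_seed"]

# fixed per-stage offsets for fanning out the global seed
_STAGE_OFFSETS = {
    "library": 101,
    "dataset": 211,
    "train": 307,
    "eval": 401,
    "storm": 503,
    "batch_b": 601,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stays below 2**31)."""
    return (int(global_seed) * 1000 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CameraSection(_Section):
    pixel_size_nm: float = 160.0
    read_noise_e: float = 1.5
    background_photons_per_px: float = 10.0

    def build(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class PsfSection(_Section):
    sigma_nm: float = 102.0
    sigma_x_nm: float | None = None
    sigma_y_nm: float | None = None

    def build(self) -> PsfModel:
        return PsfModel(**self.model_dump())


class PhotonSection(_Section):
    # stand-in defaults: the experimental photon distribution and camera
    # noise are not published; these emulate a broad single-fluorophore
    # photon spread and are fully configurable
    family: str = "lognormal"
    median: float = 5000.0
    geometric_sd: float = 1.8
    lo: float = 500.0
    hi: float = 50000.0

    def build(self) -> PhotonDistribution:
        return PhotonDistribution(**self.model_dump())


class BlinkSection(_Section):
    p_on: float = 1e-3
    p_off: float = 0.5

    def build(self) -> BlinkKinetics:
        return BlinkKinetics(**self.model_dump())


class DatasetSection(_Section):
    n_per_class: int = 10000
    classes: list[int] = [1, 2]
    diameter_nm: float = 240.0
    test_fraction: float = 0.1
    method: str = "fourier"
    n_molecules: int = 3000


class TrainSection(_Section):
    backbone: str = "compact"
    hidden: int = 256
    n_blocks: int = 2
    epochs: int = 60
    batch_size: int = 64
    lr_initial: float = 1e-3
    lr_final: float = 1e-5
    weight_decay: float = 1e-4
    loss_variant: str = "canonical-mse"

    def build(self, seed: int = 0, paper_scale: bool = False) -> TrainConfig:
        return TrainConfig(**self.model_dump(), seed=seed, paper_scale=paper_scale)


class StormSection(_Section):
    n_frames: int = 2000
    frame_px: int = 28
    densities: list[int] = [50, 150, 250, 350, 450, 550]


class RunConfig(_Section):
    """Top-level configuration with desk / paper-scale profiles."""

    seed: int = 0
    profile: str = "desk"
    camera: CameraSection = CameraSection()
    psf: PsfSection = PsfSection()
    photons: PhotonSection = PhotonSection()
    blinking: BlinkSection = BlinkSection()
    dataset: DatasetSection = DatasetSection()
    training: TrainSection = TrainSection()
    storm: StormSection = StormSection()

    def model_post_init(self, _ctx) -> None:
        if self.profile not in ("desk", "paper-scale"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "paper-scale":
            # full-size recipe: 280k training spots, 400 epochs, 8000 frames
            self.dataset.n_per_class = 150000
            self.training.epochs = 400
            self.training.lr_initial, self.training.lr_final = 1e-5, 1e-8
            self.training.weight_decay = 0.01
            self.storm.n_frames = 8000

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        from .io import load_yaml

        data = load_yaml(path)
        data.update(overrides)
        return cls(**data)
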