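"""Two-channel fluorescence phantom of a sensor-expressing astrocyte.

The scene is a voxel occupancy map: the soma is fully occupied (occupancy
1.0, i.e. a volume fraction of 100%), while the surrounding neuropil shell
holds fine processes whose per-voxel occupancy is strictly below 1.  During
swelling, process occupancy scales linearly with relative cell volume v(t)
(clipped at full occupancy); the soma stays saturated.  If fluorophore
dilution is enabled, intracellular sensor concentration scales as 1/v(t),
so the expected donor intensity of a process voxel is

    base_intensity · clip(occ₀ · v(t), 1) · 1/v(t)

and of a soma voxel ``base_intensity / v(t)``.  The acceptor channel is the
donor expectation times the FRET ratio.  This reproduces the central
ratiometric identity: process/soma donor fluorescence equals the occupancy-
weighted volume fraction, with concentration cancelling.

Photon (counting) noise is approximated by a signal-dependent Gaussian
above 20 expected photons and exact Poisson draws below; a constant
Gaussian read noise and a constant sub-voxel drift velocity (rounded to
integer voxel shifts per frame) are optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from ..datatypes import ImagingSeries, ROISet

__all__ = [
    "SceneConfig",
    "PhantomScene",
    "OpticsNoiseParams",
    "GroundTruth",
    "build_astrocyte_phantom",
    "render_timeseries",
]

_POISSON_GAUSSIAN_CROSSOVER = 20.0  # expected photons


@dataclass
class SceneConfig:
    """Geometry of the synthetic astrocyte scene.

    The voxel calibration matches a 512-px / 132.96-μm time-series field
    (0.26 μm/px) with 2-μm z-steps; the field itself is cropped to a small
    volume around one cell.
    """

    shape: tuple[int, int, int] = (12, 64, 64)  # (z, y, x) voxels
    pixel_size: float = 132.96 / 512  # μm / px
    z_step: float = 2.0  # μm
    soma_radius: float = 3.0  # μm
    process_inner_radius: float = 3.5  # μm
    process_outer_radius: float = 7.5  # μm
    process_occupancy_mean: float = 0.25
    process_occupancy_conc: float = 10.0  # Beta concentration (a+b)

    def validate(self) -> None:
        half_y = self.shape[1] * self.pixel_size / 2.0
        half_x = self.shape[2] * self.pixel_size / 2.0
        half_z = self.shape[0] * self.z_step / 2.0
        if self.soma_radius >= min(half_y, half_x, half_z):
            raise ValueError("soma radius exceeds the field of view")
        if self.process_outer_radius > min(half_y, half_x, half_z):
            raise ValueError("process shell exceeds the field of view")
        if not self.soma_radius < self.process_inner_radius < self.process_outer_radius:
            raise ValueError("need soma_radius < inner < outer shell radius")
        if not 0.0 < self.process_occupancy_mean < 1.0:
            raise ValueError("process occupancy mean must lie in (0, 1)")


@dataclass
class PhantomScene:
    """Static occupancy map plus designated soma and process ROIs."""

    occupancy: np.ndarray  # (z, y, x) in [0, 1]
    soma_mask: np.ndarray
    process_mask: np.ndarray
    soma_center: tuple[int, int, int]
    config: SceneConfig

    @property
    def rois(self) -> ROISet:
        return ROISet(soma_mask=self.soma_mask, process_mask=self.process_mask)


@dataclass
class OpticsNoiseParams:
    """Emission and noise model settings."""

    base_intensity: float = 200.0  # expected photons, fully occupied voxel
    dilution_coupling: bool = True  # sensor concentration ∝ 1/v(t)
    photon_noise: bool = True
    read_noise_sd: float = 1.0  # intensity units; 0 disables
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)  # voxels (z,y,x)

    def validate(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError("base_intensity must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Generator-side truth serialized alongside each rendered series."""

    v_series: np.ndarray
    cl_series: np.ndarray
    ratio_series: np.ndarray
    vf_truth: np.ndarray  # true process-ROI mean occupancy per frame
    occupancy0_mean: float  # resting process-ROI mean occupancy
    shifts: np.ndarray  # (t, 3) applied integer voxel shifts
    rvd_nominal: float | None
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None


def build_astrocyte_phantom(
    config: SceneConfig | None = None, seed: int | None = 0
) -> PhantomScene:
    """Build the static occupancy scene; deterministic given ``seed``.

    Soma voxels (within ``soma_radius`` of the center) have occupancy
    exactly 1.0.  Shell voxels draw occupancy from a Beta distribution with
    the configured mean (support strictly inside (0, 1)).
    """
    config = config or SceneConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    nz, ny, nx = config.shape
    center = (nz // 2, ny // 2, nx // 2)
    zz, yy, xx = np.meshgrid(
        (np.arange(nz) - center[0]) * config.z_step,
        (np.arange(ny) - center[1]) * config.pixel_size,
        (np.arange(nx) - center[2]) * config.pixel_size,
        indexing="ij",
    )
    dist = np.sqrt(zz**2 + yy**2 + xx**2)
    soma = dist <= config.soma_radius
    shell = (dist > config.process_inner_radius) & (
        dist <= config.process_outer_radius
    )
    a = config.process_occupancy_mean * config.process_occupancy_conc
    b = (1.0 - config.process_occupancy_mean) * config.process_occupancy_conc
    occupancy = np.zeros(config.shape, dtype=float)
    occupancy[soma] = 1.0
    occupancy[shell] = rng.beta(a, b, size=int(shell.sum()))
    return PhantomScene(
        occupancy=occupancy,
        soma_mask=soma,
        process_mask=shell,
        soma_center=center,
        config=config,
    )


def _apply_noise(
    expected: np.ndarray, optics: OpticsNoiseParams, rng: np.random.Generator
) -> np.ndarray:
    out = expected
    if optics.photon_noise:
        out = np.array(expected, dtype=float)
        low = expected < _POISSON_GAUSSIAN_CROSSOVER
        out[low] = rng.poisson(expected[low])
        high = ~low
        out[high] = rng.normal(expected[high], np.sqrt(expected[high]))
    if optics.read_noise_sd > 0:
        out = out + rng.normal(0.0, optics.read_noise_sd, size=expected.shape)
    return np.clip(out, 0.0, None)


def render_timeseries(
    scene: PhantomScene,
    v_series: np.ndarray,
    ratio_series: np.ndarray,
    optics: OpticsNoiseParams | None = None,
    seed: int | None = 0,
    frame_interval: float = 120.0,
    stimulus_onset_frame: int = 5,
    cl_series: np.ndarray | None = None,
    rvd_nominal: float | None = None,
) -> tuple[ImagingSeries, GroundTruth]:
    """Render a two-channel (donor, acceptor) image series from ground truth.

    Returns the series together with a :class:`GroundTruth` record holding
    the exact per-frame process-ROI occupancy mean (the oracle for the
    downstream volume-fraction estimator) and the applied drift shifts.
    """
    optics = optics or OpticsNoiseParams()
    optics.validate()
    v = np.asarray(v_series, dtype=float)
    ratio = np.asarray(ratio_series, dtype=float)
    if v.shape != ratio.shape:
        raise ValueError("v_series and ratio_series lengths must match")
    if np.any(v <= 0) or np.any(ratio <= 0):
        raise ValueError("volume and ratio series must be positive")
    rng = np.random.default_rng(seed)
    n_frames = v.size
    occ0 = scene.occupancy
    soma, shell = scene.soma_mask, scene.process_mask

    drift = np.asarray(optics.drift_per_frame, dtype=float)
    shifts = np.rint(drift[None, :] * np.arange(n_frames)[:, None]).astype(int)

    data = np.empty((n_frames, *occ0.shape, 2), dtype=float)
    vf_truth = np.empty(n_frames)
    for ti in range(n_frames):
        occ_t = np.where(soma, 1.0, np.clip(occ0 * v[ti], 0.0, 1.0))
        vf_truth[ti] = occ_t[shell].mean()
        conc = 1.0 / v[ti] if optics.dilution_coupling else 1.0
        cer = optics.base_intensity * occ_t * conc
        yfp = cer * ratio[ti]
        if np.any(shifts[ti]):
            cer = np.roll(cer, shifts[ti], axis=(0, 1, 2))
            yfp = np.roll(yfp, shifts[ti], axis=(0, 1, 2))
        data[ti, ..., 0] = _apply_noise(cer, optics, rng)
        data[ti, ..., 1] = _apply_noise(yfp, optics, rng)

    series = ImagingSeries(
        data=data,
        pixel_size=scene.config.pixel_size,
        z_step=scene.config.z_step,
        frame_interval=frame_interval,
        channel_roles={"cerulean": 0, "yfp": 1},
        stimulus_onset_frame=min(stimulus_onset_frame, n_frames - 1),
    )
    truth = GroundTruth(
        v_series=v.copy(),
        cl_series=None if cl_series is None else np.asarray(cl_series, float),
        ratio_series=ratio.copy(),
        vf_truth=vf_truth,
        occupancy0_mean=float(occ0[shell].mean()),
        shifts=shifts,
        rvd_nominal=rvd_nominal,
        params={"optics": asdict(optics), "scene": asdict(scene.config)},
        seed=seed,
    )
    return series, truth
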