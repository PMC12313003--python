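"""Core containers shared by the imaging and electrophysiology pipelines.

Conventions
-----------
* Image data are 5-D float arrays ordered ``(t, z, y, x, channel)``.
* Frame indices are 0-based; times derive from ``frame_interval`` (s).
* Currents are in pA, voltages in mV, resistances in MΩ.
* ROI masks are boolean voxel-inclusive arrays over ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ImagingSeries",
    "ROISet",
    "VFTrace",
    "FretTrace",
    "Sweep",
    "SweepSet",
    "IVCurve",
    "ExpFit",
]


@dataclass
class ImagingSeries:
    """Two-channel fluorescence z-stack time series with calibration.

    ``channel_roles`` maps the donor ("cerulean", chloride-insensitive) and
    acceptor ("yfp", chloride-sensitive) fluorophores of the FRET chloride
    sensor to channel indices of ``data``.
    """

    data: np.ndarray  # (t, z, y, x, c), float, >= 0
    pixel_size: float  # μm / pixel (x and y)
    z_step: float  # μm
    frame_interval: float  # s
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"cerulean": 0, "yfp": 1}
    )
    stimulus_onset_frame: int = 5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("data must be 5-D (t, z, y, x, channel)")
        if not 0 <= self.stimulus_onset_frame < self.n_frames:
            raise ValueError("stimulus_onset_frame outside the series")
        for role in ("cerulean", "yfp"):
            if role not in self.channel_roles:
                raise ValueError(f"channel_roles must assign {role!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:4]

    def channel(self, role: str) -> np.ndarray:
        """Return the (t, z, y, x) stack for a channel role."""
        return self.data[..., self.channel_roles[role]]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ROISet:
    """Soma and process regions of interest as boolean (z, y, x) masks."""

    soma_mask: np.ndarray
    process_mask: np.ndarray

    def __post_init__(self) -> None:
        self.soma_mask = np.asarray(self.soma_mask, dtype=bool)
        self.process_mask = np.asarray(self.process_mask, dtype=bool)
        if self.soma_mask.shape != self.process_mask.shape:
            raise ValueError("ROI masks must share one volume shape")
        if not self.soma_mask.any() or not self.process_mask.any():
            raise ValueError("ROIs must be non-empty")
        if (self.soma_mask & self.process_mask).any():
            raise ValueError("soma and process ROIs must not overlap")


@dataclass
class VFTrace:
    """Per-cell volume-fraction time series with QC flags.

    ``raw_vf`` is F_process / F_soma on the donor channel; ``normalized_vf``
    divides by the mean over the baseline frames.  ``rvd_percent`` is only
    set when both QC flags pass.
    """

    raw_vf: np.ndarray
    normalized_vf: np.ndarray
    baseline_frames: int
    peak_change: float
    end_change: float | None
    qc_baseline_stable: bool
    qc_min_swelling: bool
    baseline_deviation: float
    rvd_percent: float | None

    @property
    def qc_pass(self) -> bool:
        return self.qc_baseline_stable and self.qc_min_swelling


@dataclass
class FretTrace:
    """Per-cell soma FRET-ratio (acceptor/donor) time series."""

    raw_ratio: np.ndarray
    normalized_ratio: np.ndarray
    baseline_frames: int
    peak_ratio_change_percent: float


@dataclass
class Sweep:
    """One patch-clamp sweep (uniformly sampled current or voltage)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    protocol_tag: str  # e.g. "iv_step", "stc_single", "stc_train9", "vm_monitor"
    kind: str = "current"  # "current" (pA) or "voltage" (mV)
    repeat_index: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class SweepSet:
    """A collection of sweeps acquired under one protocol."""

    sweeps: list[Sweep]
    protocol: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sweeps)

    def __len__(self) -> int:
        return len(self.sweeps)

    def select(self, protocol_tag: str) -> list[Sweep]:
        return [s for s in self.sweeps if s.protocol_tag == protocol_tag]


@dataclass
class IVCurve:
    """Steady-state current–voltage relationship from a step protocol."""

    step_voltages: np.ndarray  # mV, strictly increasing
    steady_state_currents: np.ndarray  # pA
    steady_window: tuple[float, float]  # s, relative to sweep start

    def __post_init__(self) -> None:
        self.step_voltages = np.asarray(self.step_voltages, dtype=float)
        self.steady_state_currents = np.asarray(
            self.steady_state_currents, dtype=float
        )
        if self.step_voltages.size != self.steady_state_currents.size:
            raise ValueError("one current per voltage required")
        if np.any(np.diff(self.step_voltages) <= 0):
            raise ValueError("step voltages must be strictly increasing")


@dataclass
class ExpFit:
    """Mono-exponential fit result: I(t) = A·exp(−(t−t0)/τ) + C."""

    amplitude: float  # A, trace units
    tau: float  # s
    offset: float  # C, trace units
    window: tuple[float, float]  # s, absolute trace time
    r_squared: float
    identifiable: bool = True

    @property
    def tau_ms(self) -> float:
        return self.tau * 1e3
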