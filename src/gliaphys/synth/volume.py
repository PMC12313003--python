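"""Ground-truth volume and chloride dynamics for synthetic astrocytes.

The stimulus paradigm mirrors a mild potassium challenge in an acute slice:
after a baseline in standard aCSF, raising bath [K⁺] from 3 to 6 mM drives
water influx and swelling of the fine processes; active regulatory volume
decrease (RVD) then relaxes the cell back toward (or past) its resting
volume.  Relative cell volume v(t) is 1.0 at rest, rises exponentially
toward 1 + peak_change after stimulus onset, and relaxes exponentially
toward 1 + end_change.

Intracellular chloride follows mass balance: dilution by the volume change
plus an optional phenomenological cumulative efflux (the electroneutral
osmolyte loss that drives RVD),

    cl(t) = cl_baseline · (1 − cumulative_efflux(t)) / v(t).

The FRET chloride sensor is modeled as a single-site binding curve with
half-saturation ``kd``; chloride binding quenches the acceptor, so the
acceptor/donor ratio falls as [Cl⁻] rises:

    ratio(t) = ratio_min + (ratio_max − ratio_min) · kd / (kd + cl(t)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VolumeDynamicsParams",
    "ChlorideDynamicsParams",
    "simulate_volume_timecourse",
    "simulate_chloride_timecourse",
    "ground_truth_rvd",
]


@dataclass
class VolumeDynamicsParams:
    """Parameters of the relative-volume time course v(t).

    Defaults describe the wild-type-like condition: 5 baseline frames at a
    2-min interval, ~34% peak swelling roughly 10 min after the potassium
    switch, and recovery with a small undershoot below baseline.
    """

    n_frames: int = 25
    baseline_frames: int = 5
    frame_interval: float = 120.0  # s
    onset_frame: int = 5
    peak_change: float = 0.340  # relative VF change at peak
    end_change: float = -0.070  # relative change at recording end (<0 = undershoot)
    tau_swell: float = 120.0  # s
    tau_recovery: float = 240.0  # s; np.inf disables recovery
    rise_duration: float | None = None  # s; default 5·tau_swell
    baseline_drift: float = 0.0  # total fractional drift across the baseline

    def validate(self) -> None:
        if self.tau_swell <= 0 or self.tau_recovery <= 0:
            raise ValueError("time constants must be positive")
        if self.onset_frame < self.baseline_frames:
            raise ValueError("stimulus onset must not precede the baseline end")
        if self.onset_frame >= self.n_frames:
            raise ValueError("onset_frame outside the recording")
        if self.baseline_frames < 2:
            raise ValueError("need at least 2 baseline frames")


@dataclass
class ChlorideDynamicsParams:
    """Chloride mass balance and FRET-sensor parameters.

    The sensor constants are free parameters (no published calibration is
    assumed); defaults are a physiologically plausible astrocyte resting
    chloride of 30 mM and a half-saturation of 8.1 mM.
    """

    cl_baseline: float = 30.0  # mM
    efflux_fraction: float = 0.30  # fraction of resting Cl⁻ content extruded
    tau_efflux: float = 240.0  # s; efflux develops during the recovery phase
    kd: float = 8.1  # mM
    ratio_min: float = 0.6
    ratio_max: float = 1.8

    def validate(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if not 0.0 <= self.efflux_fraction <= 1.0:
            raise ValueError("efflux_fraction must lie in [0, 1]")
        if self.cl_baseline <= 0:
            raise ValueError("cl_baseline must be positive")
        if self.ratio_max <= self.ratio_min:
            raise ValueError("ratio_max must exceed ratio_min")
        if self.tau_efflux <= 0:
            raise ValueError("tau_efflux must be positive")


def simulate_volume_timecourse(params: VolumeDynamicsParams) -> np.ndarray:
    """Return the relative-volume series v(t) at the imaging frame times.

    Baseline frames are exactly 1.0 (plus any configured baseline drift,
    which is mean-centered so the baseline average stays 1.0).  The rise
    phase lasts ``rise_duration`` (default 5·tau_swell, so the achieved
    maximum is within 1% of ``1 + peak_change``), after which the curve
    relaxes toward ``1 + end_change`` with ``tau_recovery``.
    """
    params.validate()
    t = np.arange(params.n_frames) * params.frame_interval
    t_on = params.onset_frame * params.frame_interval
    rise = (
        5.0 * params.tau_swell
        if params.rise_duration is None
        else float(params.rise_duration)
    )
    if rise <= 0:
        raise ValueError("rise_duration must be positive")
    t_peak = t_on + rise

    v = np.ones(params.n_frames, dtype=float)
    if params.baseline_drift != 0.0:
        nb = params.baseline_frames
        ramp = (np.arange(nb) - (nb - 1) / 2.0) / nb
        v[:nb] += params.baseline_drift * ramp

    rising = (t >= t_on) & (t < t_peak)
    v[rising] = 1.0 + params.peak_change * (
        1.0 - np.exp(-(t[rising] - t_on) / params.tau_swell)
    )
    v_peak = 1.0 + params.peak_change * (1.0 - np.exp(-rise / params.tau_swell))
    relaxing = t >= t_peak
    target = 1.0 + params.end_change
    with np.errstate(over="ignore"):
        decay = np.exp(-(t[relaxing] - t_peak) / params.tau_recovery)
    v[relaxing] = target + (v_peak - target) * decay
    if np.any(v <= 0):
        raise ValueError("volume time course reached non-positive values")
    return v


def simulate_chloride_timecourse(
    v_series: np.ndarray,
    params: ChlorideDynamicsParams,
    frame_interval: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ([Cl⁻]ᵢ series in mM, FRET-ratio series) matching ``v_series``.

    Cumulative efflux starts at the volume peak (the onset of regulatory
    volume decrease) and saturates at ``efflux_fraction`` with time constant
    ``tau_efflux``.  With ``efflux_fraction = 0`` chloride content
    cl(t)·v(t) is conserved exactly (pure dilution).
    """
    params.validate()
    v = np.asarray(v_series, dtype=float)
    if np.any(v <= 0):
        raise ValueError("v_series must be strictly positive")
    t = np.arange(v.size) * frame_interval
    t_peak = t[int(np.argmax(v))]
    cum_efflux = np.where(
        t >= t_peak,
        params.efflux_fraction * (1.0 - np.exp(-(t - t_peak) / params.tau_efflux)),
        0.0,
    )
    cl = params.cl_baseline * (1.0 - cum_efflux) / v
    ratio = params.ratio_min + (params.ratio_max - params.ratio_min) * params.kd / (
        params.kd + cl
    )
    return cl, ratio


def ground_truth_rvd(params: VolumeDynamicsParams) -> float:
    """Nominal RVD (%) implied by the generator parameters,
    (peak change − end change) / peak change × 100."""
    if params.peak_change <= 0:
        raise ValueError("peak_change must be positive for an RVD")
    return (params.peak_change - params.end_change) / params.peak_change * 100.0
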