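"""Synthetic passive-astrocyte patch-clamp sweeps with known ground truth.

Astrocytes are modeled as passive (ohmic) cells: steady-state current under
a voltage step V is (V − v_rest)/(R_M + R_pip).  Synaptically evoked
currents superimpose, per stimulus pulse, a fast synaptically activated
transporter current (STC; instantaneous rise, mono-exponential decay) and a
slow potassium "bioelectrode" current tracking extracellular K⁺.  Pulse
trains saturate glutamate uptake: per-pulse STC amplitude and decay time
are scaled by configurable schedules.  The slow K⁺ component is contributed
by pulses 1–9 only (extracellular K⁺ accumulation saturates within the
train), so 9- and 10-pulse trains share an identical slow component and
their difference isolates the 10th-pulse STC exactly.

The syncytial-isopotentiality assay replaces pipette K⁺ with Na⁺: the
membrane potential relaxes from v_rest toward a steady value set by the
divider between the gap-junctional conductance to the (hyperpolarized)
syncytium and the dialyzed cell's own (0 mV-reversing) conductance,

    V_∞ = v_rest · coupling_strength / (1 + coupling_strength),

so an uncoupled cell (coupling 0, the gap-junction-blocker limit)
depolarizes fully toward 0 mV.

Stimulus artifacts and capacitive spikes are omitted by default (a flag
adds a capacitive transient to IV steps); analyses start after them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import Sweep, SweepSet

__all__ = [
    "EphysGroundTruth",
    "simulate_iv_sweeps",
    "simulate_stc_sweeps",
    "simulate_na_dialysis_vm",
    "coupling_for_depolarization",
]


def _linear_schedule(last: float, n: int = 10) -> tuple[float, ...]:
    return tuple(np.linspace(1.0, last, n))


@dataclass
class EphysGroundTruth:
    """Generator parameters for one synthetic astrocyte recording."""

    r_membrane: float = 25.0  # MΩ
    r_pipette: float = 5.0  # MΩ
    v_rest: float = -80.0  # mV
    stc_tau: float = 7.353e-3  # s (single-pulse STC decay)
    stc_amplitude: float = -120.0  # pA (inward)
    k_tau: float = 1.856  # s (slow K⁺ current decay)
    k_increment: float = -6.0  # pA added per pulse (pulses 1–9)
    amp_scale: tuple[float, ...] = field(default_factory=lambda: _linear_schedule(0.75))
    tau_scale: tuple[float, ...] = field(
        default_factory=lambda: _linear_schedule(12.12 / 7.353)
    )
    coupling_strength: float = 11.6  # dimensionless; 0 = uncoupled (MFA-like)
    dialysis_tau: float = 100.0  # s
    noise_sd: float = 4.0  # pA additive current noise
    vm_noise_sd: float = 0.3  # mV additive voltage noise
    sampling_rate: float = 10_000.0  # Hz

    def validate(self) -> None:
        if self.r_membrane <= 0 or self.r_pipette < 0:
            raise ValueError("resistances must be positive (pipette ≥ 0)")
        if self.stc_tau <= 0 or self.k_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.stc_tau >= self.k_tau:
            raise ValueError("stc_tau must be much smaller than k_tau")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def simulate_iv_sweeps(
    gt: EphysGroundTruth,
    step_min: float = -120.0,
    step_max: float = 30.0,
    step_size: float = 10.0,
    step_duration: float = 1.0,
    pre_duration: float = 0.2,
    holding: float = -80.0,
    capacitive: bool = False,
    noise: bool = False,
    seed: int | None = 0,
) -> SweepSet:
    """Voltage-step protocol (−120..+30 mV in 10-mV steps by default).

    Each sweep holds at ``holding`` for ``pre_duration`` then steps to the
    test potential for ``step_duration``; currents are ohmic through
    R_M + R_pip.  ``capacitive=True`` adds a fast charging transient at the
    step onset.
    """
    gt.validate()
    if step_size <= 0 or step_max < step_min:
        raise ValueError("malformed step protocol")
    r_total = gt.r_membrane + gt.r_pipette
    if r_total <= 0:
        raise ValueError("total resistance must be positive")
    rng = np.random.default_rng(seed)
    fs = gt.sampling_rate
    n_pre = int(round(pre_duration * fs))
    n_step = int(round(step_duration * fs))
    t_step = np.arange(n_step) / fs
    voltages = np.arange(step_min, step_max + step_size / 2, step_size)
    sweeps = []
    for v_cmd in voltages:
        i_hold = (holding - gt.v_rest) / r_total * 1e3  # pA
        i_step = (v_cmd - gt.v_rest) / r_total * 1e3
        trace = np.concatenate(
            [np.full(n_pre, i_hold), np.full(n_step, i_step)]
        )
        if capacitive:
            tau_c = 2e-3  # s, access charging
            amp_c = (v_cmd - holding) / max(gt.r_pipette, 1e-3) * 1e3
            trace[n_pre:] += amp_c * np.exp(-t_step / tau_c)
        if noise and gt.noise_sd > 0:
            trace = trace + rng.normal(0.0, gt.noise_sd, trace.size)
        sweeps.append(
            Sweep(
                samples=trace,
                sampling_rate=fs,
                protocol_tag="iv_step",
                kind="current",
                meta={
                    "step_voltage": float(v_cmd),
                    "step_start": pre_duration,
                    "step_duration": step_duration,
                    "holding": holding,
                },
            )
        )
    return SweepSet(sweeps=sweeps, protocol="iv", meta={"v_rest": gt.v_rest})


def _stc_trace(
    gt: EphysGroundTruth,
    n_pulses: int,
    t: np.ndarray,
    stim_time: float,
    pulse_interval: float,
    include_k: bool,
) -> np.ndarray:
    """Noise-free evoked current: sum of per-pulse fast and slow components."""
    trace = np.zeros_like(t)
    for k in range(n_pulses):
        t_k = stim_time + k * pulse_interval
        after = t >= t_k
        amp = gt.stc_amplitude * gt.amp_scale[k]
        tau = gt.stc_tau * gt.tau_scale[k]
        trace[after] += amp * np.exp(-(t[after] - t_k) / tau)
        if include_k and k < 9:
            trace[after] += gt.k_increment * np.exp(-(t[after] - t_k) / gt.k_tau)
    return trace


def simulate_stc_sweeps(
    gt: EphysGroundTruth,
    n_pulses: int = 1,
    repeats: int = 5,
    seed: int | None = 0,
    stim_time: float = 0.1,
    pulse_rate: float = 100.0,
    duration: float | None = None,
    noise: bool = True,
    include_k: bool = True,
) -> SweepSet:
    """Evoked-current sweeps: single pulses or 100-Hz trains (n ∈ {1, 9, 10}).

    Traces are holding-current-subtracted (baseline 0).  Each repeat gets
    independent additive Gaussian noise from ``seed``.
    """
    gt.validate()
    if n_pulses not in (1, 9, 10):
        raise ValueError("n_pulses must be 1, 9 or 10")
    pulse_interval = 1.0 / pulse_rate
    if pulse_interval < 1.0 / gt.sampling_rate:
        raise ValueError("pulse spacing shorter than the sample interval")
    if duration is None:
        train_end = stim_time + (n_pulses - 1) * pulse_interval
        duration = train_end + (0.7 if n_pulses == 1 else 10.7)
    fs = gt.sampling_rate
    t = np.arange(int(round(duration * fs))) / fs
    clean = _stc_trace(gt, n_pulses, t, stim_time, pulse_interval, include_k)
    rng = np.random.default_rng(seed)
    tag = "stc_single" if n_pulses == 1 else f"stc_train{n_pulses}"
    meta = {
        "stim_time": stim_time,
        "n_pulses": n_pulses,
        "pulse_interval": pulse_interval,
        "train_end": stim_time + (n_pulses - 1) * pulse_interval,
    }
    sweeps = []
    for rep in range(repeats):
        trace = clean
        if noise and gt.noise_sd > 0:
            trace = clean + rng.normal(0.0, gt.noise_sd, clean.size)
        sweeps.append(
            Sweep(
                samples=trace.copy(),
                sampling_rate=fs,
                protocol_tag=tag,
                kind="current",
                repeat_index=rep,
                meta=dict(meta),
            )
        )
    return SweepSet(sweeps=sweeps, protocol=tag, meta=dict(meta))


def tenth_pulse_fast_component(
    gt: EphysGroundTruth, t: np.ndarray, stim_time: float = 0.1,
    pulse_rate: float = 100.0,
) -> np.ndarray:
    """Analytic 10th-pulse fast STC (the superposition-oracle reference)."""
    t_k = stim_time + 9 / pulse_rate
    amp = gt.stc_amplitude * gt.amp_scale[9]
    tau = gt.stc_tau * gt.tau_scale[9]
    out = np.zeros_like(t)
    after = t >= t_k
    out[after] = amp * np.exp(-(t[after] - t_k) / tau)
    return out


def simulate_na_dialysis_vm(
    gt: EphysGroundTruth,
    duration: float = 600.0,
    sampling_rate: float = 10.0,
    noise: bool = True,
    seed: int | None = 0,
) -> Sweep:
    """Membrane potential during intracellular Na⁺ dialysis.

    V_M relaxes from v_rest toward V_∞ = v_rest·c/(1+c); c = 0 reproduces
    the uncoupled (gap-junction-blocked) limit of full depolarization.
    """
    gt.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    c = gt.coupling_strength
    v_inf = gt.v_rest if np.isinf(c) else gt.v_rest * c / (1.0 + c)
    vm = v_inf + (gt.v_rest - v_inf) * np.exp(-t / gt.dialysis_tau)
    if noise and gt.vm_noise_sd > 0:
        rng = np.random.default_rng(seed)
        vm = vm + rng.normal(0.0, gt.vm_noise_sd, vm.size)
    return Sweep(
        samples=vm,
        sampling_rate=sampling_rate,
        protocol_tag="vm_monitor",
        kind="voltage",
        meta={"duration": duration, "coupling_strength": c},
    )


def coupling_for_depolarization(
    target_dvm: float,
    v_rest: float = -80.0,
    duration: float = 600.0,
    dialysis_tau: float = 100.0,
    initial_window: float = 10.0,
    measure_window: float = 30.0,
) -> float:
    """Invert the dialysis model: coupling strength giving a target
    depolarization ΔV_M (mV, positive) measured at ``duration``.

    Matches the analysis-side measurement (mean over an initial window vs
    mean over a window ending at ``duration``), so the recovered ΔV_M
    equals the target up to noise.
    """
    if target_dvm <= 0:
        raise ValueError("target depolarization must be positive")

    def window_mean_exp(t0: float, t1: float) -> float:
        # mean of exp(−t/τ) over [t0, t1]
        return (
            dialysis_tau
            / (t1 - t0)
            * (np.exp(-t0 / dialysis_tau) - np.exp(-t1 / dialysis_tau))
        )

    factor = window_mean_exp(0.0, initial_window) - window_mean_exp(
        duration - measure_window, duration
    )
    dv_inf = target_dvm / factor
    c = -v_rest / dv_inf - 1.0
    if c < 0:
        raise ValueError("target exceeds the fully uncoupled depolarization")
    return float(c)
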