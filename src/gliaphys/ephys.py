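"""Patch-clamp sweep analysis for passive astrocytes.

Covers the passive-membrane workup (steady-state I–V, membrane resistance
with pipette-resistance subtraction, resting potential), glutamate
transporter current (STC) kinetics via repeat averaging, 10-minus-9-pulse
train subtraction and mono-exponential decay fitting, the slow K⁺ current
decay after high-frequency stimulation, and the Na⁺-dialysis depolarization
used to probe syncytial isopotentiality.

Fits use damped least squares (Levenberg–Marquardt) from a log-linear
initial guess on offset-subtracted data.  Units: currents pA, voltages mV,
STC τ reported in ms, K⁺ τ in s.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats

from .datatypes import Sweep, SweepSet, IVCurve, ExpFit

__all__ = [
    "steady_state_iv",
    "membrane_resistance",
    "resting_potential",
    "average_repeats",
    "isolate_10th_pulse_stc",
    "fit_monoexponential_decay",
    "stc_decay_time",
    "k_current_decay_time",
    "saturation_ratio",
    "dialysis_depolarization",
]

TAU_BOUNDS = (1e-4, 60.0)  # s, plausibility bounds for fitted decays
BASELINE_WINDOW = 0.05  # s before the first stimulus


def steady_state_iv(sweeps: SweepSet | list[Sweep], window_fraction: float = 0.1) -> IVCurve:
    """Steady-state I–V from a voltage-step protocol.

    Per step the current is averaged over the final ``window_fraction`` of
    the step.  A warning flags a visibly nonlinear I–V (e.g. the window
    caught the capacitive transient).
    """
    step_sweeps = [s for s in sweeps if s.protocol_tag == "iv_step"]
    if len(step_sweeps) < 2:
        raise ValueError("need at least 2 step sweeps")
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    voltages, currents = [], []
    windows = []
    for s in step_sweeps:
        try:
            v = s.meta["step_voltage"]
            start = s.meta["step_start"]
            dur = s.meta["step_duration"]
        except KeyError as err:
            raise ValueError(f"sweep lacks step metadata: {err}") from err
        t0 = start + dur * (1.0 - window_fraction)
        i0 = int(round(t0 * s.sampling_rate))
        i1 = int(round((start + dur) * s.sampling_rate))
        seg = s.samples[i0:i1]
        if seg.size == 0:
            raise ValueError("steady-state window contains no samples")
        voltages.append(v)
        currents.append(seg.mean())
        windows.append((t0, start + dur))
    order = np.argsort(voltages)
    v_arr = np.asarray(voltages)[order]
    i_arr = np.asarray(currents)[order]
    curve = IVCurve(
        step_voltages=v_arr, steady_state_currents=i_arr, steady_window=windows[0]
    )
    fit = stats.linregress(v_arr, i_arr)
    resid = i_arr - (fit.intercept + fit.slope * v_arr)
    span = np.ptp(i_arr)
    if span > 0 and np.max(np.abs(resid)) > 0.05 * span:
        warnings.warn(
            "I–V relationship deviates from linearity; steady-state window "
            "may overlap a transient"
        )
    return curve


def membrane_resistance(iv: IVCurve, pipette_resistance: float = 0.0) -> float:
    """Membrane resistance (MΩ): inverted slope of the steady-state I–V,
    minus the pipette resistance determined before the experiment."""
    if iv.step_voltages.size < 2:
        raise ValueError("need at least 2 I–V points")
    fit = stats.linregress(iv.step_voltages, iv.steady_state_currents)
    if fit.slope <= 0:
        raise ValueError("non-positive I–V slope; cannot invert")
    r_total = 1e3 / fit.slope  # mV/pA → MΩ
    r_m = r_total - pipette_resistance
    if r_m <= 0:
        warnings.warn("membrane resistance ≤ 0 after pipette subtraction")
    return r_m


def resting_potential(vm_sweep: Sweep, window: float = 1.0) -> float:
    """Resting membrane potential (mV): mean over the first ``window`` s of
    a current-clamp recording taken right after break-in."""
    if vm_sweep.kind != "voltage":
        raise ValueError("resting potential requires a voltage sweep")
    if vm_sweep.samples.size == 0:
        raise ValueError("empty sweep")
    n = max(1, int(round(window * vm_sweep.sampling_rate)))
    return float(vm_sweep.samples[:n].mean())


def average_repeats(
    sweeps: SweepSet | list[Sweep],
    protocol_tag: str | None = None,
    expected: int = 5,
) -> Sweep:
    """Pointwise mean across repeats of one protocol."""
    pool = list(sweeps)
    if protocol_tag is not None:
        pool = [s for s in pool if s.protocol_tag == protocol_tag]
    if not pool:
        raise ValueError("no sweeps to average")
    lengths = {s.samples.size for s in pool}
    if len(lengths) != 1:
        raise ValueError("repeat sweeps have mismatched lengths")
    rates = {s.sampling_rate for s in pool}
    if len(rates) != 1:
        raise ValueError("repeat sweeps have mismatched sampling rates")
    if len(pool) != expected:
        warnings.warn(f"expected {expected} repeats, found {len(pool)}")
    mean = np.mean([s.samples for s in pool], axis=0)
    proto = pool[0]
    return Sweep(
        samples=mean,
        sampling_rate=proto.sampling_rate,
        protocol_tag=proto.protocol_tag,
        kind=proto.kind,
        repeat_index=-1,
        meta={**proto.meta, "n_averaged": len(pool)},
    )


def _baseline(sweep: Sweep, stim_time: float) -> float:
    i1 = int(round(stim_time * sweep.sampling_rate))
    i0 = max(0, i1 - int(round(BASELINE_WINDOW * sweep.sampling_rate)))
    if i1 <= i0:
        return 0.0
    return float(sweep.samples[i0:i1].mean())


def isolate_10th_pulse_stc(avg_10train: Sweep, avg_9train: Sweep) -> Sweep:
    """Isolate the 10th-pulse STC by subtracting the 9-pulse average trace
    from the 10-pulse average trace, after aligning pre-stimulus baselines."""
    if avg_10train.sampling_rate != avg_9train.sampling_rate:
        raise ValueError("sampling rates differ; traces are misaligned")
    n = min(avg_10train.samples.size, avg_9train.samples.size)
    stim = avg_10train.meta.get("stim_time", 0.0)
    if stim != avg_9train.meta.get("stim_time", 0.0):
        raise ValueError("stimulus times differ; traces are misaligned")
    a = avg_10train.samples[:n] - _baseline(avg_10train, stim)
    b = avg_9train.samples[:n] - _baseline(avg_9train, stim)
    diff = a - b
    meta = dict(avg_10train.meta)
    meta["isolated_pulse"] = 10
    return Sweep(
        samples=diff,
        sampling_rate=avg_10train.sampling_rate,
        protocol_tag="stc_isolated10",
        kind="current",
        meta=meta,
    )


def fit_monoexponential_decay(
    trace: np.ndarray,
    sampling_rate: float,
    window: tuple[float, float],
) -> ExpFit:
    """Least-squares fit of I(t) = A·exp(−(t−t₀)/τ) + C over a time window.

    Initialization: C from the final 10% of the window, τ from a log-linear
    regression of |I − C|; refined by Levenberg–Marquardt.  τ outside
    plausibility bounds (0.1 ms – 60 s) raises; a flat window returns an
    unidentifiable fit with amplitude ≈ 0.
    """
    trace = np.asarray(trace, dtype=float)
    t0, t1 = window
    i0, i1 = int(round(t0 * sampling_rate)), int(round(t1 * sampling_rate))
    if not 0 <= i0 < i1 <= trace.size:
        raise ValueError("fit window outside the trace")
    y = trace[i0:i1]
    if y.size < 10:
        raise ValueError("need at least 10 samples in the fit window")
    t = np.arange(y.size) / sampling_rate

    tail = y[-max(1, y.size // 10):]
    c0 = tail.mean()
    a0 = y[0] - c0
    span = np.ptp(y)
    if span == 0 or abs(a0) < 1e-12:
        return ExpFit(
            amplitude=0.0, tau=np.nan, offset=c0, window=window,
            r_squared=1.0 if span == 0 else 0.0, identifiable=False,
        )
    resid0 = np.abs(y - c0)
    usable = resid0 > max(1e-3 * abs(a0), 1e-30)
    if usable.sum() >= 2:
        slope, intercept, *_ = stats.linregress(t[usable], np.log(resid0[usable]))
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0
    tau0 = float(np.clip(tau0, 1e-6, 600.0))

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(a0, tau0, c0), method="lm", maxfev=2000
        )
    except RuntimeError as err:
        raise ValueError(f"mono-exponential fit did not converge: {err}") from err
    a_hat, tau_hat, c_hat = popt
    if not TAU_BOUNDS[0] <= tau_hat <= TAU_BOUNDS[1]:
        raise ValueError(
            f"fitted τ = {tau_hat:.4g} s outside plausible bounds {TAU_BOUNDS}"
        )
    pred = model(t, *popt)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExpFit(
        amplitude=float(a_hat), tau=float(tau_hat), offset=float(c_hat),
        window=window, r_squared=r2, identifiable=True,
    )


def _find_peak(trace: np.ndarray, sampling_rate: float, stim_time: float) -> int:
    """Index of the largest post-stimulus deviation from the pre-stimulus
    baseline (sign-agnostic; STCs are inward/negative)."""
    i_stim = int(round(stim_time * sampling_rate))
    if i_stim >= trace.size:
        raise ValueError("stimulus time beyond the trace")
    base = trace[max(0, i_stim - int(BASELINE_WINDOW * sampling_rate)):i_stim]
    b = base.mean() if base.size else 0.0
    dev = np.abs(trace[i_stim:] - b)
    if dev.max() == 0:
        raise ValueError("no post-stimulus peak found")
    return i_stim + int(np.argmax(dev))


def stc_decay_time(
    avg_sweep: Sweep,
    stim_time: float | None = None,
    window_taus: float = 5.0,
) -> ExpFit:
    """Decay time of an STC (single-pulse average or isolated 10th pulse).

    The fit window runs from the post-stimulus peak for ``window_taus``
    times an initial τ guess (the 1/e decay time of the peak deviation),
    then the fit is repeated once with the window set from the fitted τ.
    The returned fit's ``tau_ms`` is the headline statistic.
    """
    fs = avg_sweep.sampling_rate
    if stim_time is None:
        stim_time = avg_sweep.meta.get("stim_time", 0.0)
        if avg_sweep.protocol_tag == "stc_isolated10":
            stim_time = stim_time + 9 * avg_sweep.meta.get("pulse_interval", 0.01)
    i_peak = _find_peak(avg_sweep.samples, fs, stim_time)
    t_peak = i_peak / fs
    base = _baseline(avg_sweep, stim_time)
    dev = np.abs(avg_sweep.samples - base)
    peak_dev = dev[i_peak]
    below = np.nonzero(dev[i_peak:] < peak_dev / np.e)[0]
    tau_guess = (below[0] / fs) if below.size else 0.05
    tau_guess = max(tau_guess, 2.0 / fs)
    fit = None
    for _ in range(2):
        t_end = min(t_peak + window_taus * tau_guess, avg_sweep.samples.size / fs)
        fit = fit_monoexponential_decay(avg_sweep.samples, fs, (t_peak, t_end))
        if not fit.identifiable:
            return fit
        tau_guess = fit.tau
    return fit


def k_current_decay_time(
    avg_10train: Sweep,
    post_train_start: float = 0.2,
    post_train_end: float = 10.0,
) -> ExpFit:
    """Decay of the slow K⁺ inward current after a high-frequency train.

    The window starts ``post_train_start`` s after the last pulse — by
    default 200 ms, where the saturated fast STC has fully decayed — and
    the fitted τ is reported in seconds (``fit.tau``).
    """
    fs = avg_10train.sampling_rate
    train_end = avg_10train.meta.get("train_end")
    if train_end is None:
        raise ValueError("sweep metadata lacks train_end")
    t0 = train_end + post_train_start
    t1 = min(train_end + post_train_end, avg_10train.samples.size / fs)
    fit = fit_monoexponential_decay(avg_10train.samples, fs, (t0, t1))
    if fit.identifiable and abs(fit.amplitude) < 1e-3:  # pA; no K⁺ current
        return ExpFit(
            amplitude=fit.amplitude, tau=np.nan, offset=fit.offset,
            window=fit.window, r_squared=fit.r_squared, identifiable=False,
        )
    return fit


def saturation_ratio(tau_train_10th_ms: float, tau_single_ms: float) -> float:
    """Ratio of the 10th-pulse (train) STC decay constant to the
    single-pulse one; > 1 indicates uptake saturation during the train."""
    if tau_single_ms <= 0 or tau_train_10th_ms <= 0:
        raise ValueError("decay constants must be positive")
    return tau_train_10th_ms / tau_single_ms


def dialysis_depolarization(
    vm_sweep: Sweep,
    t_measure: float = 600.0,
    initial_window: float = 10.0,
    measure_window: float = 30.0,
) -> float:
    """Depolarization ΔV_M (mV) after ``t_measure`` s of Na⁺ dialysis.

    ΔV_M = mean V_M over the ``measure_window`` ending at ``t_measure``
    minus the mean over the initial window; positive = depolarization.
    """
    fs = vm_sweep.sampling_rate
    if vm_sweep.samples.size / fs < t_measure:
        raise ValueError("series shorter than the measurement time")
    n0 = max(1, int(round(initial_window * fs)))
    i1 = int(round(t_measure * fs))
    i0 = max(0, i1 - int(round(measure_window * fs)))
    return float(vm_sweep.samples[i0:i1].mean() - vm_sweep.samples[:n0].mean())
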