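"""Astrocyte volume-fraction, RVD and chloride FRET quantification.

The astrocyte volume fraction (VF) of the fine processes is estimated
ratiometrically from the chloride-insensitive donor (Cerulean) channel as

    VF(t) = F_process(t) / F_soma(t),

where the soma ROI, being fully occupied by the cell, represents a VF of
100%.  Because both ROIs share the intracellular fluorophore concentration,
the ratio cancels concentration changes (fluorophore dilution during
swelling) and global intensity scale.  Traces are normalized to the mean
over the baseline frames acquired in standard aCSF.

Quality control follows two exclusion rules: recordings whose baseline VF
is unstable (second half of the baseline deviating > 12.5% from the mean of
the first half) and astrocytes showing < 5% swelling after the potassium
stimulus are excluded.  Regulatory volume decrease is quantified as

    RVD (%) = (peak VF change − end VF change) / peak VF change × 100,

which exceeds 100% when the volume undershoots the baseline.

The chloride readout is the soma FRET ratio F_YFP/F_Cerulean; chloride
binding quenches the acceptor, so the ratio rises as [Cl⁻]ᵢ falls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import median as _median_filter
from skimage.morphology import disk as _disk
from skimage.registration import phase_cross_correlation

from .datatypes import ImagingSeries, ROISet, VFTrace, FretTrace

__all__ = [
    "ImagingConfig",
    "CellResult",
    "correct_drift",
    "roi_mean_intensity",
    "compute_vf_trace",
    "normalize_trace",
    "qc_baseline_stability",
    "qc_minimum_swelling",
    "compute_rvd",
    "compute_fret_trace",
    "li_threshold",
    "measure_soma_area",
    "run_imaging_pipeline",
]


@dataclass
class ImagingConfig:
    """Tunable analysis settings with their defaults.

    ``baseline_frames`` is the number of pre-stimulus acquisitions in
    standard aCSF (5 at a 2-min interval).  The baseline-stability rule is
    applied to half-window means by default; ``per_frame`` checks every
    second-half frame instead.
    """

    baseline_frames: int = 5
    baseline_threshold: float = 0.125  # fail iff deviation strictly exceeds
    swelling_threshold: float = 0.05  # fail iff peak change strictly below
    baseline_mode: str = "mean"  # "mean" or "per_frame"
    end_window: int = 3  # frames averaged for the "end VF change"
    smoothing_window: int = 1  # frames; 1 = no smoothing before peak search
    drift_correction: bool = True


@dataclass
class CellResult:
    """Full per-cell output of the imaging pipeline."""

    vf: VFTrace
    fret: FretTrace
    shifts: np.ndarray | None
    config: ImagingConfig = field(default_factory=ImagingConfig)

    @property
    def analyzed(self) -> bool:
        return self.vf.qc_pass


def correct_drift(
    series: ImagingSeries, reference_frame: int = 0
) -> tuple[ImagingSeries, np.ndarray]:
    """Register every frame to the reference by an integer 3-D shift.

    The shift maximizing the cross-correlation of the donor (Cerulean)
    channel is found by Fourier cross-correlation and applied identically
    to both channels.  Returns the corrected series and the per-frame
    shifts (t, 3) in (z, y, x) voxels.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to register")
    cer = series.channel("cerulean")
    ref = cer[reference_frame]
    if not np.any(ref):
        raise ValueError("reference frame is all-zero; no registration signal")
    corrected = np.array(series.data, dtype=float)
    shifts = np.zeros((series.n_frames, 3), dtype=int)
    for ti in range(series.n_frames):
        if ti == reference_frame:
            continue
        if not np.any(cer[ti]):
            raise ValueError(f"frame {ti} is all-zero; no registration signal")
        shift, _, _ = phase_cross_correlation(
            ref, cer[ti], upsample_factor=1, normalization=None
        )
        shifts[ti] = np.rint(shift).astype(int)
        corrected[ti] = np.roll(corrected[ti], shifts[ti], axis=(0, 1, 2))
    out = ImagingSeries(
        data=corrected,
        pixel_size=series.pixel_size,
        z_step=series.z_step,
        frame_interval=series.frame_interval,
        channel_roles=dict(series.channel_roles),
        stimulus_onset_frame=series.stimulus_onset_frame,
    )
    return out, shifts


def roi_mean_intensity(
    series: ImagingSeries, roi_mask: np.ndarray, channel: str
) -> np.ndarray:
    """Mean intensity over the ROI voxels for every frame."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != series.volume_shape:
        raise ValueError("ROI mask does not match the series volume shape")
    if not roi_mask.any():
        raise ValueError("empty ROI")
    stack = series.channel(channel)
    return stack[:, roi_mask].mean(axis=1)


def compute_vf_trace(series: ImagingSeries, rois: ROISet) -> np.ndarray:
    """Raw volume fraction F_process/F_soma on the donor channel."""
    f_roi = roi_mean_intensity(series, rois.process_mask, "cerulean")
    f_soma = roi_mean_intensity(series, rois.soma_mask, "cerulean")
    if np.any(f_soma <= 0):
        raise ValueError("soma donor intensity must be positive at every frame")
    return f_roi / f_soma


def normalize_trace(values: np.ndarray, baseline_frames: int = 5) -> np.ndarray:
    """Divide a trace by its mean over the first ``baseline_frames`` values."""
    values = np.asarray(values, dtype=float)
    if baseline_frames < 2:
        raise ValueError("need at least 2 baseline frames")
    if values.size < baseline_frames:
        raise ValueError("trace shorter than the baseline window")
    base = values[:baseline_frames].mean()
    if base <= 0:
        raise ValueError("non-positive baseline mean")
    return values / base


def qc_baseline_stability(
    normalized_vf: np.ndarray,
    baseline_frames: int = 5,
    threshold: float = 0.125,
    mode: str = "mean",
) -> tuple[bool, float]:
    """Baseline-stability exclusion rule.

    Splits the baseline into halves and compares the second half with the
    averaged first half; the recording fails iff the relative deviation
    strictly exceeds ``threshold`` (> 12.5% by default).  ``mode="mean"``
    compares half-window means; ``mode="per_frame"`` takes the worst
    per-frame deviation of the second half.
    Returns (passed, deviation).
    """
    if baseline_frames < 4:
        raise ValueError("need ≥ 4 baseline frames for two non-empty halves")
    base = np.asarray(normalized_vf, dtype=float)[:baseline_frames]
    if base.size < baseline_frames:
        raise ValueError("trace shorter than the baseline window")
    split = (baseline_frames + 1) // 2
    first, second = base[:split], base[split:]
    m1 = first.mean()
    if m1 <= 0:
        raise ValueError("non-positive first-half baseline mean")
    if mode == "mean":
        deviation = abs(second.mean() - m1) / m1
    elif mode == "per_frame":
        deviation = float(np.max(np.abs(second - m1)) / m1)
    else:
        raise ValueError("mode must be 'mean' or 'per_frame'")
    return bool(deviation <= threshold), float(deviation)


def qc_minimum_swelling(
    normalized_vf: np.ndarray, onset: int, threshold: float = 0.05
) -> tuple[bool, float]:
    """Minimum-swelling exclusion rule (< 5% peak VF increase fails).

    Returns (passed, peak_change) with peak_change the maximum of
    normalized VF − 1 over post-onset frames.
    """
    trace = np.asarray(normalized_vf, dtype=float)
    if not 0 <= onset < trace.size:
        raise ValueError("onset outside the series")
    post = trace[onset:]
    if post.size == 0:
        raise ValueError("no post-onset frames")
    peak_change = float(post.max() - 1.0)
    return bool(peak_change >= threshold), peak_change


def compute_rvd(
    normalized_vf: np.ndarray,
    onset: int,
    end_window: int = 3,
    smoothing_window: int = 1,
) -> tuple[float, float, float]:
    """Regulatory volume decrease statistic.

    peak change = max(normalized VF) − 1 over post-onset frames (optionally
    after a centered moving-average smoothing); end change = mean of the
    last ``end_window`` frames − 1; RVD = (peak − end)/peak × 100.
    Returns (rvd_percent, peak_change, end_change).
    """
    trace = np.asarray(normalized_vf, dtype=float)
    if not 0 <= onset < trace.size:
        raise ValueError("onset outside the series")
    if end_window < 1 or end_window > trace.size:
        raise ValueError("invalid end window")
    work = trace
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        work = np.convolve(trace, kernel, mode="same")
    peak_change = float(work[onset:].max() - 1.0)
    if peak_change <= 0:
        raise ValueError("peak change must be positive to define RVD")
    end_change = float(trace[-end_window:].mean() - 1.0)
    rvd = (peak_change - end_change) / peak_change * 100.0
    return rvd, peak_change, end_change


def compute_fret_trace(
    series: ImagingSeries, soma_mask: np.ndarray, baseline_frames: int = 5
) -> FretTrace:
    """Soma FRET ratio F_YFP/F_Cerulean, normalized to the baseline mean."""
    f_yfp = roi_mean_intensity(series, soma_mask, "yfp")
    f_cer = roi_mean_intensity(series, soma_mask, "cerulean")
    if np.any(f_cer <= 0):
        raise ValueError("soma donor intensity must be positive at every frame")
    raw = f_yfp / f_cer
    norm = normalize_trace(raw, baseline_frames)
    peak_change = float((norm.max() - 1.0) * 100.0)
    return FretTrace(
        raw_ratio=raw,
        normalized_ratio=norm,
        baseline_frames=baseline_frames,
        peak_ratio_change_percent=peak_change,
    )


def li_threshold(image: np.ndarray, tol: float = 0.5, max_iter: int = 200) -> float:
    """Minimum cross-entropy (Li) threshold of a positive-valued image.

    Iterates t_{k+1} = (μ_fg(t_k) − μ_bg(t_k)) / (ln μ_fg(t_k) − ln μ_bg(t_k))
    from the image mean until |Δt| < ``tol`` intensity units, where μ_bg and
    μ_fg are the means of values ≤ t and > t.  The fixed point minimizes the
    cross-entropy between the image and its binary reconstruction.
    """
    vals = np.asarray(image, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty image")
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise ValueError("constant image has no threshold")
    if np.any(vals <= 0):
        raise ValueError("Li threshold requires strictly positive intensities")

    def log_mean(mu_b: float, mu_f: float) -> float:
        return (mu_f - mu_b) / (np.log(mu_f) - np.log(mu_b))

    t = vals.mean()
    converged = False
    for _ in range(max_iter):
        bg = vals[vals <= t]
        fg = vals[vals > t]
        if bg.size == 0 or fg.size == 0:
            # mean fell outside the occupied range; nudge inside
            t = 0.5 * (vals.min() + vals.max())
            continue
        mu_b, mu_f = bg.mean(), fg.mean()
        if np.isclose(mu_b, mu_f):
            return float(t)
        t_new = log_mean(mu_b, mu_f)
        if abs(t_new - t) < tol:
            t = t_new
            converged = True
            break
        t = t_new
    if not converged:
        warnings.warn("Li threshold did not converge; returning last iterate")

    # A fixed point of the iteration is not always the cross-entropy
    # minimizing partition (the criterion need not be unimodal over the
    # discrete partitions); verify against all partitions and move the
    # threshold if a strictly better one exists.
    sorted_vals = np.sort(vals)
    csum = np.cumsum(sorted_vals)
    total = csum[-1]
    n = sorted_vals.size
    boundaries = np.nonzero(np.diff(sorted_vals) > 0)[0]  # last index of ≤-side

    n_b = boundaries + 1
    n_f = n - n_b
    s_b = csum[boundaries]
    s_f = total - s_b
    etas = -s_b * np.log(s_b / n_b) - s_f * np.log(s_f / n_f)
    k = int(boundaries[np.argmin(etas)])
    # keep the Li fixed point when it already induces the optimal partition
    if sorted_vals[k] <= t <= sorted_vals[k + 1]:
        return float(t)
    return float(log_mean(csum[k] / (k + 1), (total - csum[k]) / (n - k - 1)))


def measure_soma_area(
    zstack: np.ndarray,
    soma_roi_2d: np.ndarray,
    pixel_size: float,
    median_radius: int = 2,
) -> tuple[float, int]:
    """Astrocyte soma area (μm²) from a high-resolution z-stack.

    Each plane is median-filtered with a disk of ``median_radius`` pixels
    and binarized at the Li threshold; the area is the mask pixel count
    inside the soma ROI at the plane where that count is maximal (the
    soma's widest optical section), times pixel_size².
    Returns (area_um2, plane_index).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3:
        raise ValueError("zstack must be (z, y, x)")
    soma_roi_2d = np.asarray(soma_roi_2d, dtype=bool)
    if soma_roi_2d.shape != zstack.shape[1:]:
        raise ValueError("ROI must match the plane shape")
    footprint = _disk(median_radius)
    best_count, best_plane = 0, -1
    for zi, plane in enumerate(zstack):
        filtered = _median_filter(plane, footprint=footprint)
        # shift to a strictly positive range for the log-based threshold
        shifted = filtered - filtered.min() + 0.01 * max(np.ptp(filtered), 1e-12)
        if np.unique(shifted).size < 2:
            continue
        mask = shifted > li_threshold(shifted)
        count = int(np.count_nonzero(mask & soma_roi_2d))
        if count > best_count:
            best_count, best_plane = count, zi
    if best_count == 0:
        raise ValueError("empty mask inside the soma ROI on every plane")
    return best_count * pixel_size**2, best_plane


def run_imaging_pipeline(
    series: ImagingSeries,
    rois: ROISet,
    config: ImagingConfig | None = None,
) -> CellResult:
    """Full per-cell analysis: drift correction → VF → normalization →
    QC → RVD → FRET trace.

    RVD is reported only when both QC rules pass; QC flags and the measured
    deviations are always reported.
    """
    config = config or ImagingConfig()
    shifts = None
    if config.drift_correction:
        try:
            series, shifts = correct_drift(series)
        except ValueError as err:
            raise ValueError(f"drift-correction stage failed: {err}") from err
    try:
        raw_vf = compute_vf_trace(series, rois)
        norm_vf = normalize_trace(raw_vf, config.baseline_frames)
    except ValueError as err:
        raise ValueError(f"volume-fraction stage failed: {err}") from err
    onset = series.stimulus_onset_frame
    stable, deviation = qc_baseline_stability(
        norm_vf, config.baseline_frames, config.baseline_threshold,
        config.baseline_mode,
    )
    swelled, peak_change = qc_minimum_swelling(
        norm_vf, onset, config.swelling_threshold
    )
    rvd = end_change = None
    if stable and swelled:
        rvd, peak_change, end_change = compute_rvd(
            norm_vf, onset, config.end_window, config.smoothing_window
        )
    vf = VFTrace(
        raw_vf=raw_vf,
        normalized_vf=norm_vf,
        baseline_frames=config.baseline_frames,
        peak_change=peak_change,
        end_change=end_change,
        qc_baseline_stable=stable,
        qc_min_swelling=swelled,
        baseline_deviation=deviation,
        rvd_percent=rvd,
    )
    try:
        fret = compute_fret_trace(series, rois.soma_mask, config.baseline_frames)
    except ValueError as err:
        raise ValueError(f"FRET stage failed: {err}") from err
    return CellResult(vf=vf, fret=fret, shifts=shifts, config=config)
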