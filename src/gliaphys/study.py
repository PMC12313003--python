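"""Synthetic two-genotype study: cohort generation, analysis, reporting.

`run_full_study` mirrors the structure of a slice-physiology comparison of
wild-type and mutant astrocytes: it generates imaging phantoms and
patch-clamp sweeps for two groups with distinct ground truth, runs the
imaging and ephys pipelines per cell, and writes group summaries and
two-group comparisons (CSV tables plus a JSON bundle).

Per-time-point group comparisons of the normalized VF trace are provided
with Bonferroni correction in place of a repeated-measures ANOVA.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ephys as ea
from .datatypes import ImagingSeries, ROISet, Sweep
from .imaging import ImagingConfig, run_imaging_pipeline
from .stats import compare_two_groups, summarize_group
from .synth import (
    ChlorideDynamicsParams,
    EphysGroundTruth,
    GroundTruth,
    OpticsNoiseParams,
    SceneConfig,
    VolumeDynamicsParams,
    build_astrocyte_phantom,
    ground_truth_rvd,
    render_timeseries,
    simulate_chloride_timecourse,
    simulate_iv_sweeps,
    simulate_na_dialysis_vm,
    simulate_stc_sweeps,
    simulate_volume_timecourse,
)

__all__ = [
    "GroupConfig",
    "StudyConfig",
    "wild_type_like",
    "glialcam_null_like",
    "simulate_imaging_cohort",
    "analyze_imaging_cohort",
    "simulate_and_analyze_ephys_cell",
    "run_full_study",
]


@dataclass
class GroupConfig:
    """Ground-truth settings for one genotype/condition group."""

    label: str
    volume: VolumeDynamicsParams = field(default_factory=VolumeDynamicsParams)
    chloride: ChlorideDynamicsParams = field(default_factory=ChlorideDynamicsParams)
    scene: SceneConfig = field(default_factory=SceneConfig)
    optics: OpticsNoiseParams = field(default_factory=OpticsNoiseParams)
    ephys: EphysGroundTruth = field(default_factory=EphysGroundTruth)
    # cell-to-cell biological scatter (SDs of per-cell parameter jitter)
    peak_change_sd: float = 0.05
    end_change_sd: float = 0.05
    tau_jitter_cv: float = 0.10  # CV applied to STC and K decay constants


def wild_type_like() -> GroupConfig:
    """Wild-type-like defaults: robust RVD with undershoot, fast uptake."""
    return GroupConfig(
        label="wild-type",
        volume=VolumeDynamicsParams(peak_change=0.340, end_change=-0.070),
        ephys=EphysGroundTruth(
            r_membrane=32.91, v_rest=-81.83,
            stc_tau=7.353e-3, k_tau=1.856,
            tau_scale=tuple(np.linspace(1.0, 12.12 / 7.353, 10)),
        ),
    )


def glialcam_null_like() -> GroupConfig:
    """Mutant-like defaults: blunted RVD (no recovery below peak trend),
    slower glutamate uptake, slightly depolarized resting potential."""
    return GroupConfig(
        label="glialcam-null",
        volume=VolumeDynamicsParams(peak_change=0.336, end_change=0.0994),
        ephys=EphysGroundTruth(
            r_membrane=25.50, v_rest=-77.65,
            stc_tau=8.951e-3, k_tau=1.844,
            tau_scale=tuple(np.linspace(1.0, 15.53 / 8.951, 10)),
        ),
    )


@dataclass
class StudyConfig:
    """Configuration of a two-group synthetic study."""

    group_a: GroupConfig = field(default_factory=wild_type_like)
    group_b: GroupConfig = field(default_factory=glialcam_null_like)
    n_cells_imaging: int = 20
    n_cells_ephys: int = 10
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    # per-endpoint test choice, mirroring per-figure practice
    tests: dict = field(
        default_factory=lambda: {
            "rvd_percent": "welch_t",
            "peak_fret_change_percent": "mann_whitney",
            "stc_tau_single_ms": "mann_whitney",
            "stc_tau_10th_ms": "mann_whitney",
            "k_tau_s": "welch_t",
            "r_membrane_mohm": "mann_whitney",
            "v_rest_mv": "welch_t",
            "dialysis_depolarization_mv": "welch_t",
        }
    )


def simulate_imaging_cohort(
    group: GroupConfig,
    n_cells: int,
    seed: int = 0,
    n_unstable: int = 0,
    n_low_swelling: int = 0,
    jitter: bool = True,
) -> list[tuple[ImagingSeries, ROISet, GroundTruth]]:
    """Generate ``n_cells`` phantom cells for one group.

    The first ``n_unstable`` cells are built with a drifting baseline
    (violating the 12.5% stability rule) and the next ``n_low_swelling``
    with 4% peak swelling (violating the 5% minimum-swelling rule); the
    rest follow the group ground truth with per-cell biological jitter.
    """
    if n_unstable + n_low_swelling > n_cells:
        raise ValueError("more QC-violating cells requested than cells")
    rng = np.random.default_rng(seed)
    cells = []
    for ci in range(n_cells):
        vol = replace(group.volume)
        if ci < n_unstable:
            vol = replace(vol, baseline_drift=0.40)
        elif ci < n_unstable + n_low_swelling:
            vol = replace(vol, peak_change=0.04, end_change=min(vol.end_change, 0.0))
        elif jitter:
            vol = replace(
                vol,
                peak_change=max(
                    0.08, vol.peak_change + rng.normal(0.0, group.peak_change_sd)
                ),
                end_change=vol.end_change + rng.normal(0.0, group.end_change_sd),
            )
        v = simulate_volume_timecourse(vol)
        cl, ratio = simulate_chloride_timecourse(
            v, group.chloride, vol.frame_interval
        )
        scene = build_astrocyte_phantom(
            group.scene, seed=int(rng.integers(2**31 - 1))
        )
        series, truth = render_timeseries(
            scene,
            v,
            ratio,
            group.optics,
            seed=int(rng.integers(2**31 - 1)),
            frame_interval=vol.frame_interval,
            stimulus_onset_frame=vol.onset_frame,
            cl_series=cl,
            rvd_nominal=(
                ground_truth_rvd(vol) if vol.peak_change > 0 else None
            ),
        )
        cells.append((series, scene.rois, truth))
    return cells


def analyze_imaging_cohort(
    cells: list[tuple[ImagingSeries, ROISet, GroundTruth]],
    config: ImagingConfig | None = None,
    label: str = "",
    collect_traces: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Run the imaging pipeline on every cell; one row per cell.

    With ``collect_traces`` the normalized VF traces of the QC-passing
    cells are returned alongside the table.
    """
    config = config or ImagingConfig()
    rows = []
    traces = []
    for ci, (series, rois, truth) in enumerate(cells):
        res = run_imaging_pipeline(series, rois, config)
        if res.analyzed:
            traces.append(res.vf.normalized_vf)
        rows.append(
            {
                "group": label,
                "cell": ci,
                "qc_baseline_stable": res.vf.qc_baseline_stable,
                "qc_min_swelling": res.vf.qc_min_swelling,
                "analyzed": res.analyzed,
                "baseline_deviation": res.vf.baseline_deviation,
                "peak_change": res.vf.peak_change,
                "end_change": res.vf.end_change,
                "rvd_percent": res.vf.rvd_percent,
                "peak_fret_change_percent": res.fret.peak_ratio_change_percent,
                "rvd_nominal": truth.rvd_nominal,
            }
        )
    table = pd.DataFrame(rows)
    if collect_traces:
        return table, np.array(traces)
    return table


def simulate_and_analyze_ephys_cell(
    group: GroupConfig, seed: int, jitter: bool = True
) -> dict:
    """One synthetic patched astrocyte: simulate all protocols, analyze."""
    rng = np.random.default_rng(seed)
    gt = replace(group.ephys)
    if jitter:
        cv = group.tau_jitter_cv
        gt = replace(
            gt,
            stc_tau=gt.stc_tau * float(np.exp(rng.normal(0.0, cv))),
            k_tau=gt.k_tau * float(np.exp(rng.normal(0.0, cv))),
            r_membrane=gt.r_membrane * float(np.exp(rng.normal(0.0, cv / 2))),
            v_rest=gt.v_rest + float(rng.normal(0.0, 2.0)),
        )
    s1, s2, s3, s4 = (int(x) for x in rng.integers(2**31 - 1, size=4))

    iv_set = simulate_iv_sweeps(gt, noise=True, seed=s1)
    iv = ea.steady_state_iv(iv_set)
    r_m = ea.membrane_resistance(iv, gt.r_pipette)

    single = simulate_stc_sweeps(gt, n_pulses=1, seed=s2)
    avg_single = ea.average_repeats(single)
    fit_single = ea.stc_decay_time(avg_single)

    train9 = simulate_stc_sweeps(gt, n_pulses=9, seed=s3)
    train10 = simulate_stc_sweeps(gt, n_pulses=10, seed=s4)
    avg9 = ea.average_repeats(train9)
    avg10 = ea.average_repeats(train10)
    isolated = ea.isolate_10th_pulse_stc(avg10, avg9)
    fit_10th = ea.stc_decay_time(isolated)
    fit_k = ea.k_current_decay_time(avg10)

    vm = simulate_na_dialysis_vm(gt, seed=s1)
    dvm = ea.dialysis_depolarization(vm)

    # brief current-clamp recording right after break-in (K⁺-based internal)
    rest_sweep = Sweep(
        samples=gt.v_rest
        + rng.normal(0.0, gt.vm_noise_sd, int(2 * gt.sampling_rate)),
        sampling_rate=gt.sampling_rate,
        protocol_tag="vm_monitor",
        kind="voltage",
    )
    v_rest_hat = ea.resting_potential(rest_sweep)

    return {
        "r_membrane_mohm": r_m,
        "v_rest_mv": v_rest_hat,
        "stc_tau_single_ms": fit_single.tau_ms,
        "stc_tau_10th_ms": fit_10th.tau_ms,
        "k_tau_s": fit_k.tau,
        "saturation_ratio": ea.saturation_ratio(fit_10th.tau_ms, fit_single.tau_ms),
        "dialysis_depolarization_mv": dvm,
        "gt_stc_tau_ms": gt.stc_tau * 1e3,
        "gt_k_tau_s": gt.k_tau,
        "gt_r_membrane_mohm": gt.r_membrane,
        "gt_v_rest_mv": gt.v_rest,
    }


def _per_timepoint_vf_comparisons(
    ta: np.ndarray, tb: np.ndarray, onset: int
) -> pd.DataFrame:
    """Welch tests of normalized VF per post-onset frame, Bonferroni-corrected
    (substitute for a repeated-measures ANOVA with post hoc tests)."""
    if ta.shape[0] < 2 or tb.shape[0] < 2:
        return pd.DataFrame()
    n_tests = ta.shape[1] - onset
    rows = []
    for fi in range(onset, ta.shape[1]):
        cmp_res = compare_two_groups(ta[:, fi], tb[:, fi], test="welch_t")
        rows.append(
            {
                "frame": fi,
                "p_raw": cmp_res.p_value,
                "p_bonferroni": min(1.0, cmp_res.p_value * n_tests),
            }
        )
    return pd.DataFrame(rows)


def run_full_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate and analyze a complete two-group study; return the bundle.

    The bundle holds per-cell tables, group summaries and comparisons; with
    ``out_dir`` set, CSV tables and a JSON summary are written there.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    t_start = time.time()

    cell_tables, summaries, comparisons = [], [], []
    group_traces = {}
    onset = config.group_a.volume.onset_frame
    for group in (config.group_a, config.group_b):
        cells = simulate_imaging_cohort(
            group, config.n_cells_imaging, seed=int(rng.integers(2**31 - 1))
        )
        table, traces = analyze_imaging_cohort(
            cells, config.imaging, label=group.label, collect_traces=True
        )
        cell_tables.append(table)
        group_traces[group.label] = traces
    imaging_df = pd.concat(cell_tables, ignore_index=True)

    ephys_rows = []
    for group in (config.group_a, config.group_b):
        for ci in range(config.n_cells_ephys):
            row = simulate_and_analyze_ephys_cell(
                group, seed=int(rng.integers(2**31 - 1))
            )
            row.update({"group": group.label, "cell": ci})
            ephys_rows.append(row)
    ephys_df = pd.DataFrame(ephys_rows)

    label_a, label_b = config.group_a.label, config.group_b.label
    endpoint_sources = {
        "rvd_percent": imaging_df[imaging_df.analyzed],
        "peak_fret_change_percent": imaging_df[imaging_df.analyzed],
        "stc_tau_single_ms": ephys_df,
        "stc_tau_10th_ms": ephys_df,
        "k_tau_s": ephys_df,
        "r_membrane_mohm": ephys_df,
        "v_rest_mv": ephys_df,
        "dialysis_depolarization_mv": ephys_df,
    }
    for endpoint, source in endpoint_sources.items():
        if source.empty or endpoint not in source.columns:
            continue
        vals_a = source.loc[source.group == label_a, endpoint].dropna().to_numpy()
        vals_b = source.loc[source.group == label_b, endpoint].dropna().to_numpy()
        if vals_a.size == 0 or vals_b.size == 0:
            continue
        for label, vals in ((label_a, vals_a), (label_b, vals_b)):
            s = summarize_group(vals, label=label)
            summaries.append(
                {
                    "endpoint": endpoint,
                    "group": label,
                    "n_cells": s.n_cells,
                    "mean": s.mean,
                    "sd": s.sd,
                    "sem": s.sem,
                }
            )
        if vals_a.size >= 2 and vals_b.size >= 2:
            cmp_res = compare_two_groups(
                vals_a,
                vals_b,
                test=config.tests.get(endpoint, "welch_t"),
                labels=(label_a, label_b),
            )
            comparisons.append(
                {
                    "endpoint": endpoint,
                    "test": cmp_res.test_name,
                    "statistic": cmp_res.statistic,
                    "p_value": round(cmp_res.p_value, 4),
                }
            )

    timepoint_df = _per_timepoint_vf_comparisons(
        group_traces[label_a], group_traces[label_b], onset
    )

    bundle = {
        "seed": seed,
        "imaging_cells": imaging_df,
        "ephys_cells": ephys_df,
        "summaries": pd.DataFrame(summaries),
        "comparisons": pd.DataFrame(comparisons),
        "vf_timepoint_comparisons": timepoint_df,
        "runtime_s": time.time() - t_start,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["imaging_cells"].to_csv(out / "imaging_cells.csv", index=False)
        bundle["ephys_cells"].to_csv(out / "ephys_cells.csv", index=False)
        bundle["summaries"].to_csv(out / "group_summaries.csv", index=False)
        bundle["comparisons"].to_csv(out / "comparisons.csv", index=False)
        if not timepoint_df.empty:
            timepoint_df.to_csv(out / "vf_timepoint_comparisons.csv", index=False)
        report = {
            "seed": seed,
            "groups": [label_a, label_b],
            "n_cells_imaging": config.n_cells_imaging,
            "n_cells_ephys": config.n_cells_ephys,
            "summaries": bundle["summaries"].to_dict(orient="records"),
            "comparisons": bundle["comparisons"].to_dict(orient="records"),
        }
        (out / "study.json").write_text(json.dumps(report, indent=2))
    return bundle
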