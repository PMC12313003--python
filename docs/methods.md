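# Methods

This note documents the models behind `gliaphys`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical choices that affect results.

## 1. Volume dynamics model

Relative cell volume v(t) is piecewise exponential: exactly 1.0 during the
baseline, rising toward 1 + `peak_change` with time constant `tau_swell`
after stimulus onset, then relaxing toward 1 + `end_change` with
`tau_recovery`. The rise phase lasts 5·`tau_swell` by default, so the
achieved maximum is within exp(−5) ≈ 0.7% of the nominal peak; the same
truncation logic applies to the end value. `end_change` may be negative
(volume undershoot), in which case the RVD statistic exceeds 100%, or equal
to `peak_change` with `tau_recovery = ∞` (no recovery).

Defaults (per frame-based acquisition at a 2-min interval): 25 frames, 5
baseline frames, onset at frame 5, `peak_change` +0.340, `end_change`
−0.070, `tau_swell` 120 s, `tau_recovery` 240 s. With these constants the
volume peaks ~10 min after the potassium switch and the recording ends
~30 min later — the time scale of a mild (3→6 mM K⁺) swelling challenge.
An optional mean-centered linear `baseline_drift` across the baseline
frames produces baseline-unstable cells for QC testing without changing
the baseline mean.

## 2. Chloride and sensor model

Chloride follows mass balance: cl(t) = cl₀·(1 − E(t))/v(t), where E(t) is a
phenomenological cumulative efflux saturating at `efflux_fraction` with
time constant `tau_efflux` (default 240 s, tied to the volume-recovery time
constant) starting at the volume peak — i.e. the osmolyte loss that drives
regulatory volume decrease. With `efflux_fraction = 0`, chloride content
cl·v is conserved exactly (pure dilution). No channel-level (VRAC/NKCC)
biophysics is modeled; the generator's purpose is a controllable, invertible
ground truth, not a mechanistic simulation.

The FRET sensor is a single-site binding curve,
ratio(t) = r_min + (r_max − r_min)·kd/(kd + cl(t)); chloride binding
quenches the acceptor, so the acceptor/donor ratio falls as chloride rises.
No published calibration is assumed for the sensor constants: kd defaults
to 8.1 mM and the ratio bounds to 0.6–1.8, all configurable and reported as
free parameters. Resting chloride defaults to 30 mM (astrocytes keep
[Cl⁻]ᵢ well above the passive distribution). The sensor's pH sensitivity is
**not** modeled — a known limitation, since intracellular alkalization also
raises the acceptor/donor ratio.

## 3. Imaging phantom and emission model

The scene is a voxel occupancy map: a spherical soma with occupancy exactly
1.0 (the soma ROI defines a volume fraction of 100%) inside a shell of
"process" voxels whose occupancy is Beta-distributed with mean 0.25
(support strictly inside (0, 1)). During swelling, process occupancy scales
linearly with v(t), clipped at 1; the soma stays saturated. This linear
small-VF mapping is the regime in which process-ROI fluorescence tracks
volume.

Expected donor intensity of a voxel is
`base_intensity · occupancy(t) · concentration(t)` with concentration
∝ 1/v(t) when `dilution_coupling` is on; the acceptor channel is the donor
expectation times the FRET ratio. This reproduces the ratiometric identity
the VF estimator relies on: process/soma donor fluorescence equals the
occupancy-weighted volume fraction with concentration cancelling — and the
generator records the exact per-frame process-ROI occupancy mean
(`vf_truth`) as the oracle, so the cancellation can be asserted to machine
precision (clipping makes `vf_truth` the honest reference rather than
occ₀·v(t) itself).

Counting noise is Poisson below 20 expected photons and a signal-dependent
Gaussian (σ = √mean) above — exact low-count behavior with fast sampling at
high counts and the correct variance everywhere. Optional constant read
noise and a constant sub-voxel drift velocity, rounded to cumulative
integer voxel shifts per frame, complete the artifact model. Integer drift
is deliberate: it is exactly what integer-shift registration can undo, so
registration accuracy and downstream bias can be separated. Defaults:
64×64×12 voxels at 0.26 μm/px and 2 μm z-steps (a crop of a 512-px/133-μm
time-series field), base intensity 200 photons, drift (0, +0.08, −0.12)
voxels/frame.

What the phantom does **not** emulate: real astrocyte morphology (territory,
endfeet, branchlets), spatially heterogeneous swelling (a per-region option
exists but has no literature-backed default), scattering/depth attenuation,
bleaching, and sensor pH sensitivity. Passing recovery tests therefore
demonstrates estimator correctness under the stated optical model, not
robustness to every property of real tissue data.

## 4. Imaging analysis

* **Drift correction** registers every frame's donor volume to the
  reference frame by the integer 3-D shift maximizing Fourier
  cross-correlation (scikit-image's phase correlation, integer precision),
  applied identically to both channels. The donor channel is used because
  it is ion-insensitive.
* **Normalization** divides by the mean over the first 5 frames (the
  pre-stimulus acquisitions in standard aCSF). It is idempotent.
* **Baseline QC**: deviation = |mean(second half) − mean(first half)| /
  mean(first half) over the baseline frames; fail iff strictly > 12.5%.
  The half-window-mean reading was chosen over a per-frame reading for
  robustness at 5 frames (a `per_frame` mode exists; with 5 frames the
  halves split 3 + 2).
* **Swelling QC**: peak change = max(normalized VF) − 1 over post-onset
  frames; fail iff strictly < 5%.
* **RVD**: end change = mean of the last 3 frames − 1 (a single "end" frame
  is noise-sensitive; the window is configurable). Peak detection uses the
  unsmoothed trace by default (optional moving-average window). Reported
  as-is, including values above 100%.
* **Li threshold** implements the minimum-cross-entropy iteration
  t ← (μ_fg − μ_bg)/(ln μ_fg − ln μ_bg) to |Δt| < 0.5, then verifies the
  resulting partition against all discrete partitions (cumulative-sum scan)
  and moves the threshold if a strictly better partition exists — the
  fixed-point iteration alone can settle one data value away from the
  cross-entropy minimum when the criterion is nearly flat. Inputs must be
  strictly positive (the criterion is log-based); the soma-area routine
  shifts each median-filtered plane into a positive range before
  thresholding.
* **Soma area**: per plane, median filter (disk, radius 2 px), Li
  threshold, binarize; the area is the mask pixel count inside the soma ROI
  at the plane where that count is maximal (the soma's widest optical
  section) times pixel_size².

## 5. Electrophysiology

The synthetic astrocyte is passive: steady-state step current
(V − v_rest)/(R_M + R_pip), in pA with mV and MΩ. Evoked currents
superimpose, per stimulus pulse, a fast STC (instantaneous rise,
mono-exponential decay; per-pulse amplitude and τ schedules model uptake
saturation along a 100-Hz train, defaults ramping τ to the saturated
10th-pulse value) and a slow K⁺ current. The slow component is contributed
by pulses 1–9 only — extracellular K⁺ accumulation saturates within the
train — which makes the slow component of 9- and 10-pulse trains identical,
so the 10-minus-9 subtraction isolates the 10th-pulse fast STC exactly (a
linear-superposition identity the tests assert to < 1e−9 of the peak).
Stimulus artifacts and capacitive spikes are omitted by default (an IV flag
adds a charging transient); analyses start after the artifact.

Analysis choices:

* Steady-state I–V: mean over the last 10% of each step; a linearity check
  warns when the window appears to catch a transient. R_M = 1/slope −
  R_pipette (least squares); the estimator is independent of v_rest.
* Mono-exponential fits: Levenberg–Marquardt from a log-linear initial
  guess, offset initialized from the final 10% of the window; fitted τ
  outside 0.1 ms – 60 s raises; flat windows return an unidentifiable fit.
* STC fit window: from the post-stimulus peak for 5 initial-τ-guesses,
  fitted, then refitted once with the window set from the fitted τ. The
  window choice matters: a window placed on the slow tail recovers the K⁺ τ
  instead (documented behavior, exercised in tests).
* K⁺ fit window: 200 ms to 10 s after the train end. 200 ms (rather than
  100 ms) because the saturated 10th-pulse STC (τ ≈ 12–16 ms) still
  contributes ~exp(−8) of its amplitude at 100 ms, enough to bias a
  noiseless fit beyond 4-significant-digit agreement; at 200 ms the
  contamination is ~exp(−16) and negligible. The window start is
  configurable.
* Baselines: mean over the 50 ms preceding the first stimulus.
* Na⁺ dialysis: V_M relaxes from v_rest toward
  V_∞ = v_rest·c/(1 + c) (two-conductance divider between the gap-junction
  coupling c to the hyperpolarized syncytium and the dialyzed cell's own
  0-mV-reversing conductance); c = 0 is the uncoupled
  (gap-junction-blocked) limit. ΔV_M compares the mean over a 30-s window
  ending at 10 min with the mean over the first 10 s; the generator-side
  inversion `coupling_for_depolarization` accounts for the same window
  averaging.
* Units follow reporting convention: STC τ in ms, K⁺ τ in s, currents pA,
  voltages mV. Temperature, holding potential and solutions are metadata
  only.

## 6. Statistics

Groups are summarized as mean ± SEM (sd/√n, ddof = 1) with cell and animal
counts carried separately; tests are performed at the cell level. Two-group
comparisons: Welch t (default), pooled-variance t, or two-sided
Mann–Whitney U — exact by full enumeration of rank assignments (midranks
for ties) when pooled n ≤ 14, tie-corrected normal approximation otherwise.
The exact two-sided p counts assignments with U ≤ min(U, U′) or
U ≥ max(U, U′), capped at 1. Normality is never auto-tested; the test is a
per-endpoint configuration choice. Per-time-point Welch tests with
Bonferroni correction substitute for a repeated-measures ANOVA on the VF
traces, and are labeled as such in the report. p-values are reported to 4
decimals; no one-sided options.

## 7. The synthetic two-genotype study

`run_full_study` generates a wild-type-like group (RVD ground truth 120.6%:
peak +0.340, end −0.070; fast uptake τ 7.353 ms saturating to 12.12 ms; K⁺
τ 1.856 s; R_M 32.91 MΩ; v_rest −81.83 mV) and a mutant-like group with
blunted volume recovery (70.42%: peak +0.336, end +0.0994) and slower
uptake (8.951 → 15.53 ms; K⁺ τ 1.844 s; R_M 25.50 MΩ; v_rest −77.65 mV).
Cell-to-cell biological scatter is log-normal on decay constants (CV 10%)
and Gaussian on the volume excursion (SD 0.05 on peak and end changes) —
modest scatter chosen so that the configured group difference is reliably
detectable at the default cohort sizes (20 imaging / 10 ephys cells per
group). Problem sizes in the test suite and acceptance script (20-cell
cohorts, 50-replicate Monte-Carlo for fit recovery, 10 seeded study runs at
reduced scene size for the power checks) were chosen as the smallest sizes
at which the corresponding law-of-large-numbers statements are stable.

## 8. Known limitations

* The sensor model omits pH sensitivity and photobleaching; FRET-ratio
  recovery tests validate the binding-curve arithmetic, not spectroscopy.
* Occupancy clipping at 1 makes the true VF trace (recorded per frame)
  slightly sublinear in v(t) for the brightest process voxels.
* Drift is integer-voxel by construction; sub-voxel registration error of
  real data is not represented.
* The ephys generator is strictly passive and linear; no access-resistance
  dynamics or capacitance estimation (an access-resistance > 20 MΩ
  exclusion is an upstream recording-quality criterion, not modeled here).
* Animal-level nesting is carried as metadata but not modeled
  (no mixed-effects analysis); tests are cell-level.
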