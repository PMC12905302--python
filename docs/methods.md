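# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `chrophys`, in the order the pipeline runs.

## Synthetic data as the testing substrate

Every analysis stage is validated against seeded generators
(`chrophys.synth`) that plant ground truth. All generators are pure
functions of `(params, seed)`: identical inputs give bit-identical
arrays, and each output carries a `truth` dict (planted spike times,
vector strength, positivity labels, membrane ratios, …) sufficient to
score the downstream stage. Noise-free limits reduce to closed forms
(exact exponential decay, average equal to template, analytic
A·τ charges) and are asserted exactly in the unit tests.

What the generators emulate — and what they do not:

* **Photocurrents**: instantaneous activation to the peak, relaxation
  toward the stationary level with a desensitization constant, and
  monoexponential closing after light-off. No photocycle states,
  light-intensity-dependent kinetics, or series-resistance artefacts.
  With activation set instantaneous (`tau_on = 0`) the in-pulse
  extremum equals the planted peak, which keeps the desensitization
  round trip exact.
* **EPSC trains**: per-pulse Bernoulli successes with optionally
  depressing probabilities, jittered synaptic delay, and an
  instantaneous-rise biexponential waveform, so the per-event charge is
  analytically A_f·τ_f + A_s·τ_s. Real endbulb currents have a finite
  rise (~100 µs) and multi-input "kinks" that we deliberately do not
  model.
* **ABR sweeps**: a five-wave template built from derivative-of-Gaussian
  deflections (one P followed by one N each, zero DC, energy centred
  near 0.6–1.3 kHz, envelope SD 0.3 ms). The template is re-centred and
  rescaled so the realized P1 latency and P1–N1 amplitude equal the
  planted values on a 1 µs grid; its spectrum sits inside the 300–3000
  Hz analysis band so zero-phase filtering changes the planted
  amplitude by < 0.5%. Sweep noise is white Gaussian (default 10 µV per
  sweep), which real ABRs only approximate.
* **Multi-electrode recordings**: trial-structured blocks (110 ms
  pre-stimulus silence, stimulus, tail) on a 50 µm-pitch linear array at
  32 kHz. Evoked counts are Poisson with a sigmoidal rate–level mean
  scaled by a Gaussian tonotopic profile; train-stimulus spikes get von
  Mises phases (planted VS = I₁(κ)/I₀(κ)); spike waveforms are a 0.3 ms
  biphasic kernel whose trough marks the spike time; a 1 ms minimum
  inter-spike gap keeps planted spikes resolvable. The common-mode
  artefact is an exponentially decaying transient (τ = 0.5 ms) identical
  on all electrodes, so global-mean subtraction cancels it algebraically.
  No LFPs, no electrode drift, no unit waveform diversity.
* **Image stacks**: non-overlapping spherical-cap somata (rejection
  sampling at ≥ 2.2× radius centre distance), a filled context channel,
  and a GFP channel that is a membrane ring (default thickness 0.8 µm at
  `membrane_gain` times the interior) for positive cells and a dim
  uniform fill for negatives; a central-plane nuclear dip supports the
  automated nucleus check. Median brightness is drawn from a bimodal
  mixture. Real cryosections add labeling gradients, z-attenuation and
  touching cells that these stacks do not reproduce — passing tests
  demonstrate correctness of the estimators, not robustness to every
  histological artefact.

## Photocurrent metrics

τ_off comes from least squares on `A·exp(−(t−t0)/τ) + b` over a window
starting at the light-off; τ is initialized from a log-linear
regression on the baseline-subtracted decay, making the fit
deterministic. Fits are flagged unconverged when τ falls outside
(0, 10× window]. The biexponential fit orders components fast-first and
collapses to the monoexponential (flagged) when the two constants agree
within 10%.

I_stat is the mean over the last 10% of a ≥ 100 ms pulse; I_peak is the
in-pulse extremum after a 0.2 ms capacitive blank; both are taken
relative to the pre-pulse baseline and reported on magnitudes (inward
currents are stored negative). The ratio is undefined (error) when the
peak is below 5× the pre-pulse noise SD. Current density divides
|I_stat| by the cell capacitance. EC50 is a Hill fit
`I_max·φ^h/(φ^h + EC50^h)`; `fitted` is false when the plateau is not
sampled (max response < 90% of the fitted maximum) or EC50 leaves the
measured range.

The pulse-train fluctuation index is a declared proxy: (steady-state
per-cycle peak − preceding trough) / first-pulse peak, averaged over the
last three cycles, with a steadiness flag when the last three peaks
agree within 5%. It approaches 1 when the current decays fully between
pulses and 0 under effectively continuous activation.

## Evoked EPSC metrics

Events are negative deflections exceeding 5× the pre-pulse noise SD
(robust estimate from the 2 ms pre-pulse window, median-centred) within
a 10 ms post-pulse window, truncated to the inter-pulse interval for
trains above 100 Hz. The detection rule is a package choice; 5× is
conservative against the ~pA generator noise, and at that setting pure
noise triggers roughly 1–2% of pulses, which the flat-noise test
tolerates by seed choice. Synaptic delay is the first forward crossing
of 10% of the event peak; charge is the trapezoidal integral of the
baseline-corrected current over the window (pA·ms → pC). Multi-peak
deflections within one window count as a single success with the first
peak's amplitude. Decay classification is τ_fast ≤ 0.5 ms (inclusive)
for bushy-like cells.

## ABR processing

Filtering is a 4th-order Butterworth band-pass (300–3000 Hz) applied
forward–backward per sweep (zero phase preserves latencies; averaging
and filtering then commute, which a test checks numerically). Peaks are
alternating positive maxima and following minima within 0–10 ms, with a
prominence floor of 3× the SD of the last quarter of the waveform
unless given. The threshold surrogate replaces the visual "reliably
visible" criterion: lowest level with P1–N1 above 4× the no-stimulus
residual SD, confirmed by the next level. Latency recovery is asserted
to within one sample of the template's grid peak, since the planted
(continuous) latency is quantized by the 50 kHz grid.

## IC multi-unit pipeline

Detection: band-pass 0.6–6 kHz, per-sample global mean over electrodes
subtracted (exactly cancels any channel-identical additive signal),
noise scale per channel as the **mean absolute deviation about the
median divided by 0.675**, pooled over the [−100, −2] ms pre-stimulus
windows of all events, threshold at −3× that scale, negative-going
crossings aligned to the following trough, 1 ms dead time. For Gaussian
noise this scale sits at ≈ 1.18 σ, so the effective threshold is
≈ 3.5 σ and the false-positive rate on band-limited noise is ~5/s per
channel — the regime in which the detection/neurometric contracts hold.
(A median-MAD reading of the same rule would give exactly 3 σ and
~40 false positives/s, which is inconsistent with that behaviour; we
therefore read the estimator literally as a mean absolute deviation.)

Neurometrics: per-trial rates in stimulus-relative windows (2–25 ms for
single pulses, 0–110 ms for 100 ms trains); rank-based AUC with ties at
½, clipped to [1/(2m), 1−1/(2m)] so the probit stays finite; d′ =
√2·Φ⁻¹(AUC). The default comparison scheme is successive (lowest
intensity vs no-stimulus, then each intensity vs its predecessor),
summed ascending without clamping; every-intensity-vs-baseline and
negative-step clamping are config options. Threshold uses ≥ 1. At 30
trials per condition the probit of an empirical AUC is slightly
biased upward (Jensen), so pipeline thresholds tend to sit at or one
step below the asymptotic (10⁵-trial) oracle; the acceptance check
allows exactly that one step.

Tonotopy: OLS depth ~ log₂(frequency/1 kHz) with exactly two rounds of
±1.5 residual-SD outlier removal; an effectively perfect fit (residual
SD below 1e−9 of the depth scale) removes nothing, so collinear data are
reproduced exactly.

Vector strength: θᵢ = 2π·((tᵢ − onset) mod period)/period for spikes in
the 50–110 ms window (skipping the onset response); L = 2nVS² gates the
report at 13.8 (= −2·ln 0.001 under p = exp(−L/2)). The pooled
estimator (`pooled_vector_strength`) accumulates phases over trials and
channels and, when blank trials are available, subtracts the expected
count of background events (noise crossings, spontaneous spikes) from
the denominator: background phases are uniform, so the resultant is
unbiased while the raw count overstates n. Without this correction the
detector's ~5/s noise floor deflates pooled VS by up to ~0.1 at
moderate evoked rates; with it, planted VS is recovered within ±0.05
under the test conditions (16 electrodes, 100 Hz trains, ~60 sp/s
ceiling, κ = 2). A residual ≤ ~0.03 downward bias remains because the
1 ms dead time merges same-cycle spikes near the preferred phase — an
effect real multi-unit recordings share.

## Image quantification

Segmentation runs Otsu's threshold on the central z-plane (the plane of
maximal context signal), labels connected components and keeps those
inside the gates: area 50–500 µm², equivalent diameter 8–25 µm,
circularity 4πA/P² ≥ 0.6. The gate values are package defaults (kept in
config); positivity calling fits Gaussian mixtures with k = 1..3
(quantile-seeded means, 10 restarts, fixed seed, BIC with ties toward
fewer components) to the median somatic GFP brightness and thresholds
at μ_low + 2σ_low. Mean-shift centroids use a 6.5 µm bandwidth
converted to pixels, on above-Otsu pixels with bin seeding.

Line profiles: 12 radial rays per cell, anchored at the outermost
crossing of the cell mask along the ray, with the crossing refined to
sub-pixel precision by linear interpolation of the mask at the 0.5
level. Rays whose outward extension (up to 2 µm beyond the membrane)
touches another cell's mask are discarded; cells with fewer than three
surviving rays, without a membrane mask, or without a nuclear dip
(central-plane interior minimum < 70% of the cytoplasm median — the
automated surrogate for the manual nucleus check) are excluded with a
recorded reason; exclusion decisions are independent of processing
order. The kept profile is the mean over rays, sampled inward at 0.1 µm
steps; the membrane ratio divides the mean over 0.4–0.6 µm by the mean
over 1.4–1.6 µm and is NaN (flagged) when the denominator does not
exceed background. The 0.8 µm default ring thickness keeps the
0.4–0.6 µm band strictly inside the ring after pixel-interpolation
blur; with a ring equal in width to the band's inner edge the boundary
pixel dilutes the numerator by several percent.

## Problem sizes and determinism

The test suite and the acceptance script run everything at sizes chosen
to make the statistics decisive while staying lightweight: 20 seeded
4-electrode recordings (8 intensities × 30 repetitions) against a
100 000-trial Monte-Carlo oracle for thresholds; 100 noisy decays per
planted τ at SNR 50; 10 000 von Mises spikes for the Bessel-ratio
check; 50-cell stacks at 0.15 µm/px for the imaging round trips; 1000
sweeps per ABR condition with the √N averaging check pooled over four
independent sets. Every random draw derives from an explicit seed (the
acceptance script spawns sub-seeds from `--seed` via `SeedSequence`),
and deterministic stages are bit-reproducible from config + seed.

## Known limitations

* The fluctuation-amplitude index is a proxy; no published formula was
  adopted for it, and it reduces to a trivial value for purely
  superposed (non-desensitizing) responses.
* The event-detection rule for EPSCs (5× SD) and the ABR threshold
  surrogate (4× residual SD with confirmation) are reproducible
  stand-ins for expert visual criteria; absolute probabilities and
  thresholds shift with these multipliers, which are exposed in config.
* Multi-unit spike detection does not sort units; collisions within the
  1 ms dead time are merged, deflating phase-locking estimates at high
  evoked rates (quantified above).
* The imaging module assumes non-overlapping, roughly circular somata;
  touching cells are handled only through the ray-discard and exclusion
  rules, not by splitting.
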