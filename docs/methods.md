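# Methods

This note describes the models and numerical procedures behind
`synaptoscope`, the assumptions they make, and what the synthetic-data
generator does and does not emulate.

## Scientific setting

The package analyzes two kinds of recording from pharmacology experiments
on spontaneous glutamate release:

1. **Voltage-clamp current traces.** A neuron held at −70 mV shows
   spontaneous excitatory postsynaptic currents (sEPSCs) as brief inward
   (negative) deflections, sampled at 5 kHz. A drug applied in the bath
   (e.g. a nicotinic agonist acting on presynaptic terminals) changes the
   event rate and amplitude; the experiment is structured as
   control → drug → wash epochs.
2. **Calcium-imaging movies.** A small field (280 × 260 μm) of
   indicator-loaded somata imaged at 4 frames/s for 6 min (1,440 frames).
   Each firing episode produces a calcium transient — a fast ΔF/F rise
   with a slow (~1–2 s) decay. Population synchrony is assessed on the
   binary onset raster.

## Drug-effect model (`protocol`)

Drug action is a multiplicative factor on event rate and amplitude. During
a drug epoch the factor approaches its asymptote `R` exponentially,
`f(t) = R + (f₀ − R)·exp(−(t−t₀)/τ)`, with `onset_tau` defaulting to 60 s:
bath-applied drugs reach cells at different depths with variable delay, so
a first-order approach is the simplest defensible shape. During wash the
factor holds at `1 + p·(f_end − 1)` where `p = washout_persistence ∈ [0,1]`;
`p = 1` models effects that outlast the recording (as nicotinic
potentiation of glutamate release does over typical 30-min washes), `p = 0`
full reversal. There is no quantitative washout-kinetics model; persistence
is a free parameter, not fitted.

Defaults `drug_rate_ratio = 2.72` and `drug_amp_ratio = 2.40` correspond to
the +172% frequency and +140% amplitude changes typical of bath nicotine on
spontaneous release.

## Synthetic sEPSC traces (`synth.simulate_epsc_trace`)

* Background events are an inhomogeneous Poisson process,
  rate = `base_rate × rate_factor(t)`, sampled by thinning. Default
  baseline 3.5 Hz.
* Amplitudes are lognormal (median 20 pA, σ_log 0.4) — spontaneous-event
  amplitude histograms are right-skewed — scaled by the amplitude factor.
* The event kernel is a unit-peak biexponential, rise 0.5 ms / decay 3 ms,
  typical of AMPA-receptor-mediated events at 5 kHz sampling; the kernel
  peaks ~1.1 ms after onset.
* Bursts (clusters modelling synchronized multivesicular release) are
  initiated by a Poisson process at `burst_rate` restricted to drug and
  wash epochs, since bursting is a drug phenomenon in this setting; each
  burst contains 3–6 events at 15–25 ms spacing (~50 Hz within-burst).
* A 2-ms refractory merge removes events closer than the detector could
  ever resolve.
* White Gaussian noise, default SD 2 pA. Real recordings additionally
  contain line noise, drift and access-resistance changes that the
  generator does not emulate — passing tests show detector correctness
  under the stated noise model, not robustness to instrumentation
  artifacts.

Ground truth (`SimTruth`) lists every inserted event's onset time,
amplitude and burst membership.

## sEPSC analysis (`epsc`)

* **Noise.** SD = MAD × 1.4826 / √2 of the first-differenced trace.
  Differencing is a one-sample high-pass that removes the holding-current
  offset and slow drift exactly; the MAD makes the estimate insensitive to
  the sparse events themselves. On pure Gaussian noise the estimate is
  unbiased (verified to 2% at 50 s × 5 kHz).
* **Detection.** The trace is smoothed with a 1-sample Gaussian; inward
  local minima at least `refractory` (2 ms) apart are candidates, and a
  candidate is an event when its amplitude — local pre-event baseline
  (median of the 2 ms ending 1 ms before the peak) minus peak — reaches
  `k_threshold` (3) × noise SD. Amplitude from a *local* baseline makes
  detection exactly invariant to constant offsets and robust to overlap
  with a preceding event's decay. Measured fidelity: recall ≈ 0.985,
  precision ≈ 0.999 for 5×SD events at 3.5 Hz.
* **Binning.** 10-s bins; count/width in Hz (or mean amplitude in pA); the
  trailing partial bin is dropped so every bin has equal exposure.
* **Normalization.** Percent of the control-epoch mean (baseline ≡ 100%).
* **Maximal-effect window.** The 5-min bin-aligned window at/after drug
  onset with the greatest mean, ties to the earliest. Because this is a
  maximum over overlapping windows it is upward-biased on noisy single-cell
  series (~+3–6% relative at small effects); the group-level estimate
  therefore averages the normalized histograms across cells *first* and
  selects the window on the group mean, which is also how such experiments
  are conventionally reported. Group recovery error is ≲3% relative for
  rate ratios 1.5–2.72 at 20 cells.
* **Bursts.** A burst is a maximal run of ≥ 3 consecutive events spanning
  50–150 ms whose within-run frequency `(n−1)/span` is at least 1.5× the
  baseline frequency. The 1.5× reading ("exceeded baseline by 50%") is a
  design decision: the alternative reading (half the baseline rate) would
  classify essentially all activity as bursting. Note that with a low
  baseline (e.g. 3.5 Hz) the span constraint dominates — any 3 events
  inside 150 ms already exceed 1.5× baseline — so chance clusters of a
  homogeneous Poisson train do qualify; at 3.5 Hz roughly 0.08 per event.
  Callers wanting a conservative detector should raise `min_events` or
  `rate_factor`. The within-burst frequency uses n−1 intervals, so the
  worked 6-event/100-ms cluster is exactly 50 Hz.
* **Responsiveness.** A cell is responsive when a two-sided Mann–Whitney U
  between control-epoch bins and the bins within 10 min after drug onset
  gives p < 0.05. Under a null protocol the rejection rate is at the
  nominal level (~5–7% over seeds).

## Synthetic calcium traces and movies (`synth`)

Per-cell raw fluorescence = baseline 1.0 + transients (instantaneous rise
of `transient_amp` = 0.3, exponential decay `decay_tau` = 1.5 s) at
background Poisson event frames (0.03 Hz/cell) and at planted ensemble
frames — a population-synchrony process at `ensemble_rate` in which each
cell participates with probability 0.6 — plus Gaussian noise (SD 0.03).
Background and ensemble rates scale per epoch by `condition_rate_ratios`
(default control 1, drug 2, wash 2: activity roughly doubles and
persists). Defaults give 24 cells, 4 frames/s; a 6-min protocol is exactly
1,440 frames.

`render_movie` draws each cell as a uniform disk (diameters 12–20 μm,
within the 4–30 μm template range; somata in this preparation average
~17 μm) at rejection-sampled non-overlapping positions, disk intensity
`cell_intensity × trace`, background 100 a.u., Gaussian pixel noise. Not
emulated: optical point-spread, neuropil contamination, motion,
photobleaching, overlapping somata. End-to-end tests therefore validate the
geometry and signal path of ROI extraction, not robustness to those
nuisances (motion correction and neuropil subtraction are out of scope).

## Calcium analysis (`caimg`)

* **ΔF/F** = (F − F₀)/F₀ with F₀ the 10th percentile of the raw trace —
  a "resting fluorescence" estimate that transients cannot contaminate
  (they occupy well under half of the recording at the modelled rates).
  Cells with F₀ ≤ 0 are excluded with a diagnostic. ΔF/F is exactly
  invariant to multiplicative illumination gain.
* **ROI extraction.** The summary image is the per-pixel temporal SD,
  which highlights active somata and is identically flat for static
  structures; after 1-px Gaussian smoothing, local maxima above a robust
  floor (median + 5 MAD) are candidate centres. Because a uniform soma
  produces an SD *plateau*, each candidate is refined by two mean-shift
  steps on the supra-floor mass before fitting the disk diameter
  (disk-minus-annulus contrast, 4–30 μm) and greedily accepting
  non-overlapping ROIs in decreasing peak order. Rendered-movie recovery:
  centres within 2 px of truth.
* **Transient detection.** Per cell, with robust noise SD σ (MAD with one
  masking iteration): onsets are local maxima (with a prominence floor) of
  the two-frame rise statistic `r_t = (x_{t+1}+x_t−x_{t−1}−x_{t−2})/2`
  exceeding `k_deriv` (2.5) × the robust SD of `r`, accepted when the
  following ΔF/F peak reaches `k_amp` (2.5) × σ. The two-frame rise is
  used instead of the plain first difference deliberately: for white noise
  its SD equals σ while it captures ~0.92 of a step transient's amplitude,
  whereas a single-frame difference carries √2σ noise and would miss ~15%
  of 5σ transients. Joint gating keeps the false-event rate
  (~1.6×10⁻³/frame) well below the Gaussian tail bound for k = 2.5
  (6.2×10⁻³) while recall and precision stay ≥ 0.95 at 5σ amplitude.
  Onsets are localized to ±1 frame; events closer than ~2 frames (500 ms)
  are below the temporal resolution and merge.
* **Raster.** 1 exactly at onset frames. Onset-only marking (rather than
  the transient's full duration) follows from using the derivative as the
  firing indicator; duration-marking would inflate coactivity at a 1.5-s
  decay.
* **Coactivity and significance.** Coactivity is the per-frame column sum.
  The null preserves each cell's event count and within-cell timing while
  destroying across-cell alignment: every surrogate circularly shifts each
  row by an independent uniform offset, and the per-surrogate *maximum*
  coactivity builds a family-wise null over frames. The threshold is the
  smallest count reached by fewer than `alpha × n_surrogates` (default
  0.05 × 1,000) surrogates. On independent-cell rasters the family-wise
  rate of declaring any peak is at or below the nominal 5% (discreteness
  of the count statistic makes it conservative, typically 1–4%). With
  `alpha ≥ 1` the threshold degenerates to 1 (every coactive frame
  flagged), documented as a limiting case.
* **Per-cell activity.** Active-frame counts and fractions per condition;
  condition comparisons use two-sample KS tests against control and a
  Friedman test across the paired per-cell triplets.

## Nonparametric tests (`stats`)

Mann–Whitney U (midranks; exact by full enumeration of the C(n+m, n)
relabelings for n+m ≤ 12, else tie-corrected normal approximation with
continuity correction; two-sided p = doubled smaller tail, capped at 1),
two-sample KS (D by ECDF sweep; exact enumeration for n+m ≤ 10, else
Kolmogorov asymptotic with the Stephens small-sample correction), Friedman
(tie-corrected chi-square on within-subject midranks; fully tied rows give
statistic 0, p = 1). Exact enumeration under exchangeability is valid with
ties, which the small-sample bin comparisons routinely contain. Agreement
with brute-force enumeration is exact to 1e-12; asymptotic branches match
scipy.

## Numerical and degenerate-input choices

* Robust scale estimates use MAD × 1.4826 throughout; noiseless traces
  (SD = 0) degrade detection thresholds to "any strictly positive
  deflection", so noiseless fixtures behave deterministically.
* Empty event trains, all-zero rasters, and 0-cell movies flow through and
  produce empty results rather than errors wherever the operation is
  well-defined; genuinely ill-posed requests (zero-duration bins, windows
  that do not fit, fewer than 3 baseline bins, control mean of zero)
  raise `ValueError` with a diagnostic.
* Window selection and burst scans break ties to the earliest candidate;
  all detection is deterministic for a fixed trace, and every stochastic
  stage (generators, surrogates) takes an explicit seed and is
  bit-reproducible.

## Problem sizes

Validation uses the recording geometry the defaults describe: 5 kHz ×
10-min epochs for current traces, 1,440-frame rasters of 20–30 cells,
1,000 surrogates, 20 cells per drug-effect recovery run, and 200 replicate
rasters for the family-wise-rate simulation.

## Known limitations

* The burst definition is intentionally permissive at low baseline rates
  (see above); burst counts on undrugged Poisson-like activity are
  non-zero by construction.
* Transients, not spikes: no deconvolution to spike counts is attempted,
  and events within ~2 frames merge.
* The generator's conditions are stationary within epochs; slow
  non-stationarities (rundown, drift) are not modelled.
* The Monte Carlo scheme (circular shifts, maximum-coactivity statistic)
  is one standard, conservative choice among several used for ensemble
  detection; no claim is made that it reproduces any particular
  acquisition software's internal test.
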