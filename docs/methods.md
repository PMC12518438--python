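# Methods

This note records the models, conventions and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
known limitations. Units throughout: time in s (ms where stated), lengths in
µm, potentials in mV, currents in pA, capacitance in pF.

## Beat analysis

**Processing order.** Per recording: (1) moving median filter, radius 10
samples; (2) moving mean filter, radius 5; (3) subtraction of the global
minimum (offset); (4) noise-amplitude estimation; (5) per-stimulus beat
analysis; (6) per-frequency summary. "Radius r" means a centered window of
2r+1 samples; windows shrink at the trace edges rather than padding, and the
implementation is verified element-wise against a naive sliding-window
reference. Sarcomere-length traces are negated before step (1) so the same
peak-oriented machinery applies; reported diastolic levels are mapped back
to µm.

**Stimulus detection** thresholds the stimulus-voltage channel at half its
maximum and takes rising edges. Pacing intervals are segmented wherever the
inter-stimulus interval changes by more than 10 % relative to its
predecessor — the tightest adjacent step in the 0.5–4 Hz ladder
(2.5 → 3 Hz) changes the interval by 16.7 %, so all seven rungs separate.

**Noise amplitude.** A_noise is the maximum of the offset-subtracted
filtered signal over every 200 ms pre-stimulus window in intervals paced at
≤ 1 Hz. If no such interval exists the caller must supply A_noise
explicitly; it is never silently estimated at faster rates, where late decay
contaminates the window.

**Per-beat metrics.** The search window of a stimulus runs to the next
stimulus (or trace end). The diastolic level is the *mean* of the 200 ms
pre-stimulus window (falling back to the value at the stimulus). The window
minimum is also available (`diastolic_mode="min"`), but the minimum of a
noisy window is biased low by O(σ), and because the TTP/TTBL levels sit at
10 % of the amplitude — where the decay is nearly flat — that small level
bias is amplified ~20× into the TTBL₉₀ crossing time; the mean is unbiased
and equally simple. Capture requires a peak ≥ 2·A_noise above the diastolic
level (`scipy.signal.find_peaks`; ties break toward the earliest sample).
The amplitude is the filtered maximum minus the diastolic level. For the
kinetic metrics the peak *time* is refined as the local maximum of a cubic
polynomial fitted over ±20 ms around the sample argmax: under noise the raw
argmax of an asymmetric transient drifts systematically toward the flatter
decay flank, and the cubic term absorbs exactly that flank asymmetry
(a parabola does not). The 10 % crossings are found by linear interpolation
between bracketing samples, taking the last sub-level sample before the peak
on the upstroke and the first after it on the decay. A decay that never
recrosses 10 % before the window ends leaves TTBL₉₀/CATD₉₀ undefined
(`decay_resolved=False`) rather than truncated. CATD₉₀ is computed as the
sum TTP₉₀ + TTBL₉₀, so the identity holds exactly by construction.

**Summary.** The mean over the last six captured beats of an interval
(fewer if fewer were captured, with the count recorded).

**Sarcomere length from striations.** Power spectrum of the mean-subtracted
brightfield profile, restricted to the physiological period band
1.4–2.4 µm; the peak is refined by parabolic interpolation of log-power
across the three bins around the maximum. If the in-band peak is below 10×
the median non-DC power the estimate is undefined and an error is raised —
white-noise periodograms reach ~5–7× the median by chance, genuine striation
peaks sit orders of magnitude above.

## TATS quantification

**Cell segmentation** (`segment_cell`). Gaussian smoothing, then either
Otsu's threshold (`mode="interior"`, for volume dyes) or, for
surface-stain images (`mode="membrane"`): threshold at half the sarcolemmal
peak level (99.9th percentile of the smoothed volume), per-z-slice hole
filling, largest connected component. The half-max contour of a membrane
*ridge* sits one half-width-at-half-max outside the ridge centre, so the
filled mask is eroded back by √(2 ln 2)·σ_total (σ_total from the smoothing
width and a nominal 0.12 µm confocal PSF; overridable via
`edge_erode_um`). On phantoms this places the boundary within ~0.1 µm of
the true surface.

**Tubule segmentation** (`segment_tats`). A 0.5 µm surface rim (Euclidean
erosion in physical units) is excluded so the sarcolemma does not count as
tubules. The image is background-corrected by subtracting a 2 µm-smoothed
copy; the threshold is the full-width-half-maximum rule — halfway between
the interior background (median) and the tubule peak level (99.5th
percentile of interior voxels) — which places the mask edge at the true
tubule boundary under a symmetric PSF. Otsu's method was rejected here: on
sparse bright structures over a dominant background its threshold falls into
the blur skirt and roughly triples the segmented volume. If the peak level
does not clear the background by 4 robust standard deviations
(median absolute deviation × 1.4826) the cell is reported tubule-free.

**Metrics.** Volume density = 100·|tats|/|cell|. Mean distance: Euclidean
distance transform of the tubule complement with anisotropic voxel sampling,
averaged over all cell voxels (tubule voxels contribute zero); verified
bit-for-bit against exhaustive nearest-tubule search on small volumes.
Skeleton density uses `skimage.morphology.skeletonize` (3-D thinning).
Spectral density: the tubule occupancy fraction per slice along the
longitudinal axis (within-cell normalisation), mean-subtracted, Fourier
transformed; the score is band power (periods 1.5–2.5 µm, the sarcomeric
band) over total non-DC power. The score is dimensionless, in [0, 1],
translation-invariant, and should not be compared numerically across
differently normalised definitions of "spectral density".

## Mitochondrial ratiometry

Cell masks from the autofluorescence proxy: three-class Otsu separates
background / cytosol / mitochondria; the boundary threshold is the midpoint
of the background and cytosol class *modes* (class medians are dragged
upward by mitochondria-adjacent voxels), which places the edge at the
half-height of the blurred background→cytosol step. The mitochondrial
threshold is the within-cell histogram mode (256 bins over the observed
range, ties toward the lower bin) plus 2× the sample SD of the *raw*
(unbinned) within-cell intensities, applied to the MTG channel — the
potential-independent structural marker. The TMRM/MTG ratio is the quotient
of the within-cell channel sums; colocalization is the Pearson correlation
over within-cell voxels. The binning choice is fixed in the API and
reproduced exactly by an independent histogram oracle in the tests.

## Electrophysiology

**AP metrics** are read from one selected beat (default the 30th, the
steady-state convention; fewer beats raise an error naming the rule).
Upstrokes are runs of at least two consecutive samples whose discrete
dV/dt exceeds max(20 mV/ms, 25 % of the trace maximum) — the persistence
and adaptive floor prevent isolated noise excursions from counting as
beats over long recordings. The upstroke onset (first sample of the run) is
time zero for all APDs; RMP is the mean over 50→5 ms before onset;
dV/dt_max is the maximum discrete derivative between onset and peak;
overshoot is the peak (mV above 0); APD_x is the interpolated time to x %
repolarisation between peak and RMP, APD_0mV the first downward 0 mV
crossing.

**Current measures.** I_to per sweep = (pulse peak − end-of-pulse mean) /
capacitance, with the end window the last 5 % of the commanded step
(configurable). The peak is read from a lightly smoothed copy of the pulse
(1 ms boxcar): the raw maximum of a noisy trace estimates the noise ceiling,
not the current, and the smoothing bias cancels exactly in all normalised
quantities (activation, availability, paired-pulse ratios). I_K is the
end-of-pulse mean density; I_K1 the control-minus-blocked end-of-pulse
difference per commanded potential (inward currents negative); protocols
must match or the pair is rejected. Activation normalises I_to(V) to the
+60 mV reference — under a linear driving-force assumption the reversal
potential cancels in that quotient, so no E_rev correction is applied by
default.

**Fits.** Boltzmann: y = 1/(1+exp(±(V50−V)/k)), sign per direction, k
reported positive; initial V50 from the half-crossing, k from a small grid;
flat data (range < 0.2) is rejected as transition-free. Bi-exponential:
amplitudes and offset solved linearly on a log-spaced τ grid, best grid
point refined by `scipy.optimize.curve_fit`; τ_fast < τ_slow enforced by
post-fit ordering, c₁ = A_f/(A_f+A_s), and a τ ratio < 2 triggers a
poor-separability warning. Recovery: y(t) = 1 − a e^(−t/K_f) − b e^(−t/K_s)
with a, b ≥ 0, same grid-then-refine strategy. All fits are invariant to
the time origin of the sweep.

## Equivalence statistics

Welch's t test (unequal variances, Satterthwaite df) for differences;
Holm–Bonferroni step-down for multiplicity, applied within each parameter
across its group comparisons. Equivalence uses TOST at α = 0.05 with
relevance bounds of ±30 % of the control-group mean (bounds follow the sign
of the control mean, so negative-valued metrics such as RMP work
unchanged).

The relative bound makes the anchor itself an estimate. Treating
0.3·x̄_control as a known constant and running a plain TOST underestimates
the variance of the anchored contrast — var(x̄_t − 1.3·x̄_c) =
σ_t²/n_t + 1.69·σ_c²/n_c, while the plain test uses σ_c²/n_c + σ_t²/n_t —
which inflates the type-I error at the equivalence boundary to ≈ 0.07
*regardless of sample size*. Each one-sided hypothesis is therefore tested
as a Welch comparison of the treated group against the correspondingly
*scaled* control group (factors 0.7 and 1.3), which propagates the anchor
uncertainty and holds the boundary size at ≈ α (verified by simulation at
10⁴ replicates). A fixed-bound TOST is also provided; on that path the
p-value rule and the (1−2α)-CI inclusion rule agree exactly, and the
p-values match `statsmodels` to 10⁻⁹.

The troponin worked example is arithmetic: an assay that never reaches its
detection limit c_min in volume V bounds the released amount at c_min·V,
and dividing by the organ's total content bounds the damaged-cell fraction.
The exact quotient is reported without rounding.

## Synthetic generators: what they emulate, and what not

All generators are deterministic under an explicit seed (no global state)
and return ground truth sufficient to compute the expected downstream
output.

**Transient/contraction traces.** The beat is a peak-normalised difference
of exponentials (1−e^(−t/τ_rise))·e^(−t/τ_decay) — chosen for monotone
rise/decay and a closed-form peak time τ_rise·ln(1+τ_decay/τ_rise) — scaled
by the amplitude and added to the diastolic level; consecutive beats
superpose linearly, so the diastolic level rises at fast pacing as in real
cells. Defaults: τ_rise 15 ms, τ_decay 65 ms (TTP₉₀ ≈ 24 ms, TTBL₉₀ ≈
165 ms, realistic for rat myocytes near 35 °C and resolvable inside the
250 ms period at 4 Hz), amplitude 0.5 ratio units on a diastolic level of
1.0, noise SD 5 % of the amplitude, 5 % missed beats, pacing ladder
0.5/1/1.5/2/2.5/3/4 Hz with each interval ≥ 24 stimuli or ≥ 12 s. The
sampling rate (2 kHz) is set by a resolvability rule: the 21-sample median
window must stay short against the rise time (at 2 kHz it spans 10.5 ms and
attenuates the peak by ~1 %). Specs whose pulse peak falls outside one
stimulation period at the fastest rate are rejected as unresolvable.
Per-beat ground truth (amplitude, TTP₉₀, TTBL₉₀) is evaluated on the
noise-free continuous model at 5× oversampling with the same metric
definitions, so superposition at fast pacing is part of the truth, not an
analysis error. Stimuli are 2-sample 5 V rectangles — the generator does not
model stimulus-artifact shapes. No Ca²⁺ buffering, alternans, or
frequency-dependent kinetics are modelled: passing recovery tests shows the
*measurement chain* is unbiased, not that the pulse model captures cell
physiology.

**TATS phantom.** Transverse tubules are radius-0.25 µm cylinders along y
on an (x, z) lattice (spacing 1.8 µm, positional jitter 0.05 µm), with
optional axial connectors and Bernoulli dropout; the cell is a box with a
1-voxel bright sarcolemmal shell and a dim cytosolic interior, blurred by a
Gaussian PSF (0.2/0.1/0.1 µm in z/y/x) with additive noise. The analytic
volume fraction of the transverse lattice is πr²/(s_x·s_z)·(1−dropout);
voxelisation puts the rendered truth mask within ~15 % of it. Real TATS
geometry (branching, orientation mixtures, depth-dependent attenuation) is
not modelled.

**Mitochondrial phantom.** The mitochondrial compartment is a smoothed
random field thresholded at the quantile that realises the target volume
fraction, excluded from a 0.3 µm cortical rim below the sarcolemma (where
the myofilament lattice excludes large organelles — this also keeps
boundary partial-volume effects out of the masks). MTG is near-binary
(contrast 300 over background 100, noise SD 15); TMRM carries a smooth
multiplicative texture inside mitochondria, emulating membrane-potential
heterogeneity, whose amplitude is solved from the realised sample moments
so the within-cell Pearson correlation of the noisy channels hits the
target (default 0.7) up to the noise draw. A target of 1.0 yields exactly
proportional channels.

**Voltage-clamp and AP templates.** Currents follow the bi-exponential
density model gated by a Boltzmann activation at each potential; truth
constants default to measured adult-rat values (τ_fast 48.7 ms, τ_slow
322 ms, c₁ 55.2 %, half-inactivation −34 mV, K_fast 50.5 ms, K_slow
1319 ms, I_to ≈ 42 pA/pF at +60 mV on 172.6 pF, I_K 18.9 pA/pF, I_K1 ≈
−5.9 pA/pF at −120 mV). The paired-pulse recovery intervals grow
geometrically by 1.5 from 5 ms. The AP template is a linear 1 ms upstroke
and a single-exponential repolarisation with τ = APD₅₀/ln 2 measured from
the onset, which fixes every APD in closed form. These are measurement
templates, not membrane models — no Hodgkin–Huxley dynamics, no I_Na/I_Ca
interplay, no rate adaptation.

**Group samples and study.** Per-cell metrics are normal with a common
coefficient of variation (default 8–10 %); the treated mean is
(1+effect)·control. The end-to-end study runs 2 groups × n cells (default
10; 6 in the acceptance run) through every modality at reduced problem
sizes — pacing ladder restricted to 1–2 Hz, phantom extents of a few
hundred thousand voxels — chosen so a complete study finishes in about a
minute while every per-metric TOST at ±30 % retains essentially full power
at the configured cell-to-cell variability.

## Known limitations

* The beat model's fixed kinetics make TTBL₉₀ at 4 Hz partly a summation
  effect rather than true acceleration of decay; recovery statistics only
  use beats whose decay resolves within the window.
* The TATS spectral score is a band-power ratio; its absolute value depends
  on the projection and normalisation and is comparable only within this
  package.
* Membrane-mode cell segmentation assumes a closed sarcolemmal outline per
  z-slice (valid for rod-shaped myocytes; not for ruptured cells).
* The mode+2SD mitochondrial threshold under-counts the true volume
  fraction by a few points when the within-cell histogram is strongly
  bimodal (threshold ≈ mode + 0.92×separation); recovered fractions of
  ~28 % for a 30 % phantom reflect the estimator, not a bug.
* Capacitance is an input; no leak subtraction or series-resistance
  modelling is attempted.
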