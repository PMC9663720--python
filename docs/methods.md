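# Methods

This note documents the models, the synthetic-data assumptions, the numerical
choices, and the limitations of `rfus`. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Signal model of the simulated acquisition

A compound-frame movie is the sum of three components on a fixed grid of
100 µm pixels:

* **Tissue clutter** — an exactly rank-k component (default k = 2): smooth
  complex spatial patterns times slow (< 0.2 Hz) temporal courses, scaled to
  20× the RMS blood amplitude with distinct per-component scales. Rank-k
  clutter at high amplitude is the minimal structure under which SVD
  spatiotemporal filtering is meaningful: the clutter occupies the k largest
  singular components of every block's Casorati matrix and is removed
  exactly whenever k is below the number of removed components.
* **Blood** — a temporally white circular complex Gaussian process confined
  to a vessel mask, with per-frame variance `baseline_blood_power × (1 + h(t))`,
  where `h` is the planted four-cosine response triggered at each flash
  onset. Power Doppler therefore tracks blood volume by construction, which
  is the physical premise of fUS.
* **Noise** — white circular complex Gaussian, sd `noise_sd` per complex
  sample (default 0.05 against unit blood power).

All random draws derive from a single seed through spawned sub-streams;
every simulator is bit-reproducible.

The **stimulation protocol** defaults to 45 s baseline, 50 trials of
15 s OFF / 0.8 s flash / 15 s OFF, and 75 s recovery — 1660 s in total, with
flash onsets at 60 + 30.8k s. The trial period is 30.8 s: this is the only
reading consistent with the 1660 s total duration.

### Ground-truth response presets

The planted response uses the four-cosine model itself (delay 0.4 s, rise
2 s, fall 5 s, undershoot 2% of baseline, return 6 s), with amplitude 21% of
baseline for the wild-type preset and 37% for the transgenic preset — the
two presets differ only in amplitude. The timing was chosen as a fast,
retina-like transient that still correlates (r ≈ 0.44) with the canonical
double-gamma regressor used for detection: the detection stage of this
method only works on responses with appreciable canonical overlap, so a
ground truth nearly orthogonal to the canonical kernel would be an
unrealistic stand-in for data on which the method demonstrably operates.

The group presets used in statistical experiments plant per-animal mean
amplitudes of 20.83% (WT) and 37.25% (TG) with between-animal spreads of
3.03 and 5.06 percentage points. With those spreads the exact rank-sum test
at n = 6 vs 6 detects the group difference in essentially every replicate,
while identically planted rise/fall times are flagged at roughly the nominal
false-positive rate.

## Scaled acquisition preset

Simulating the acquisition at hardware scale (1660 s × 500 Hz × 128×100
complex pixels) costs ~13 GB per animal and hours of SVD. End-to-end runs
therefore use a scaled preset — 100 Hz compound rate, blocks of 40 frames
with 12 singular values removed, 32×32 grid — chosen to preserve every ratio
the analysis depends on: the 2.5 Hz Doppler rate (hence the 77-sample trial
epochs), the 30% singular-value cut, and clutter rank ≪ removed components.
The price of the smaller block is √5 more per-pixel speckle noise in each
Doppler sample; detection head-room and amplitude recovery are re-validated
by the tests under this preset. Type defaults (block 200, 60 removed,
500 Hz) remain the hardware values.

Two small systematic effects are visible in planted-truth recovery and are
properties of the method, not bugs: (i) each Doppler sample integrates the
blood variance over its 0.4 s block, flattening the response peak by ~1.5%
of the amplitude; (ii) the clutter filter removes a stochastic share of
blood power per block, adding multiplicative noise that largely cancels in
the percent-change normalisation. Together they bias the recovered amplitude
by about −2 to −3% (relative), within the 5% recovery tolerance used
throughout.

## Activation mapping

The design matrix has three columns: the flash boxcar convolved with the
canonical double-gamma HRF (gamma shapes 6 and 16, unit scale, undershoot
ratio 1/6, 32 s support, peak-normalised — its mode is at 5 s), a constant,
and a zero-mean linear trend (equivalent to linear detrending; no spatial or
temporal smoothing anywhere). Per pixel, ordinary least squares gives
t = β_stim/SE with n−3 degrees of freedom, converted to z through the normal
quantile of the t tail probability and capped at ±38 (the double-precision
tail limit); zero-variance pixels yield z = 0, p = 1 and are flagged rather
than raised. rRBV is defined from the GLM coefficients as
`100 · β_stim · max(regressor) / β_const`. Bonferroni (α divided by the
pixel count) is a display threshold only; the ROI — a disc of 1.4 mm
diameter centred on the z argmax, ties broken in row-major order — feeds the
quantitative pipeline regardless of thresholding.

The ROI trace is the spatial mean over the disc, expressed as percent change
against the mean over the initial 45 s baseline period (the definition of
"baseline samples" is otherwise unstated; the pre-stimulus recording is the
unambiguous choice). Epochs span [−14.8 s, +16.0 s) around each onset — 77
samples aligned to the 0.4 s Doppler grid, 37 of them pre-onset — and each
trial is re-baselined to its own pre-onset mean.

## Four-cosine fitting

Bound-constrained least squares (`scipy.optimize.least_squares`, trf) with
box bounds t0 ∈ [0,3], tr ∈ [0.2,10], A ∈ [0,200], tf ∈ [0.2,15],
tb ∈ [0.2,15] s; the undershoot is parameterised internally as
`Au = ratio · A` with ratio ∈ [0,1], so the physiological constraint
0 ≤ Au ≤ A stays a box. Multi-starts are deterministic: a data-driven
initialisation (peak height, crude timings) plus a seeded Latin-hypercube of
the box (8 starts by default); tolerances 1e-8. Noiseless model samples are
recovered to machine precision; under noise sd = A/10 on a 77-sample trial
the amplitude lands within 10% of truth in ≳95% of runs. Non-convergence is
reported in the result, never raised. Delay, undershoot and return time are
fitted and reported but excluded from group statistics by default — they are
poorly identified on single-animal averages.

## Bootstrap stability

For each subset size N (default 5…50), 100 resamples of N trials drawn with
replacement are averaged and refitted (warm-started from the full-data fit;
the multi-start machinery still guards the full fit). The stability rule
declares a parameter stable at the smallest N whose relative error stays
below 5% for **all** larger N, guarding against dips. Two definitions of
relative error are provided: bootstrap sd divided by the N = 50 estimate
(default) and |mean(N) − mean(50)| / mean(50) (`criterion="bias"`); the
underlying report is ambiguous between them. Under the default calibration
(20% amplitude, 10% noise per sample) the sd-based relative error at N = 25
sits almost exactly on the 5% bar — the matched-filter lower bound for any
estimator under those conditions is ≈4%, so the stable-N of the amplitude
scatters between roughly 24 and 33 across seeds. The bias-based criterion
stabilises far earlier. This knife-edge behaviour is a property of the
prescribed calibration, documented rather than tuned away.

## Group statistics

"Wilcoxon test" between two independent groups is read as the rank-sum
(Mann–Whitney) test — signed-rank would require a pairing that does not
exist. `scipy.stats.mannwhitneyu` computes it, exact for groups of ≤ 8
without ties, tie-corrected normal approximation otherwise; an enumeration
oracle cross-checks the exact branch in the tests. No correction is applied
across the four compared parameters. Group summaries are mean ± SEM.

## Ultrasound localization microscopy

Detection: regional maxima above threshold with minimum separation 2σ of the
point-spread function. Sub-pixel refinement: Gaussian-weighted centroid in a
(2⌈2σ⌉+1)² window, iterated to its fixed point — for a Gaussian spot the
iteration converges to the true centre, removing the single-pass bias toward
the detection pixel. At spot SNR 10 (peak amplitude / noise sd) and
σ = 1.2 px, the per-axis localization RMSE is ≈0.085 px, at the Cramér–Rao
limit for this model (a per-spot Gaussian least-squares fit achieves the
same). Linking is greedy nearest-neighbour under a speed gate (default
50 mm/s, optional frame gaps), with tracks shorter than 3 positions
discarded. Density maps count localized positions on a 10 µm grid; speed and
direction maps assign to every crossed pixel the track's end-to-end mean
velocity — the mean velocity of the bubble that passed through — which
suppresses localization jitter that would otherwise bias instantaneous speed
upward; direction is the sign of the mean axial velocity (toward vs away
from the probe — the artery/vein colour code). Planted speeds of 5–40 mm/s
are recovered within 5% through the full chain.

## What the generator does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
low-rank clutter, power-modulated Gaussian blood, white noise, point-like
bubbles on deterministic paths. It does not simulate acoustic propagation,
beamforming, speckle correlation, eye anatomy beyond a vessel mask, motion,
out-of-plane flow, or bubble-concentration dynamics. Passing planted-truth
tests therefore validates the pipeline's correctness and calibration under
its own model assumptions — not robustness to the physics the model omits
(notably motion artefacts and the lens's speed-of-sound aberration).

## Known limitations

* The canonical-HRF regressor is a deliberate shape mismatch to the fast
  retinal response; detection power depends on their overlap, and responses
  much faster than the presets would be missed by the mapping stage.
* The percent-change normalisation assumes the ROI's baseline power is
  dominated by blood; at very low blood-to-noise ratios the recovered
  amplitude is diluted.
* Greedy (not globally optimal) track linking can swap identities in dense
  bubble fields; simulations here use sparse bubble rates where this is
  negligible.
* Bootstrap resamples reuse the single acquisition's trials; the stability
  curves quantify within-acquisition sampling error only, not between-session
  variability.
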