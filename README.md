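# rfus — retinal functional ultrasound analysis

`rfus` implements the analysis chain for functional ultrasound (fUS) imaging
of the retina: measuring the hemodynamic response of the retinal vascular
network to brief light flashes, and comparing its parameters between animal
groups (e.g. wild-type vs transgenic Alzheimer's-model rats). It also
implements ultrasound localization microscopy (ULM) for super-resolved
density and velocity mapping of the retinal microvasculature from microbubble
movies.

Because raw acquisitions of this kind are not publicly available, the package
ships a first-class synthetic-data generator that emulates every input —
compound plane-wave movies with planted clutter, blood and response
structure, single-pixel blood-volume traces, and microbubble movies — with
complete ground-truth records, so that every stage of the analysis can be
validated by planted-truth recovery.

## The method

1. **Power Doppler via SVD clutter filtering.** Compound frames (default
   500 Hz, from 11 plane waves at 5.5 kHz PRF) are cut into blocks of 200;
   each block's Casorati matrix (pixels × frames) is decomposed by SVD and
   the 60 largest singular components — dominated by slow, high-amplitude
   tissue motion — are removed. The mean squared magnitude of the filtered
   block is one power-Doppler image (2.5 Hz), proportional to local blood
   volume.
2. **GLM activation mapping.** Each pixel's Doppler series is regressed on
   the flash boxcar convolved with the canonical double-gamma HRF, plus a
   constant and a linear trend. z / p maps follow from the per-pixel t
   statistic; the relative-blood-volume map (rRBV, %) is the stimulus
   coefficient relative to the constant term; Bonferroni correction sets the
   display threshold. A 1.4 mm circular ROI is placed on the peak z-score.
3. **Trial averaging and four-cosine HRF fitting.** The ROI trace (percent
   of baseline) is epoched around the 50 flash onsets and averaged. The mean
   trial is fitted with a piecewise model of four half-period cosines with
   six parameters — delay t0, rise time tr, amplitude A, fall time tf,
   undershoot Au, return time tb:

       h(t) = 0                                    t < t0
              A/2 · (1 − cos π(t−t0)/tr)           t0 ≤ t < t0+tr
              A/2 · (1 + cos π(t−t0−tr)/tf)        … rise → fall
              −Au/2 · (1 − cos 2π(…)/tb)           undershoot descent
              −Au/2 · (1 + cos 2π(…)/tb)           return to baseline

   fitted by bound-constrained least squares with deterministic multi-starts.
4. **Bootstrap robustness.** For subset sizes N = 5…50, trials are resampled
   with replacement (100 resamples per size), averaged and refitted; the
   spread of the fitted parameters versus N tells how many trials a stable
   estimate needs.
5. **Group comparison.** Per-animal amplitude, rise and fall times (and
   baseline blood volume) are compared between groups with the two-tailed
   Wilcoxon rank-sum test (exact for small samples), α = 0.05.
6. **ULM.** Microbubbles are detected per frame, localized to sub-pixel
   precision by an iterated Gaussian-weighted centroid, linked into tracks by
   gated nearest-neighbour assignment, and accumulated into density, mean
   speed, and flow-direction maps on a 10 µm grid.

## Worked example

Simulate a wild-type-like acquisition (21% planted response amplitude, 10%
per-sample noise), average its 50 trials, fit the four-cosine model and probe
bootstrap stability:

```python
import numpy as np
import rfus

protocol = rfus.make_protocol()         # 45 s + 50 x 30.8 s + 75 s = 1660 s
truth = rfus.GroundTruth(
    hrf_params_true=rfus.wt_hrf(),      # 21% amplitude, fraction units
    vessel_mask=np.ones((1, 1), bool),
    noise_sd=0.10, rng_seed=0)
times, traces, _ = rfus.simulate_roi_series(protocol, truth)

trace = 100.0 * (traces[0] - 1.0)       # percent of baseline
epochs = rfus.epoch_trials(trace, times, protocol)
fit = rfus.fit_hrf(epochs.time, epochs.mean, seed=0)
curve = rfus.bootstrap_stability(epochs.trials, epochs.time,
                                 sizes=[5, 15, 25, 50], n_resamples=100,
                                 seed=0)

print(f"acquisition: {protocol.total_duration:.0f} s, "
      f"{protocol.n_trials} trials, first flash at {protocol.onsets[0]:.0f} s")
print(f"epochs: {epochs.trials.shape[0]} trials x {epochs.trials.shape[1]} samples")
p = fit.params
print(f"fitted amplitude {p.amplitude:.1f}% of baseline, "
      f"rise {p.rise_time:.2f} s, fall {p.fall_time:.2f} s")
for n, sd in zip(curve.subset_sizes, curve.sd["amplitude"]):
    print(f"  N={n:2d} trials: bootstrap sd of amplitude {sd:.2f} points")
```

Output:

```
acquisition: 1660 s, 50 trials, first flash at 60 s
epochs: 50 trials x 77 samples
fitted amplitude 20.6% of baseline, rise 1.82 s, fall 4.96 s
  N= 5 trials: bootstrap sd of amplitude 2.46 points
  N=15 trials: bootstrap sd of amplitude 1.27 points
  N=25 trials: bootstrap sd of amplitude 0.97 points
  N=50 trials: bootstrap sd of amplitude 0.73 points
```

The fitted amplitude recovers the planted 21% within the trial-sampling
error, and the bootstrap spread shrinks roughly as 1/√N.

The full image pipeline (movie → Doppler → GLM → ROI → fit → group
comparison) is available programmatically via `rfus.cli.run_pipeline` and
from the shell:

```sh
rfus run-all out/                 # end-to-end synthetic WT-vs-TG experiment
rfus simulate movie.h5            # individual stages over files
rfus doppler movie.h5 doppler.h5
rfus activation doppler.h5 maps/
rfus ulm-sim --speed 20 ulm.h5
rfus ulm-map ulm.h5 ulm_maps/
```

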