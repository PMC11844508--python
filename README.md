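# tci — temporal-context-invariance analysis of neural integration windows

How long a stretch of stimulus does a neuron actually analyse at any
moment?  The *integration window* of a sensory neuron is the time window
within which stimuli can alter its response and beyond which they have
essentially no effect.  Estimating it is hard for nonlinear systems like
auditory cortex, because classical encoding models (e.g. spectrotemporal
receptive fields) assume a fixed linear stimulus–response mapping.

The temporal-context-invariance (TCI) paradigm estimates integration
windows without any assumption about the underlying features or their
mapping to the response.  Natural sounds are cut into segments of several
durations (e.g. 500 down to 15.625 ms, by recursive midpoint subdivision)
and presented in two pseudorandom orders, so each segment appears
surrounded by different "context" segments.  If a neuron's window is
shorter than a segment, there is a lag at which the window lies entirely
inside the shared segment and the response must be identical across the
two orders.

This package implements the full analysis for spiking data, plus a
synthetic model-neuron generator with known ground truth, for
neurophysiologists and methods developers who want to apply, test or
extend the approach.

## The analysis

**Cross-context correlation (CCC).**  Responses (5 ms binned spike
counts) around all segments of one duration are compiled into matrices
`M[i, τ; c, r]` (segment i, lag τ from segment onset, context c, stimulus
repetition r).  The CCC correlates responses across segments between the
two contexts, averaged over repetition pairs:

    CCC(τ) = (1/R²) Σ_{r1,r2} corr( M[:, τ; 1, r1], M[:, τ; 2, r2] )

Its attainable maximum given neural variability is the noise ceiling, the
same correlation computed across repetitions within a context:

    ceiling(τ) = (1/2) Σ_c 1/(R(R−1)) Σ_{r1≠r2} corr( M[:, τ; c, r1], M[:, τ; c, r2] )

A context-invariant response is one whose CCC reaches the ceiling at some
duration and lag.

**Model-estimated windows.**  The window is parametrized as a shifted,
scaled Gamma density with three parameters: width *w* (shortest interval
holding 75% of the mass), center *c* (the median, i.e. the
stimulus-to-window delay) and shape β (exponential-like to
Gaussian-like).  The model predicts the CCC from the overlap `s(τ)`
(window convolved with a crossfade-tapered segment boxcar) of the shared
segment versus the surrounding segments:

    P_CCC(τ) = ceiling(τ) · s_shared(τ)² / ( s_shared(τ)² + Σ_n s_n,surround(τ)² )

and the best window is found by exhaustive grid search (100 log-spaced
widths in [1/128, 0.5] s × 100 log-spaced centers up to 0.25 s × shapes
1–5, acausal combinations excluded), minimizing the squared prediction
error pooled over durations and lags.

**Rate yoking.**  Stretching/compressing the stimulus changes its
information rate; fitting windows separately per rate and forming

    index = (log2 w_stretched − log2 w_compressed) / log2(rate ratio)

grades each unit from time-yoked (0, window fixed in absolute time) to
fully rate-yoked (1, window scales with the stimulus).

## Worked example

Simulate one Poisson-spiking model neuron with a known 40 ms integration
window responding to two pseudorandom orders of 48 natural-sound sources
subdivided into 4 duration tiers (250 → 31.25 ms), then estimate its
window back from the spikes:

```python
import tci
from tci.study import simulate_binned, profiles_for_neuron

sources = [tci.SourceSound(f"s{k:02d}") for k in range(48)]
library = tci.build_segment_library(sources, top_tier=0.25, n_tiers=4)
sequences = tci.generate_sequences(library, seed=0)

window = tci.GammaWindow(0.040, tci.minimal_center(0.040, 2), 2)
neuron = tci.NeuronSpec("unit-0", window, gain=100.0, baseline_rate=5.0)
binned = simulate_binned(neuron, library, sequences, n_reps=8, sim_seed=0,
                         bin_width=0.005)
profiles = profiles_for_neuron(binned, library, sequences)
results = tci.fit_window(profiles)
print(results.summary())
```

```
Integration window fit (grid search)
============================================
width      40.21 ms  (75%-mass interval)
center     26.86 ms  (window median)
shape          2
delta       0.82 ms  (causal shift)
loss        0.3126  (SSE over 377 lag points)
--------------------------------------------
duration  250.00 ms : RMS residual  0.037 over 121 lags
duration  125.00 ms : RMS residual  0.030 over 96 lags
duration   62.50 ms : RMS residual  0.021 over 83 lags
duration   31.25 ms : RMS residual  0.018 over 77 lags
width band (loss < 2x min): 7.8-97.2 ms
```

The fitted width (40.21 ms) recovers the generative 40 ms window; the
per-duration residuals show how well the overlap-ratio model reproduces
the measured cross-context correlation, and the width band is a crude
loss-profile uncertainty interval.  `results.plot()` draws the measured
CCC, noise ceiling and model prediction per segment duration.

A command-line pipeline covers the same ground on files
(`tci study`, `tci fit`, `tci yoking`, `tci report`); see `tci --help`.

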