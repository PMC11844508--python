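# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic benchmarks do and do not establish.

## Stimulus design

Source sounds (nominal 500 ms) are subdivided recursively at their
midpoints into duration tiers `top/2^k`; every tier tiles its parent
exactly, so a segment of tier d has exactly two children of d/2 at
offsets 0 and d/2.  Presented segments carry half a crossfade ramp
(default ramp 15.625 ms) of extra material on each side: the nominal
onset of a presented segment is the **midpoint of its leading
raised-cosine crossfade**, which treats the extra material symmetrically
and makes nominal segments tile the sequence exactly.  The smallest legal
tier equals one ramp (the standard design bottoms out at 15.625 ms
segments with 15.625 ms crossfades); below that the two ramps of one
segment would overlap.

Two orders per tier (or one interleaved pair across all tiers) are drawn
from a seeded generator.  Order B is resampled (up to 1000 tries) until
no segment keeps the predecessor it had in order A, with the position
before the first segment treated as a silence sentinel; tiers with fewer
than three segments emit a warning and return a best-effort permutation.

Context pairs for a duration are all cross-order occurrence pairs of each
segment.  With embedding enabled, occurrences inside an ancestor
presentation (at the parent onset plus the segment's offset within the
parent) are included; a pair with exactly one embedded occurrence
compares a *natural* context against a *random* one.  Pairs where both
occurrences are embedded are excluded — both then sit in their original
surroundings and the two contexts do not differ.

## Synthetic neurons

Each model neuron is a linear–nonlinear–Poisson cascade.  The stimulus is
represented by a latent feature trace per segment: a sustained
segment-specific Gaussian level (75% of variance) plus Gaussian noise
low-passed at ~50 Hz (25%), standardized over the segment ensemble,
deterministic given (segment id, feature seed).  The sustained/modulated
split matters: responses to natural sound segments are dominated by
segment-specific evoked levels, and the overlap-ratio CCC prediction
(below) is derived for exactly this generative structure — each segment
contributing one stochastic amplitude weighted by its window overlap.
With purely fast-varying features, a segment's contribution variance
scales with the overlap of the *squared* window instead, and the
prediction would be systematically biased sharp; the mixture keeps
within-segment dynamics for realism while satisfying the model's
assumption to within ~0.01 correlation units.

Sequences are rendered by crossfade-weighting segment traces with the
same raised-cosine used for the sound.  Each contribution is computed on
a segment-local grid and placed at the onset snapped to the simulation
grid (dt = 2^-10 s ≈ 0.98 ms, chosen so all dyadic durations and the
ramp are integer sample counts).  Every occurrence of a segment therefore
injects bit-identical values, preserving the ground truth the CCC must
detect: at lags where the window lies inside the segment, the noiseless
response is identical across orders up to the Gamma tail mass (~1e-6 of
the response for a 30 ms window 200 ms deep into a segment).

The drive is the convolution of the rendered trace with the neuron's
effective window — the generative window for time-yoked neurons, width
and center multiplied by the rate factor for rate-yoked neurons.  Rate
factor ρ time-scales the feature content (the trace at rate ρ is the
natural trace evaluated at t/ρ), emulating pitch-preserving stretching
or compression of the sound.  Firing rate = baseline + gain ×
nonlinearity(drive); the default nonlinearity is half-wave rectification,
so that pipeline benchmarks exercise a nonlinear system; spikes are
per-bin Poisson with an independent seeded substream per repetition.
Negative rates (possible only under the identity nonlinearity) are
counted and clipped before Poisson sampling; the noiseless path returns
the unclipped linear readout so that the identity limit is exact.

## Response pipeline

Spikes are counted in 5 ms bins for estimation (10 ms is available for
smoother plots).  Unit screening follows the split-half convention:
Pearson correlation between odd- and even-repetition mean timecourses
concatenated across sequences, thresholded at 0.1 (0.05 for sparse
non-primary data), with significance (p < 1e-5) from a permutation test
that shuffles contiguous 100 ms blocks of one half (1000 permutations)
and fits a Gaussian to the null so that very small p-values remain
measurable.  The choice to permute one half against the other (rather
than permuting both) is deliberate and calibrates correctly: under the
null the p-values are uniform (checked at ±0.02 over 200 runs).

Response matrices snap each occurrence onset to the nearest bin edge
(sub-bin offsets are tolerated by design); the matrix lag axis is
reported at **bin centres relative to the true onsets**, i.e. it includes
the mean sub-bin snap offset.  Without this the lag axis would be biased
by up to half a bin plus the snap offset (~5 ms combined), which visibly
distorts comparisons against model predictions at 20–30 ms transition
scales.  Cells whose lags fall outside the recording are NaN and handled
pairwise downstream.

## Cross-context correlation

Eq-level conventions: the CCC averages the raw Pearson correlations over
all R² ordered repetition pairs across contexts (including r1 = r2,
following the source definition literally); the ceiling averages over
ordered pairs r1 ≠ r2 within context, then over the two contexts.  No
Fisher transform.  Columns need ≥ 3 pairwise-complete segments; terms
with zero variance on either side are dropped from the average and
counted.  Random–random and natural–random pairs are pooled by default,
with `context_types` to split them.  Group summaries divide the median
CCC over units by the median ceiling, masking lags where the median
ceiling is below 0.05.

## Window model and fit

The window is a Gamma density with shape β ∈ {1..5} and rate β (unit
mean; the baseline), scaled by λ = w/w_d and shifted by δ = c − λ·c_d,
where (w_d, c_d) are the baseline's 75%-mass shortest-interval width and
median.  w_d is found by minimizing `ppf(F + 0.75) − ppf(F)` over the
lower tail probability F (2001-point scan plus bounded refinement), so
the returned interval's mass is exact; for β = 1 this reproduces the
closed forms w_d = ln 4, c_d = ln 2.  Windows with δ < 0 are acausal;
the fit excludes grid points with δ < −dt/2.

Discretized windows are computed from CDF differences (bin-averaged
density) rather than pointwise pdf samples: at 1 ms grids the narrowest
grid width (1/128 s) would otherwise mis-normalize by ~10%; the
bin-averaged form sums to the enclosed mass by construction (normalized
to 1e-4 or better) and is delay-unbiased (tap k carries the mass of the
bin centred on k·dt).

Overlaps convolve the window with a segment boxcar whose edges are
tapered by raised-cosine ramps of 7.8125 ms **centred on the nominal
boundaries**, so adjacent tiled boxcars form an exact partition of
unity.  The predicted CCC multiplies the measured noise ceiling by
`s_shared²/(s_shared² + Σ s_surround²)` with surrounds laid out as
adjacent same-duration tiles covering the window support (the ratio is 0
where every overlap vanishes).  All overlap computations run on a fine
2^-10 s grid, where dyadic durations shift by integer sample counts.

The fit is an exhaustive grid search (defaults: 100 log-spaced widths in
[1/128, 0.5] s; 100 log-spaced centers from 1 ms — the nominal lower
bound of 0 cannot be log-spaced — to 0.25 s; shapes 1–5) minimizing
unweighted squared error pooled over durations and defined lags; lags
with undefined CCC or ceiling are skipped, and a ceiling-weighted loss is
available as an option.  Ties break toward smaller width, then center,
then shape.  The fit's internal prediction and `predict_ccc` share one
code path, so a profile generated from a grid-point window is recovered
exactly with numerically zero loss.  `IntegrationWindowResults` carries
the estimates, the full loss grid (from which a crude loss-profile width
band is derived), per-duration predicted curves, `summary()` and
`plot()`.

## Rate yoking

The index divides the octave difference between stretched- and
compressed-sound windows by the octave difference a fully rate-yoked
window would show, i.e. by log2 of the **information-rate ratio between
the two conditions compared**.  The classic "factor 2" description (one
octave of rate difference, denominator 1) maps onto `factor=2`; synthetic
experiments that stretch to ρ = 2 and compress to ρ = 0.5 compare
conditions a factor 4 apart and pass `factor=4`, under which a simulated
fully rate-yoked population recovers a mean index of 1 and a time-yoked
population 0.  Split-half reliability computes per-unit indices and
rate-averaged log widths on odd/even repetition splits, Spearman
rank-correlates each across units between splits, and derives two-sided
p-values from ≥ 1000 seeded unit-level bootstrap resamples
(null-centred on the observed correlation).

## Synthetic studies and problem sizes

The default desk-scale study uses 8 source sounds, 5 tiers
(500 → 31.25 ms), 8 repetitions and 20 neurons in two groups
(primary-like widths 15–60 ms, non-primary-like 40–150 ms, log-uniform),
gains 60–140 spikes/s per unit drive and baselines 2–10 spikes/s —
plausible multi-unit rates.  Benchmarks that need tight statistics use
48 sources with tiers 250 → 31.25 ms (48–384 segments per tier), chosen
so every tier carries enough segments for stable correlations while a
full pipeline run stays in the minutes range on one CPU.  Neuron centers
default to the minimal causal center for their width, matching the
empirical finding that integration begins about as early as the window
permits.

## What the synthetic benchmarks do and do not show

Passing recovery benchmarks shows the pipeline is internally consistent:
the statistics are implemented correctly, the prediction equation matches
its generative model, windows are recovered within grid-plus-noise
tolerance (median |log2 error| ≤ 0.35 octaves across 16–128 ms widths
under Poisson noise), and yoking classification separates its two poles.
The generator does not emulate adaptation, arousal or attentional state,
learning across repetitions, spike-sorting artifacts, correlated noise
across units, or responses whose feature selectivity changes with
context; real recordings may also violate the sustained-dominant feature
assumption for some units, in which case fitted widths reflect an
effective (somewhat sharper) window.  Absolute agreement with any
particular recorded dataset is therefore not claimed.

## Known limitations

* The grid fit reports the loss-grid argmin; no continuous refinement or
  formal confidence intervals (the width band is a crude loss-profile
  heuristic).
* The noise ceiling treats any across-repetition change as noise; slow
  nonstationarities depress it.
* Sub-bin onset jitter after snapping (< 2.5 ms) slightly smears CCC
  transitions for tiers whose durations are not multiples of the bin
  width; the effect is ~1–2% for the narrowest windows.
* `segment_feature_trace` supports rate factors ≥ 0.5 out of the box
  (base support is sized for one octave of compression).
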