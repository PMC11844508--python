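"""Model neurons with known integration windows.

Each synthetic neuron is a linear-nonlinear-Poisson cascade whose linear
stage is a causal Gamma window (see `tci.window`).  The stimulus is
emulated by a latent *feature trace* per segment: a seeded, smoothed
(low-pass, ~50 Hz at the natural rate) zero-mean unit-variance signal that
stands in for whatever acoustic feature drives the cell.  Traces of
distinct segments are independent; consecutive segments in a sequence are
mixed with the same raised-cosine crossfade weights as the sound, so
context leakage at segment boundaries matches the experiment.

Stimulus rate manipulations (stretching/compression) time-scale the
feature traces: at rate factor ``rho`` the trace of a segment is the
``rho``-times slowed copy of its natural-rate trace.  A *time-yoked*
neuron keeps the same window at every rate; a *rate-yoked* neuron scales
its window width and center with the rate factor.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import SegmentLibrary, SequenceSpec, DEFAULT_RAMP
from .window import GammaWindow

__all__ = [
    "NeuronSpec",
    "FeatureTrace",
    "segment_feature_trace",
    "render_sequence_features",
    "effective_window",
    "simulate_response",
    "SimulatedResponse",
]

#: simulation time step, seconds.  2^-10 s (~0.98 ms) resolves windows down
#: to ~15 ms before responses are downsampled to the 5 ms analysis bins,
#: and makes every dyadic segment duration and the crossfade ramp an exact
#: number of samples, so segment onsets always fall on the grid.
SIM_DT = 2.0 ** -10

#: -3 dB cutoff of the feature low-pass at rate factor 1 (Hz).
FEATURE_CUTOFF_HZ = 50.0

#: fraction of feature variance carried by the sustained (segment-level)
#: component; the remainder is within-segment modulation.  Responses to
#: natural sound segments are dominated by segment-specific evoked levels,
#: which is also the generative assumption behind the overlap-ratio CCC
#: prediction (each segment contributes one stochastic amplitude weighted
#: by its window overlap).
SUSTAINED_FRACTION = 0.75


@dataclass(frozen=True)
class NeuronSpec:
    """Generative description of one model neuron."""

    neuron_id: str
    window: GammaWindow
    yoking: str = "time_yoked"          # or "rate_yoked"
    nonlinearity: str = "rectify"       # identity | rectify | exponential
    gain: float = 100.0                 # spikes/s per unit drive
    baseline_rate: float = 5.0          # spikes/s
    feature_seed: int = 0

    def __post_init__(self) -> None:
        if self.gain < 0 or self.baseline_rate < 0:
            raise ValueError("gain and baseline_rate must be nonnegative")
        if not self.window.causal:
            raise ValueError("generative window must be causal")
        if self.yoking not in ("time_yoked", "rate_yoked"):
            raise ValueError(f"unknown yoking {self.yoking!r}")
        if self.nonlinearity not in ("identity", "rectify", "exponential"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass
class FeatureTrace:
    """Latent stimulus drive on a uniform time grid."""

    times: np.ndarray
    values: np.ndarray
    dt: float


def _segment_stream_seed(segment_id: str, feature_seed: int) -> list[int]:
    return [int(feature_seed) & 0x7FFFFFFF, zlib.crc32(segment_id.encode()) & 0x7FFFFFFF]


def segment_feature_trace(segment_id: str, duration: float,
                          rate_factor: float = 1.0, feature_seed: int = 0,
                          dt: float = SIM_DT,
                          pad: float = DEFAULT_RAMP) -> FeatureTrace:
    """Deterministic latent feature trace for one segment.

    The trace is defined on [-pad, duration + pad] (the pad covers the
    crossfade material on either side of the nominal segment).  The
    natural-rate (rate_factor 1) trace mixes a sustained segment-specific
    level with Gaussian noise low-passed at ~50 Hz (variance split
    ``SUSTAINED_FRACTION`` : 1 - ``SUSTAINED_FRACTION``), standardized to
    zero mean and unit variance over the segment ensemble.  At rate factor
    ``rho`` the returned values are the natural trace evaluated at
    ``t / rho`` (same content, different speed), so compressing a
    stretched trace recovers the original.
    """
    if dt > 1e-3 + 1e-12:
        raise ValueError("feature traces need dt <= 1 ms")
    if rate_factor <= 0:
        raise ValueError("rate_factor must be positive")
    # base (natural-rate) support wide enough for any rate factor >= 0.5
    rho_min = min(rate_factor, 0.5)
    base_lo = (-pad - dt) / rho_min
    base_hi = (duration + pad + dt) / rho_min
    dt_b = dt / 2.0
    n_base = int(np.ceil((base_hi - base_lo) / dt_b)) + 1
    rng = np.random.default_rng(_segment_stream_seed(segment_id, feature_seed))
    level = rng.standard_normal()
    raw = rng.standard_normal(n_base)
    sigma_t = np.sqrt(np.log(2.0)) / (2.0 * np.pi * FEATURE_CUTOFF_HZ)
    smooth = ndimage.gaussian_filter1d(raw, sigma_t / dt_b, mode="wrap")
    smooth -= smooth.mean()
    smooth /= smooth.std()
    base = (np.sqrt(SUSTAINED_FRACTION) * level
            + np.sqrt(1.0 - SUSTAINED_FRACTION) * smooth)
    base_times = base_lo + np.arange(n_base) * dt_b

    times = np.arange(int(round(-pad / dt)), int(round((duration + pad) / dt)) + 1) * dt
    values = np.interp(times / rate_factor, base_times, base)
    return FeatureTrace(times=times, values=values, dt=dt)


def _crossfade_weight(t: np.ndarray, onset: float, dur: float, ramp: float) -> np.ndarray:
    """Raised-cosine presentation weight of a segment spanning
    [onset, onset + dur] nominally; transitions are centred on the nominal
    boundaries and span one full ramp."""
    half = ramp / 2.0
    w = np.zeros_like(t)
    core = (t >= onset + half) & (t <= onset + dur - half)
    w[core] = 1.0
    lead = (t > onset - half) & (t < onset + half)
    w[lead] = 0.5 * (1.0 - np.cos(np.pi * (t[lead] - onset + half) / ramp))
    trail = (t > onset + dur - half) & (t < onset + dur + half)
    w[trail] = 0.5 * (1.0 - np.cos(np.pi * (onset + dur + half - t[trail]) / ramp))
    return w


def render_sequence_features(library: SegmentLibrary, sequence: SequenceSpec,
                             rate_factor: float = 1.0, feature_seed: int = 0,
                             dt: float = SIM_DT) -> FeatureTrace:
    """Crossfade-weighted concatenation of segment traces for a sequence.

    Each segment's weighted trace is computed on a segment-local grid and
    placed at its onset snapped to the simulation grid (sub-sample onset
    quantization, well below the analysis bin width).  Every occurrence of
    a segment therefore contributes exactly the same sample values, which
    preserves the ground-truth identity of responses across orders at lags
    where the window is contained in the segment.
    """
    ramp = library.ramp_duration
    total = sequence.total_duration(library)
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    out = np.zeros(n)
    for sid, onset in sequence.entries:
        seg = library[sid]
        trace = segment_feature_trace(sid, seg.tier_duration, rate_factor,
                                      feature_seed, dt=dt, pad=ramp)
        w = _crossfade_weight(trace.times, 0.0, seg.tier_duration, ramp)
        contrib = w * trace.values
        k0 = int(round(onset / dt)) + int(round(trace.times[0] / dt))
        lo, hi = max(k0, 0), min(k0 + len(contrib), n)
        if hi > lo:
            out[lo:hi] += contrib[lo - k0: hi - k0]
    return FeatureTrace(times=t, values=out, dt=dt)


def effective_window(neuron: NeuronSpec, rate_factor: float = 1.0) -> GammaWindow:
    """The window actually applied at a given stimulus rate.

    Time-yoked neurons keep their generative window; rate-yoked neurons
    scale width and center with the rate factor (stretched sound, stretched
    window).
    """
    if neuron.yoking == "rate_yoked" and rate_factor != 1.0:
        return neuron.window.scaled(rate_factor)
    return neuron.window


_NONLINEARITIES = {
    "identity": lambda x: x,
    "rectify": lambda x: np.maximum(x, 0.0),
    "exponential": lambda x: np.exp(x) - 1.0,
}


@dataclass
class SimulatedResponse:
    """Output of one neuron x sequence simulation."""

    neuron_id: str
    sequence_id: str
    times: np.ndarray
    rate: np.ndarray              # spikes/s, after clipping
    dt: float
    spikes: pd.DataFrame | None   # columns: neuron_id, sequence_id, repetition, spike_time_s
    n_clipped: int = 0


def simulate_response(neuron: NeuronSpec, sequence: SequenceSpec,
                      library: SegmentLibrary, rate_factor: float = 1.0,
                      n_reps: int = 1, noise: str = "poisson",
                      sim_seed: int = 0, dt: float = SIM_DT) -> SimulatedResponse:
    """Simulate a neuron's response to one presented sequence.

    drive(t) = (h * f)(t) with h the effective window and f the rendered
    feature trace; rate(t) = baseline + gain * nonlinearity(drive); spikes
    are per-bin Poisson with an independent substream per repetition.
    Negative rates (possible only with the identity nonlinearity) are
    counted and clipped at zero before Poisson sampling; the noiseless path
    reports the unclipped linear readout.
    """
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    feats = render_sequence_features(library, sequence, rate_factor,
                                     neuron.feature_seed, dt=dt)
    h = effective_window(neuron, rate_factor).kernel(dt)
    drive = np.convolve(feats.values, h)[: len(feats.values)]
    rate = neuron.baseline_rate + neuron.gain * _NONLINEARITIES[neuron.nonlinearity](drive)
    n_clipped = int(np.sum(rate < 0))
    if noise == "poisson":
        rate = np.maximum(rate, 0.0)

    spikes = None
    if noise == "poisson":
        rows = []
        for rep in range(1, n_reps + 1):
            rng = np.random.default_rng(
                [int(sim_seed) & 0x7FFFFFFF,
                 zlib.crc32(f"{neuron.neuron_id}|{sequence.sequence_id}".encode())
                 & 0x7FFFFFFF, rep])
            counts = rng.poisson(rate * dt)
            lefts = np.repeat(feats.times, counts)
            t_spk = lefts + rng.random(lefts.size) * dt
            rows.append(pd.DataFrame({
                "neuron_id": neuron.neuron_id,
                "sequence_id": sequence.sequence_id,
                "repetition": rep,
                "spike_time_s": np.sort(t_spk),
            }))
        spikes = (pd.concat(rows, ignore_index=True) if rows else
                  pd.DataFrame(columns=["neuron_id", "sequence_id",
                                        "repetition", "spike_time_s"]))
    return SimulatedResponse(neuron_id=neuron.neuron_id,
                             sequence_id=sequence.sequence_id,
                             times=feats.times, rate=rate, dt=dt,
                             spikes=spikes, n_clipped=n_clipped)
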