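"""End-to-end synthetic studies with known ground truth.

`generate_study` builds a complete synthetic experiment — segment library,
two pseudorandom orders per duration tier, a population of model neurons
with known integration windows, and their spiking responses — so that the
whole pipeline (screening, cross-context correlation, window fitting,
rate yoking) can be exercised and scored against ground truth without any
recorded data.  Population defaults mimic the structure of the real
experiments: a primary-like group with short windows and a non-primary-like
group with longer ones, dyadic segment tiers subdivided from 500 ms
sources, two orders, eight repetitions.

`analyze_study` runs the pipeline on a generated study and returns
per-neuron window fits; `score_recovery` compares them with the ground
truth on an octave scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ccc as ccc_mod
from .design import (SegmentLibrary, SequenceSpec, SourceSound,
                     build_segment_library, enumerate_context_pairs,
                     generate_sequences)
from .neuron import NeuronSpec, simulate_response
from .responses import (BinnedResponse, bin_rates, bin_spikes,
                        build_response_matrix, reliability_screen)
from .window import GammaWindow, WindowGrid, fit_window, minimal_center

__all__ = [
    "GroupSpec",
    "StudySpec",
    "StudyData",
    "generate_study",
    "simulate_binned",
    "profiles_for_neuron",
    "analyze_study",
    "score_recovery",
]


@dataclass(frozen=True)
class GroupSpec:
    """One neuron group: widths drawn log-uniformly from ``width_range``."""

    name: str
    n_neurons: int
    width_range: tuple[float, float]      # seconds
    yoking: str = "time_yoked"
    nonlinearity: str = "rectify"


@dataclass(frozen=True)
class StudySpec:
    """Generative description of a synthetic experiment.

    Defaults are a desk-scale version of the recordings: 8 source sounds,
    5 duration tiers (500 down to 31.25 ms), 8 repetitions, 20 neurons in
    a short-window (primary-like, 15-60 ms) and a long-window
    (non-primary-like, 40-150 ms) group.
    """

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("MEG-like", 10, (0.015, 0.060)),
        GroupSpec("PEG-like", 10, (0.040, 0.150)),
    )
    n_sources: int = 8
    top_tier: float = 0.5
    n_tiers: int = 5
    n_reps: int = 8
    rate_factors: tuple[float, ...] = (1.0,)
    gain_range: tuple[float, float] = (60.0, 140.0)
    baseline_range: tuple[float, float] = (2.0, 10.0)
    shapes: tuple[int, ...] = (1, 2, 3, 4, 5)
    master_seed: int = 0
    bin_width: float = 0.005
    mode: str = "per_duration"

    @property
    def n_neurons(self) -> int:
        return sum(g.n_neurons for g in self.groups)


@dataclass
class StudyData:
    """A generated study: stimuli, neurons, spikes and ground truth."""

    spec: StudySpec
    library: SegmentLibrary
    sequences: list[SequenceSpec]
    neurons: list[NeuronSpec]
    truth: pd.DataFrame
    spikes: pd.DataFrame   # neuron_id, rate_factor, sequence_id, repetition, spike_time_s


def _draw_neurons(spec: StudySpec) -> tuple[list[NeuronSpec], pd.DataFrame]:
    rng = np.random.default_rng([spec.master_seed & 0x7FFFFFFF, 11])
    neurons, rows = [], []
    for g in spec.groups:
        lo, hi = np.log(g.width_range[0]), np.log(g.width_range[1])
        for j in range(g.n_neurons):
            width = float(np.exp(rng.uniform(lo, hi)))
            shape = int(rng.choice(spec.shapes))
            center = minimal_center(width, shape)
            gain = float(rng.uniform(*spec.gain_range))
            baseline = float(rng.uniform(*spec.baseline_range))
            nid = f"{g.name}-{j:02d}"
            neurons.append(NeuronSpec(
                neuron_id=nid, window=GammaWindow(width, center, shape),
                yoking=g.yoking, nonlinearity=g.nonlinearity, gain=gain,
                baseline_rate=baseline,
                feature_seed=spec.master_seed & 0x7FFFFFFF))
            rows.append({"neuron_id": nid, "group": g.name,
                         "width": width, "center": center, "shape": shape,
                         "yoking": g.yoking, "gain": gain,
                         "baseline_rate": baseline})
    return neurons, pd.DataFrame(rows)


def generate_study(spec: StudySpec) -> StudyData:
    """Generate a full synthetic experiment, deterministic in master_seed."""
    sources = [SourceSound(f"src{k:02d}") for k in range(spec.n_sources)]
    library = build_segment_library(sources, top_tier=spec.top_tier,
                                    n_tiers=spec.n_tiers)
    sequences = generate_sequences(library, mode=spec.mode,
                                   seed=(spec.master_seed & 0x7FFFFFFF) + 1,
                                   n_repetitions=spec.n_reps)
    neurons, truth = _draw_neurons(spec)
    frames = []
    for neuron in neurons:
        for rho in spec.rate_factors:
            for seq in sequences:
                sim = simulate_response(neuron, seq, library, rate_factor=rho,
                                        n_reps=spec.n_reps, noise="poisson",
                                        sim_seed=(spec.master_seed & 0x7FFFFFFF) + 7)
                df = sim.spikes.copy()
                df.insert(1, "rate_factor", rho)
                frames.append(df)
    spikes = pd.concat(frames, ignore_index=True)
    return StudyData(spec=spec, library=library, sequences=sequences,
                     neurons=neurons, truth=truth, spikes=spikes)


def simulate_binned(neuron: NeuronSpec, library: SegmentLibrary,
                    sequences: list[SequenceSpec], rate_factor: float = 1.0,
                    n_reps: int = 8, noise: str = "poisson", sim_seed: int = 0,
                    bin_width: float = 0.005,
                    reps: tuple[int, ...] | None = None) -> list[BinnedResponse]:
    """Simulate and bin one neuron's responses to a set of sequences.

    With ``noise='none'`` the binned values are expected counts from the
    noiseless rate, duplicated over ``reps`` (default a single repetition).
    """
    out = []
    for seq in sequences:
        t_end = seq.total_duration(library)
        if noise == "none":
            sim = simulate_response(neuron, seq, library, rate_factor,
                                    n_reps=0, noise="none", sim_seed=sim_seed)
            for rep in reps or (1,):
                b = bin_rates(sim.times, sim.rate, bin_width, t_end=t_end,
                              neuron_id=neuron.neuron_id,
                              sequence_id=seq.sequence_id, repetition=rep)
                out.append(b)
        else:
            sim = simulate_response(neuron, seq, library, rate_factor,
                                    n_reps=n_reps, noise="poisson",
                                    sim_seed=sim_seed)
            for rep, grp in sim.spikes.groupby("repetition"):
                out.append(bin_spikes(grp["spike_time_s"].to_numpy(), bin_width,
                                      t_end, neuron_id=neuron.neuron_id,
                                      sequence_id=seq.sequence_id,
                                      repetition=int(rep)))
    return out


def profiles_for_neuron(binned: list[BinnedResponse], library: SegmentLibrary,
                        sequences: list[SequenceSpec],
                        durations: list[float] | None = None,
                        include_embedded: bool = False,
                        context_types: tuple[str, ...] | None = None,
                        lag_range=None) -> list[ccc_mod.CCCProfile]:
    """CCC profiles for every requested duration tier of one neuron."""
    durations = durations or library.tiers
    neuron_id = binned[0].neuron_id if binned else ""
    profiles = []
    for dur in durations:
        pairs = enumerate_context_pairs(library, sequences, dur,
                                        include_embedded=include_embedded)
        mset = build_response_matrix(binned, pairs, dur, lag_range=lag_range)
        profiles.append(ccc_mod.compute_profile(mset, neuron_id=neuron_id,
                                                context_types=context_types))
    return profiles


def analyze_study(study: StudyData, grid: WindowGrid | None = None,
                  threshold: float = 0.1, alpha: float = 1e-5,
                  durations: list[float] | None = None,
                  include_embedded: bool = False,
                  screen: bool = True) -> pd.DataFrame:
    """Screen, correlate and fit every neuron (and rate factor) of a study.

    Returns one row per (neuron, rate_factor) with the screen outcome and,
    for retained units, the fitted window parameters and loss.
    """
    spec = study.spec
    rows = []
    for neuron in study.neurons:
        for rho in spec.rate_factors:
            sel = study.spikes[(study.spikes["neuron_id"] == neuron.neuron_id)
                               & (study.spikes["rate_factor"] == rho)]
            binned = []
            for seq in study.sequences:
                t_end = seq.total_duration(study.library)
                seq_spk = sel[sel["sequence_id"] == seq.sequence_id]
                for rep in range(1, spec.n_reps + 1):
                    spk = seq_spk[seq_spk["repetition"] == rep]["spike_time_s"]
                    binned.append(bin_spikes(spk.to_numpy(), spec.bin_width,
                                             t_end, neuron_id=neuron.neuron_id,
                                             sequence_id=seq.sequence_id,
                                             repetition=rep))
            row = {"neuron_id": neuron.neuron_id, "rate_factor": rho}
            if screen:
                res = reliability_screen(binned, threshold=threshold,
                                         alpha=alpha,
                                         seed=spec.master_seed & 0x7FFFFFFF)
                row.update(reliability=res.reliability, p_value=res.p_value,
                           passed=res.passed)
                if not res.passed:
                    row.update(width=np.nan, center=np.nan, shape=-1,
                               loss=np.nan)
                    rows.append(row)
                    continue
            profiles = profiles_for_neuron(binned, study.library,
                                           study.sequences,
                                           durations=durations,
                                           include_embedded=include_embedded)
            fit = fit_window(profiles, grid=grid)
            row.update(width=fit.width, center=fit.center, shape=fit.shape,
                       loss=fit.loss)
            rows.append(row)
    return pd.DataFrame(rows)


def score_recovery(fits: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron signed width-recovery errors, log2(estimate / truth).

    Neurons without a fit (screened out or failed) are kept with NaN error
    and ``fitted = False`` rather than silently dropped.
    """
    merged = fits.merge(truth[["neuron_id", "width", "yoking", "group"]],
                        on="neuron_id", suffixes=("_est", "_true"))
    merged["fitted"] = np.isfinite(merged["width_est"])
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["log2_error"] = np.log2(merged["width_est"] / merged["width_true"])
    return merged


def recovery_summary(scored: pd.DataFrame) -> dict:
    """Median and IQR of |log2 error| over fitted neurons."""
    err = scored.loc[scored["fitted"], "log2_error"].abs()
    return {"n_fitted": int(scored["fitted"].sum()),
            "n_total": int(len(scored)),
            "median_abs_log2_error": float(err.median()),
            "iqr_abs_log2_error": float(err.quantile(0.75) - err.quantile(0.25))}
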