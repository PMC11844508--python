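"""Cross-context correlation and noise ceiling."""

import numpy as np
import pytest

import tci
from tci.ccc import (compute_profile, cross_context_correlation,
                     group_normalized_ccc, noise_ceiling)
from tci.responses import ResponseMatrixSet, build_response_matrix
from tci.study import profiles_for_neuron, simulate_binned


def _noiseless_mset(library, sequences, neuron, duration, reps=(1,)):
    binned = simulate_binned(neuron, library, sequences, noise="none",
                             reps=reps)
    pairs = tci.enumerate_context_pairs(library, sequences, duration)
    return build_response_matrix(binned, pairs, duration)


class TestCrossContext:
    def test_label_swap_symmetry(self, dyadic_library, dyadic_sequences,
                                 noiseless_neuron):
        mset = _noiseless_mset(dyadic_library, dyadic_sequences,
                               noiseless_neuron, 0.25)
        ccc, _ = cross_context_correlation(mset)
        swapped = ResponseMatrixSet(duration=mset.duration, lags=mset.lags,
                                    M=mset.M[:, :, ::-1, :], pairs=mset.pairs,
                                    bin_width=mset.bin_width,
                                    repetitions=mset.repetitions)
        ccc_swapped, _ = cross_context_correlation(swapped)
        assert np.allclose(ccc, ccc_swapped, equal_nan=True)

    def test_affine_rescaling_invariance(self, dyadic_library,
                                         dyadic_sequences, noiseless_neuron):
        mset = _noiseless_mset(dyadic_library, dyadic_sequences,
                               noiseless_neuron, 0.25)
        ccc, _ = cross_context_correlation(mset)
        scaled = ResponseMatrixSet(duration=mset.duration, lags=mset.lags,
                                   M=3.7 * mset.M + 11.0, pairs=mset.pairs,
                                   bin_width=mset.bin_width,
                                   repetitions=mset.repetitions)
        ccc_scaled, _ = cross_context_correlation(scaled)
        assert np.allclose(ccc, ccc_scaled, equal_nan=True)

    def test_noiseless_ceiling_is_one(self, dyadic_library, dyadic_sequences,
                                      noiseless_neuron):
        mset = _noiseless_mset(dyadic_library, dyadic_sequences,
                               noiseless_neuron, 0.25, reps=(1, 2))
        ceil = noise_ceiling(mset)
        ok = np.isfinite(ceil)
        assert ok.any()
        assert np.allclose(ceil[ok], 1.0, atol=1e-10)

    def test_pure_noise_neuron_ceiling_near_zero(self, dyadic_library,
                                                 dyadic_sequences):
        window = tci.GammaWindow(0.03, tci.minimal_center(0.03, 2), 2)
        neuron = tci.NeuronSpec("noise", window, gain=0.0, baseline_rate=30.0)
        binned = simulate_binned(neuron, dyadic_library, dyadic_sequences,
                                 n_reps=8, sim_seed=0)
        pairs = tci.enumerate_context_pairs(dyadic_library, dyadic_sequences,
                                            0.125)
        mset = build_response_matrix(binned, pairs, 0.125)
        ceil = noise_ceiling(mset)
        ok = np.isfinite(ceil)
        assert np.abs(np.nanmean(ceil[ok])) < 2 / np.sqrt(mset.n_segments)

    def test_two_reps_equal_single_unordered_pair(self, dyadic_library,
                                                  dyadic_sequences):
        window = tci.GammaWindow(0.03, tci.minimal_center(0.03, 2), 2)
        neuron = tci.NeuronSpec("r2", window, gain=80.0, baseline_rate=5.0)
        binned = simulate_binned(neuron, dyadic_library, dyadic_sequences,
                                 n_reps=2, sim_seed=1)
        pairs = tci.enumerate_context_pairs(dyadic_library, dyadic_sequences,
                                            0.25)
        mset = build_response_matrix(binned, pairs, 0.25)
        ceil = noise_ceiling(mset)
        k = len(mset.lags) // 2
        manual = []
        for c in (0, 1):
            X = mset.M[:, k, c, :]
            rows = np.isfinite(X).all(axis=1)
            manual.append(np.corrcoef(X[rows, 0], X[rows, 1])[0, 1])
        assert ceil[k] == pytest.approx(np.mean(manual))

    def test_ccc_below_ceiling_overall(self, dyadic_library, dyadic_sequences):
        """CCC may not systematically exceed the noise ceiling."""
        window = tci.GammaWindow(0.05, tci.minimal_center(0.05, 2), 2)
        neuron = tci.NeuronSpec("b0", window, gain=80.0, baseline_rate=5.0)
        binned = simulate_binned(neuron, dyadic_library, dyadic_sequences,
                                 n_reps=8, sim_seed=2)
        profs = profiles_for_neuron(binned, dyadic_library, dyadic_sequences)
        for p in profs:
            ok = np.isfinite(p.ccc) & np.isfinite(p.ceiling)
            excess = p.ccc[ok] - p.ceiling[ok]
            assert np.mean(excess) < 0.02
            assert np.max(excess) < 0.3


class TestGroupSummary:
    def test_noiseless_group_tracks_unity_until_offset(self, dyadic_library):
        seqs = tci.generate_sequences(dyadic_library, seed=21)
        profiles = []
        for j in range(3):
            window = tci.GammaWindow(0.03, tci.minimal_center(0.03, 2), 2)
            neuron = tci.NeuronSpec(f"g{j}", window, nonlinearity="identity",
                                    gain=1.0, baseline_rate=0.0,
                                    feature_seed=j)
            binned = simulate_binned(neuron, dyadic_library, seqs,
                                     noise="none", reps=(1, 2))
            profiles.extend(profiles_for_neuron(binned, dyadic_library, seqs,
                                                durations=[0.25]))
        out = group_normalized_ccc(profiles)
        curve = out[0.25]["normalized"]
        lags = out[0.25]["lags"]
        inside = (lags > 0.15) & (lags < 0.22)
        assert np.nanmin(curve[inside]) > 0.98

    def test_single_unit_group_reduces_to_ratio(self, dyadic_library,
                                                dyadic_sequences):
        window = tci.GammaWindow(0.04, tci.minimal_center(0.04, 2), 2)
        neuron = tci.NeuronSpec("solo", window, gain=80.0, baseline_rate=5.0)
        binned = simulate_binned(neuron, dyadic_library, dyadic_sequences,
                                 n_reps=4, sim_seed=3)
        profs = profiles_for_neuron(binned, dyadic_library, dyadic_sequences,
                                    durations=[0.125])
        out = group_normalized_ccc(profs)
        p = profs[0]
        expected = np.where(p.ceiling >= 0.05, p.ccc / p.ceiling, np.nan)
        assert np.allclose(out[0.125]["normalized"], expected, equal_nan=True)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_normalized_ccc([])

    def test_short_window_group_reaches_ceiling_long_window_plateaus(self):
        """At 62.5 ms segments, 30 ms windows reach the ceiling while 100 ms
        windows plateau well below it (overlap-ratio model prediction)."""
        sources = [tci.SourceSound(f"s{k:02d}") for k in range(8)]
        lib = tci.build_segment_library(sources, top_tier=0.5, n_tiers=4)
        seqs = tci.generate_sequences(lib, seed=22)
        duration = 0.0625
        curves = {}
        for name, w in (("short", 0.03), ("long", 0.100)):
            profiles = []
            for j in range(2):
                window = tci.GammaWindow(w, tci.minimal_center(w, 2), 2)
                neuron = tci.NeuronSpec(f"{name}{j}", window,
                                        nonlinearity="identity", gain=1.0,
                                        baseline_rate=0.0, feature_seed=40 + j)
                binned = simulate_binned(neuron, lib, seqs,
                                         noise="none", reps=(1, 2))
                profiles.extend(profiles_for_neuron(binned, lib, seqs,
                                                    durations=[duration]))
            out = group_normalized_ccc(profiles)
            curves[name] = (out[duration]["lags"], out[duration]["normalized"])
        lags, short = curves["short"]
        _, long_ = curves["long"]
        assert np.nanmax(short) > 0.98
        assert np.nanmax(long_) < 0.85
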