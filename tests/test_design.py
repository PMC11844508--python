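"""Segment hierarchy, sequence orders and context-pair enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tci
from tci.design import InvalidDesignError


class TestSegmentLibrary:
    def test_standard_experiment_tiers_and_counts(self):
        sources = [tci.SourceSound(f"s{k}") for k in range(24)]
        lib = tci.build_segment_library(sources, top_tier=0.5, n_tiers=6)
        assert np.allclose(lib.tiers,
                           [0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625])
        counts = [len(lib.segments_at(t)) for t in lib.tiers]
        assert counts == [24, 48, 96, 192, 384, 768]

    def test_single_source_single_tier(self):
        lib = tci.build_segment_library([tci.SourceSound("a")], top_tier=0.5,
                                        n_tiers=1)
        assert len(lib.segments) == 1
        assert lib.children(lib.segments[0].segment_id) == []

    def test_small_hierarchy_tiling(self, small_library):
        lib = small_library
        assert len(lib.segments) == 14
        for tier, n in zip(lib.tiers, (2, 4, 8)):
            assert len(lib.segments_at(tier)) == n
        for parent in lib.segments_at(0.4):
            kids = lib.children(parent.segment_id)
            offs = sorted(k.onset_in_source - parent.onset_in_source for k in kids)
            assert offs == pytest.approx([0.0, 0.2])
        for parent in lib.segments_at(0.2):
            kids = lib.children(parent.segment_id)
            offs = sorted(k.onset_in_source - parent.onset_in_source for k in kids)
            assert offs == pytest.approx([0.0, 0.1])

    def test_children_tile_parent_exactly(self, dyadic_library):
        lib = dyadic_library
        for seg in lib.segments:
            kids = lib.children(seg.segment_id)
            if kids:
                assert sum(k.tier_duration for k in kids) == pytest.approx(
                    seg.tier_duration)

    def test_tier_shorter_than_two_ramps_rejected(self):
        with pytest.raises(InvalidDesignError):
            tci.build_segment_library([tci.SourceSound("a")], top_tier=0.05,
                                      n_tiers=3)

    def test_json_round_trip(self, small_library, tmp_path):
        p = tmp_path / "lib.json"
        small_library.to_json(p)
        lib2 = tci.SegmentLibrary.from_json(p)
        assert lib2.tiers == small_library.tiers
        assert [s.segment_id for s in lib2.segments] == \
            [s.segment_id for s in small_library.segments]


class TestSequences:
    def test_each_segment_once_per_order(self, small_library):
        seqs = tci.generate_sequences(small_library, mode="per_duration", seed=7)
        by_label = {}
        for s in seqs:
            by_label.setdefault(s.order_label, []).extend(s.segment_ids)
        all_ids = {s.segment_id for s in small_library.segments}
        assert set(by_label["A"]) == all_ids == set(by_label["B"])
        assert len(by_label["A"]) == len(all_ids)

    def test_no_shared_predecessor_bigrams(self, dyadic_library):
        seqs = tci.generate_sequences(dyadic_library, mode="interleaved", seed=7)
        a = next(s for s in seqs if s.order_label == "A").segment_ids
        b = next(s for s in seqs if s.order_label == "B").segment_ids
        preds_a = {sid: (a[i - 1] if i else None) for i, sid in enumerate(a)}
        preds_b = {sid: (b[i - 1] if i else None) for i, sid in enumerate(b)}
        shared = [sid for sid in preds_a if preds_a[sid] == preds_b[sid]]
        assert shared == []

    def test_same_seed_identical(self, small_library):
        s1 = tci.generate_sequences(small_library, seed=5)
        s2 = tci.generate_sequences(small_library, seed=5)
        assert [(q.sequence_id, q.entries) for q in s1] == \
            [(q.sequence_id, q.entries) for q in s2]

    def test_two_segment_tier_warns_but_returns_permutations(self):
        lib = tci.build_segment_library([tci.SourceSound("a"),
                                         tci.SourceSound("b")],
                                        top_tier=0.5, n_tiers=1)
        with pytest.warns(UserWarning, match="predecessor"):
            seqs = tci.generate_sequences(lib, mode="per_duration", seed=0)
        for s in seqs:
            assert sorted(s.segment_ids) == sorted(x.segment_id
                                                   for x in lib.segments)

    def test_onsets_tile_with_crossfade_overlap(self, dyadic_library):
        lib = dyadic_library
        seqs = tci.generate_sequences(lib, mode="per_duration", seed=1)
        for s in seqs:
            onsets = [o for _, o in s.entries]
            assert all(b > a for a, b in zip(onsets, onsets[1:]))
            for (sid, o1), (_, o2) in zip(s.entries, s.entries[1:]):
                assert o2 - o1 == pytest.approx(lib[sid].tier_duration)
            # final offset = sum of presented durations - overlaps
            expected = sum(lib[sid].presented_duration
                           for sid in s.segment_ids) \
                - (len(s.entries) - 1) * lib.ramp_duration
            assert s.total_duration(lib) == pytest.approx(expected)
            last_id, last_onset = s.entries[-1]
            end = last_onset + lib[last_id].tier_duration + lib.ramp_duration / 2
            assert end == pytest.approx(expected)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(n_sources=st.integers(3, 10), n_tiers=st.integers(1, 3),
           seed=st.integers(0, 10_000))
    def test_sequence_invariants_property(self, n_sources, n_tiers, seed):
        sources = [tci.SourceSound(f"s{k}") for k in range(n_sources)]
        lib = tci.build_segment_library(sources, top_tier=0.4, n_tiers=n_tiers)
        seqs = tci.generate_sequences(lib, mode="interleaved", seed=seed)
        assert len(seqs) == 2
        for s in seqs:
            assert sorted(s.segment_ids) == sorted(x.segment_id
                                                   for x in lib.segments)
            onsets = np.array([o for _, o in s.entries])
            assert (np.diff(onsets) > 0).all()


class TestContextPairs:
    def test_one_random_pair_per_segment_without_embedding(self, dyadic_library,
                                                           dyadic_sequences):
        pairs = tci.enumerate_context_pairs(dyadic_library, dyadic_sequences,
                                            0.25, include_embedded=False)
        assert len(pairs) == 16
        assert all(p.context_type == "random_random" for p in pairs)
        assert len({p.segment_id for p in pairs}) == 16

    def test_embedded_occurrences_tagged_natural(self, dyadic_library,
                                                 dyadic_sequences):
        pairs = tci.enumerate_context_pairs(dyadic_library, dyadic_sequences,
                                            0.25, include_embedded=True)
        natural = [p for p in pairs if p.context_type == "natural_random"]
        # each 250 ms segment: direct A x embedded B and embedded A x direct B
        assert len(natural) == 2 * 16
        for p in natural:
            assert p.occurrence_1.embedded != p.occurrence_2.embedded
            emb = p.occurrence_1 if p.occurrence_1.embedded else p.occurrence_2
            seg = dyadic_library[p.segment_id]
            host = dyadic_library[emb.host_id]
            offset = seg.onset_in_source - host.onset_in_source
            seqs = {s.sequence_id: s for s in dyadic_sequences}
            assert emb.onset == pytest.approx(
                seqs[emb.sequence_id].onset_of(host.segment_id) + offset)

    def test_double_embedded_pairs_excluded(self, dyadic_library,
                                            dyadic_sequences):
        pairs = tci.enumerate_context_pairs(dyadic_library, dyadic_sequences,
                                            0.125, include_embedded=True)
        for p in pairs:
            assert not (p.occurrence_1.embedded and p.occurrence_2.embedded)

    def test_unknown_duration_rejected(self, dyadic_library, dyadic_sequences):
        with pytest.raises(InvalidDesignError):
            tci.enumerate_context_pairs(dyadic_library, dyadic_sequences, 0.3)
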