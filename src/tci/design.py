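"""Segment hierarchies, pseudorandom sequence orders and context pairs.

The stimulus design behind the temporal-context-invariance analysis: source
sounds (nominally 500 ms) are recursively subdivided at their midpoints
into tiers of segments (500, 250, ..., 15.625 ms), every tier tiling its
parent exactly.  The segments of each tier are presented in two
pseudorandom orders so that each segment is surrounded by different
"context" segments in the two orders; consecutive segments are joined with
a raised-cosine crossfade (15.625 ms), and each presented segment carries
half the crossfade of extra material on each side, so a segment's nominal
onset is the midpoint of its leading ramp.

Because shorter segments live inside longer ones, a segment can occur
either directly (random context) or embedded inside an ancestor at its
original offset (natural context); `enumerate_context_pairs` lists the
usable cross-order pairs of occurrences of every segment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "SourceSound",
    "Segment",
    "SegmentLibrary",
    "SequenceSpec",
    "Occurrence",
    "ContextPair",
    "InvalidDesignError",
    "build_segment_library",
    "generate_sequences",
    "enumerate_context_pairs",
]

DEFAULT_RAMP = 0.015625

Category = Literal["speech", "ferret_vocalization", "music", "other"]


class InvalidDesignError(ValueError):
    """Raised when a stimulus design violates its structural constraints."""


@dataclass(frozen=True)
class SourceSound:
    """A source recording from which segments are excerpted."""

    sound_id: str
    category: str = "other"
    nominal_duration: float = 0.5
    rate_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.nominal_duration <= 0:
            raise InvalidDesignError("nominal_duration must be positive")
        if self.rate_factor <= 0:
            raise InvalidDesignError("rate_factor must be positive")


@dataclass(frozen=True)
class Segment:
    """One excerpt of a source at a given tier.

    ``onset_in_source`` is an integer multiple of ``tier_duration``;
    ``presented_duration`` includes the crossfade ramp (tier + ramp, half a
    ramp of extra material on each side of the nominal segment).
    """

    segment_id: str
    source_id: str
    tier_duration: float
    onset_in_source: float
    parent_id: str | None
    presented_duration: float


@dataclass
class SegmentLibrary:
    """The full segment hierarchy for one experiment."""

    sources: list[SourceSound]
    segments: list[Segment]
    tiers: list[float]          # descending durations, seconds
    ramp_duration: float = DEFAULT_RAMP

    def __post_init__(self) -> None:
        self._by_id = {s.segment_id: s for s in self.segments}
        self._children: dict[str, list[str]] = {}
        for s in self.segments:
            if s.parent_id is not None:
                self._children.setdefault(s.parent_id, []).append(s.segment_id)

    def __getitem__(self, segment_id: str) -> Segment:
        return self._by_id[segment_id]

    def segments_at(self, tier: float) -> list[Segment]:
        """All segments of one duration tier, in source order."""
        tier = self._match_tier(tier)
        return [s for s in self.segments if s.tier_duration == tier]

    def children(self, segment_id: str) -> list[Segment]:
        return [self._by_id[c] for c in self._children.get(segment_id, [])]

    def ancestors(self, segment_id: str) -> list[tuple[Segment, float]]:
        """Ancestor segments of ``segment_id`` with the offset of the
        segment inside each ancestor."""
        seg = self._by_id[segment_id]
        out = []
        cur = seg
        while cur.parent_id is not None:
            parent = self._by_id[cur.parent_id]
            out.append((parent, seg.onset_in_source - parent.onset_in_source))
            cur = parent
        return out

    def _match_tier(self, duration: float) -> float:
        for t in self.tiers:
            if abs(t - duration) < 1e-9:
                return t
        raise InvalidDesignError(f"{duration} s is not a tier of this library")

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "ramp_duration": self.ramp_duration,
            "tiers": self.tiers,
            "sources": [asdict(s) for s in self.sources],
            "segments": [asdict(s) for s in self.segments],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SegmentLibrary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(sources=[SourceSound(**s) for s in d["sources"]],
                   segments=[Segment(**s) for s in d["segments"]],
                   tiers=list(d["tiers"]), ramp_duration=d["ramp_duration"])


@dataclass
class SequenceSpec:
    """One presented ordering of segments.

    ``entries`` are (segment_id, onset) with onsets at the nominal segment
    start (midpoint of the leading crossfade ramp); presented material for
    an entry spans [onset - ramp/2, onset + tier + ramp/2], so consecutive
    presented segments overlap by exactly one ramp.
    """

    sequence_id: str
    order_label: str                     # "A" or "B"
    entries: list[tuple[str, float]]
    mode: str = "per_duration"           # or "interleaved"
    n_repetitions: int = 8
    seed: int = 0
    ramp_duration: float = DEFAULT_RAMP

    @property
    def segment_ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    def onset_of(self, segment_id: str) -> float:
        for sid, onset in self.entries:
            if sid == segment_id:
                return onset
        raise KeyError(segment_id)

    def total_duration(self, library: SegmentLibrary) -> float:
        """Span of presented material: sum of presented durations minus the
        crossfade overlaps."""
        pres = sum(library[sid].presented_duration for sid in self.segment_ids)
        return pres - (len(self.entries) - 1) * self.ramp_duration

    def to_json(self, path) -> None:
        payload = {
            "sequence_id": self.sequence_id,
            "order_label": self.order_label,
            "mode": self.mode,
            "n_repetitions": self.n_repetitions,
            "seed": self.seed,
            "ramp": self.ramp_duration,
            # onsets at microsecond precision to avoid binning drift
            "entries": [{"segment_id": sid, "onset": round(onset, 6)}
                        for sid, onset in self.entries],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SequenceSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(sequence_id=d["sequence_id"], order_label=d["order_label"],
                   entries=[(e["segment_id"], e["onset"]) for e in d["entries"]],
                   mode=d["mode"], n_repetitions=d["n_repetitions"],
                   seed=d["seed"], ramp_duration=d["ramp"])


@dataclass(frozen=True)
class Occurrence:
    """One occurrence of a segment within a presented sequence."""

    sequence_id: str
    onset: float
    embedded: bool = False
    host_id: str | None = None   # the directly presented segment carrying it


@dataclass(frozen=True)
class ContextPair:
    """Two occurrences of the same segment under different contexts."""

    segment_id: str
    duration: float
    occurrence_1: Occurrence     # order A
    occurrence_2: Occurrence     # order B
    context_type: str            # "random_random" or "natural_random"


def build_segment_library(sources: Sequence[SourceSound], top_tier: float = 0.5,
                          n_tiers: int = 6,
                          ramp: float = DEFAULT_RAMP) -> SegmentLibrary:
    """Build the tier hierarchy by recursive midpoint subdivision.

    Tier k holds segments of duration ``top_tier / 2**k``; each segment of
    tier k has exactly two children of half its duration at offsets 0 and
    d/2 within it.  The smallest tier must be at least one ramp long (the
    standard design bottoms out at segments equal to the 15.625 ms
    crossfade); below that the leading and trailing ramps of a presented
    segment would overlap.
    """
    tiers = [top_tier / 2 ** k for k in range(n_tiers)]
    if tiers[-1] < ramp - 1e-12:
        raise InvalidDesignError(
            f"smallest tier {tiers[-1] * 1e3:.3f} ms is shorter than the "
            f"crossfade ramp ({ramp * 1e3:.3f} ms)")
    segments: list[Segment] = []

    def seg_id(source_id: str, dur: float, onset: float) -> str:
        return f"{source_id}|{dur * 1e3:g}ms|{onset * 1e3:g}"

    for src in sources:
        def subdivide(dur: float, onset: float, parent: str | None) -> None:
            sid = seg_id(src.sound_id, dur, onset)
            segments.append(Segment(segment_id=sid, source_id=src.sound_id,
                                    tier_duration=dur, onset_in_source=onset,
                                    parent_id=parent,
                                    presented_duration=dur + ramp))
            if dur / 2 >= tiers[-1] - 1e-12:
                subdivide(dur / 2, onset, sid)
                subdivide(dur / 2, onset + dur / 2, sid)

        subdivide(top_tier, 0.0, None)
    return SegmentLibrary(sources=list(sources), segments=segments,
                          tiers=tiers, ramp_duration=ramp)


def _order_with_new_predecessors(ids: list[str], reference: list[str],
                                 rng: np.random.Generator,
                                 max_tries: int = 1000) -> list[str]:
    """Seeded permutation in which no segment keeps its reference
    predecessor (silence before the first segment counts as a
    predecessor)."""

    def predecessors(order: list[str]) -> dict[str, str | None]:
        return {sid: (order[i - 1] if i else None) for i, sid in enumerate(order)}

    ref = predecessors(reference)
    if len(ids) < 3:
        warnings.warn(
            f"tier with {len(ids)} segment(s): predecessor diversity cannot "
            "be guaranteed; returning best-effort permutation", stacklevel=3)
    best: list[str] | None = None
    best_shared = np.inf
    for _ in range(max_tries):
        cand = [ids[i] for i in rng.permutation(len(ids))]
        shared = sum(p == ref[sid] for sid, p in predecessors(cand).items())
        if shared == 0:
            return cand
        if shared < best_shared:
            best, best_shared = cand, shared
    warnings.warn("could not fully diversify predecessors after "
                  f"{max_tries} tries ({best_shared} shared)", stacklevel=3)
    return best  # type: ignore[return-value]


def _assign_onsets(library: SegmentLibrary, order: list[str]) -> list[tuple[str, float]]:
    onset = library.ramp_duration / 2
    entries = []
    for sid in order:
        entries.append((sid, onset))
        onset += library[sid].tier_duration
    return entries


def generate_sequences(library: SegmentLibrary,
                       mode: str = "per_duration", seed: int = 0,
                       n_repetitions: int = 8,
                       joint_categories: bool = True) -> list[SequenceSpec]:
    """Two pseudorandom presentation orders (A and B) of the library.

    ``per_duration``: a separate pair of sequences per tier, each holding
    every segment of that tier exactly once.  ``interleaved``: one pair of
    sequences holding every segment of every tier, durations and categories
    block-shuffled jointly (``joint_categories`` is a documentation flag:
    categories are always rerandomized jointly with durations).
    """
    if not library.segments:
        raise InvalidDesignError("empty segment library")
    rng = np.random.default_rng(seed)
    groups: list[tuple[str, list[str]]]
    if mode == "per_duration":
        groups = [(f"d{t * 1e3:g}ms", [s.segment_id for s in library.segments_at(t)])
                  for t in library.tiers]
    elif mode == "interleaved":
        groups = [("interleaved", [s.segment_id for s in library.segments])]
    else:
        raise InvalidDesignError(f"unknown mode {mode!r}")

    out = []
    for name, ids in groups:
        order_a = [ids[i] for i in rng.permutation(len(ids))]
        order_b = _order_with_new_predecessors(ids, order_a, rng)
        for label, order in (("A", order_a), ("B", order_b)):
            out.append(SequenceSpec(
                sequence_id=f"{name}-{label}", order_label=label,
                entries=_assign_onsets(library, order), mode=mode,
                n_repetitions=n_repetitions, seed=seed,
                ramp_duration=library.ramp_duration))
    return out


def _occurrences(library: SegmentLibrary, sequences: list[SequenceSpec],
                 segment: Segment, include_embedded: bool) -> list[Occurrence]:
    occ = []
    for seq in sequences:
        for sid, onset in seq.entries:
            if sid == segment.segment_id:
                occ.append(Occurrence(seq.sequence_id, onset, embedded=False,
                                      host_id=sid))
    if include_embedded:
        for ancestor, offset in library.ancestors(segment.segment_id):
            for seq in sequences:
                for sid, onset in seq.entries:
                    if sid == ancestor.segment_id:
                        occ.append(Occurrence(seq.sequence_id, onset + offset,
                                              embedded=True, host_id=sid))
    return occ


def enumerate_context_pairs(library: SegmentLibrary,
                            sequences: Sequence[SequenceSpec],
                            duration: float,
                            include_embedded: bool = False) -> list[ContextPair]:
    """All usable cross-order occurrence pairs for segments of one tier.

    Direct-vs-direct pairs have two random contexts; pairs with exactly one
    embedded occurrence compare a natural context (the segment inside its
    ancestor, at its original offset) against a random one.  Pairs in which
    both occurrences are embedded are excluded: both then sit in their
    original surroundings, so the two contexts are not distinct.
    """
    tier = library._match_tier(duration)
    by_label: dict[str, list[SequenceSpec]] = {"A": [], "B": []}
    for seq in sequences:
        by_label.setdefault(seq.order_label, []).append(seq)
    if not by_label["A"] or not by_label["B"]:
        raise InvalidDesignError("need sequences for both orders A and B")

    pairs = []
    for segment in library.segments_at(tier):
        occ_a = _occurrences(library, by_label["A"], segment, include_embedded)
        occ_b = _occurrences(library, by_label["B"], segment, include_embedded)
        for oa in occ_a:
            for ob in occ_b:
                if oa.embedded and ob.embedded:
                    continue
                ctype = ("natural_random" if (oa.embedded or ob.embedded)
                         else "random_random")
                pairs.append(ContextPair(segment_id=segment.segment_id,
                                         duration=tier, occurrence_1=oa,
                                         occurrence_2=ob, context_type=ctype))
    return pairs
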