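"""Mutation operators and the per-replication mutagenesis schedule.

Seven event types act on the circular genome:

* local events — *point* mutations flip one base; *small insertions* and
  *small deletions* add or remove 1-6 bases at a uniform position;
* chromosomal rearrangements — *duplications* and *large deletions* copy
  or remove the segment between two uniformly drawn breakpoints;
  *translocations* excise such a segment and reinsert it elsewhere
  (inverted with probability 1/2); *inversions* replace the segment in
  place by its reverse complement.

Per replication, the number of events of each type is binomial in the
*parent* genome length (so rearrangement pressure scales with genome
size, non-coding sequence included).  Rearrangements are applied first in
a random interleaved order, then local events, with positions drawn on
the current (possibly already edited) genome.  Every event is logged as a
typed record whose replay on the pre-event genome reproduces the
post-event genome bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import TextIO

import numpy as np

from .genome import Genome

__all__ = [
    "MutationRates",
    "MutationEvent",
    "PointMutation",
    "SmallInsertion",
    "SmallDeletion",
    "Duplication",
    "LargeDeletion",
    "Translocation",
    "Inversion",
    "apply_local",
    "apply_rearrangement",
    "replicate_genome",
    "replay",
    "write_event_log",
]

#: Hard genome-length ceiling guarding runaway duplication (bp).
DEFAULT_LENGTH_CEILING = 1_000_000


@dataclass(frozen=True)
class MutationRates:
    """Per-bp per-generation event rates."""

    point: float = 1e-6
    small_insertion: float = 1e-6
    small_deletion: float = 1e-6
    inversion: float = 1e-5
    translocation: float = 1e-5
    large_duplication: float = 1e-5
    large_deletion: float = 1e-5

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate {f.name} must be >= 0")

    @classmethod
    def wildtype(cls) -> "MutationRates":
        """Mild regime: 1e-6 for local events, 1e-5 for rearrangements."""
        return cls()

    @classmethod
    def mutator(cls) -> "MutationRates":
        """Point rate raised 100-fold (1e-4); all other rates unchanged."""
        return cls(point=1e-4)

    def with_point_rate(self, point: float) -> "MutationRates":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["point"] = point
        return MutationRates(**d)

    @staticmethod
    def zero() -> "MutationRates":
        return MutationRates(0, 0, 0, 0, 0, 0, 0)


# ---------------------------------------------------------------------------
# event records


def _circ_delete(arr: np.ndarray, start: int, length: int) -> np.ndarray:
    """Remove the circular segment [start, start+length) (0 < length < L).

    Non-wrapping cuts keep the origin; wrapping cuts re-linearize from
    the first retained base.
    """
    L = arr.size
    s = start % L
    e = s + length
    if e <= L:
        return np.concatenate([arr[:s], arr[e:]])
    return arr[e - L : s]


def _circ_extract(arr: np.ndarray, start: int, length: int) -> np.ndarray:
    idx = (start + np.arange(length)) % arr.size
    return arr[idx]


@dataclass(frozen=True)
class MutationEvent:
    """Base class: a typed, replayable record of one mutational event."""

    kind = "abstract"
    rejected: bool = field(default=False, kw_only=True)

    @property
    def length_delta(self) -> int:
        return 0

    def apply(self, g: Genome) -> Genome:
        if self.rejected:
            return g
        return Genome(self._apply(g.seq))

    def _apply(self, arr: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class PointMutation(MutationEvent):
    kind = "point"
    pos: int = 0

    def _apply(self, arr):
        out = arr.copy()
        out[self.pos % arr.size] ^= 1
        return out


@dataclass(frozen=True)
class SmallInsertion(MutationEvent):
    kind = "small_insertion"
    pos: int = 0
    payload: tuple[int, ...] = ()

    @property
    def length_delta(self) -> int:
        return 0 if self.rejected else len(self.payload)

    def _apply(self, arr):
        p = self.pos % arr.size
        ins = np.asarray(self.payload, dtype=np.uint8)
        return np.concatenate([arr[:p], ins, arr[p:]])


@dataclass(frozen=True)
class SmallDeletion(MutationEvent):
    kind = "small_deletion"
    pos: int = 0
    length: int = 0

    @property
    def length_delta(self) -> int:
        return 0 if self.rejected else -self.length

    def _apply(self, arr):
        return _circ_delete(arr, self.pos, self.length)


@dataclass(frozen=True)
class Duplication(MutationEvent):
    """Copy the segment [b1, b1+seg_len) before position ``insert_at``."""

    kind = "duplication"
    b1: int = 0
    seg_len: int = 0
    insert_at: int = 0

    @property
    def length_delta(self) -> int:
        return 0 if self.rejected else self.seg_len

    def _apply(self, arr):
        if self.seg_len == 0:
            return arr.copy()
        seg = _circ_extract(arr, self.b1, self.seg_len)
        p = self.insert_at % arr.size
        return np.concatenate([arr[:p], seg, arr[p:]])


@dataclass(frozen=True)
class LargeDeletion(MutationEvent):
    kind = "large_deletion"
    b1: int = 0
    seg_len: int = 0

    @property
    def length_delta(self) -> int:
        return 0 if self.rejected else -self.seg_len

    def _apply(self, arr):
        if self.seg_len == 0:
            return arr.copy()
        return _circ_delete(arr, self.b1, self.seg_len)


@dataclass(frozen=True)
class Translocation(MutationEvent):
    kind = "translocation"
    b1: int = 0
    seg_len: int = 0
    insert_at: int = 0      # index into the post-excision sequence
    inverted: bool = False

    def _apply(self, arr):
        if self.seg_len == 0:
            return arr.copy()
        seg = _circ_extract(arr, self.b1, self.seg_len)
        if self.inverted:
            seg = (1 - seg[::-1]).astype(np.uint8)
        rem = _circ_delete(arr, self.b1, self.seg_len)
        p = self.insert_at % rem.size if rem.size else 0
        return np.concatenate([rem[:p], seg, rem[p:]])


@dataclass(frozen=True)
class Inversion(MutationEvent):
    kind = "inversion"
    b1: int = 0
    seg_len: int = 0

    def _apply(self, arr):
        if self.seg_len == 0:
            return arr.copy()
        idx = (self.b1 + np.arange(self.seg_len)) % arr.size
        out = arr.copy()
        out[idx] = (1 - arr[idx][::-1]).astype(np.uint8)
        return out


# ---------------------------------------------------------------------------
# drawing events


def _draw_local(arr: np.ndarray, kind: str, rng: np.random.Generator) -> MutationEvent:
    L = arr.size
    if kind == "point":
        return PointMutation(pos=int(rng.integers(L)))
    if kind == "small_insertion":
        ln = int(rng.integers(1, 7))
        payload = tuple(int(b) for b in rng.integers(0, 2, size=ln))
        return SmallInsertion(pos=int(rng.integers(L)), payload=payload)
    if kind == "small_deletion":
        pos = int(rng.integers(L))
        ln = int(rng.integers(1, 7))
        ev = SmallDeletion(pos=pos, length=ln)
        if ln >= L:  # would empty the genome -> rejected, flagged
            return SmallDeletion(pos=pos, length=ln, rejected=True)
        return ev
    raise ValueError(f"unknown local mutation kind {kind!r}")


def _draw_rearrangement(
    arr: np.ndarray, kind: str, rng: np.random.Generator, length_ceiling: int
) -> MutationEvent:
    L = arr.size
    b1 = int(rng.integers(L))
    b2 = int(rng.integers(L))
    s = (b2 - b1) % L  # arc from first to second breakpoint, expected L/2
    if kind == "duplication":
        p = int(rng.integers(L))
        return Duplication(b1=b1, seg_len=s, insert_at=p,
                           rejected=L + s > length_ceiling)
    if kind == "large_deletion":
        return LargeDeletion(b1=b1, seg_len=s)
    if kind == "translocation":
        if s == 0:
            return Translocation(b1=b1, seg_len=0, insert_at=0, inverted=False)
        p = int(rng.integers(L - s))
        inv = bool(rng.random() < 0.5)
        return Translocation(b1=b1, seg_len=s, insert_at=p, inverted=inv)
    if kind == "inversion":
        return Inversion(b1=b1, seg_len=s)
    raise ValueError(f"unknown rearrangement kind {kind!r}")


def apply_local(
    g: Genome, kind: str, rng: np.random.Generator
) -> tuple[Genome, MutationEvent]:
    """Draw and apply one local mutation (point / small InDel)."""
    ev = _draw_local(g.seq, kind, rng)
    return ev.apply(g), ev


def apply_rearrangement(
    g: Genome,
    kind: str,
    rng: np.random.Generator,
    length_ceiling: int = DEFAULT_LENGTH_CEILING,
) -> tuple[Genome, MutationEvent]:
    """Draw and apply one chromosomal rearrangement.

    The affected segment is the circular arc from the first to the second
    uniformly drawn breakpoint (expected length L/2).
    """
    if len(g) < 2:
        raise ValueError("rearrangements require L >= 2")
    ev = _draw_rearrangement(g.seq, kind, rng, length_ceiling)
    return ev.apply(g), ev


_REARR_KINDS = ("duplication", "large_deletion", "translocation", "inversion")
_LOCAL_KINDS = ("point", "small_insertion", "small_deletion")

_RATE_FIELD = {
    "duplication": "large_duplication",
    "large_deletion": "large_deletion",
    "translocation": "translocation",
    "inversion": "inversion",
    "point": "point",
    "small_insertion": "small_insertion",
    "small_deletion": "small_deletion",
}


def replicate_genome(
    g: Genome,
    rates: MutationRates,
    rng: np.random.Generator,
    length_ceiling: int = DEFAULT_LENGTH_CEILING,
) -> tuple[Genome, list[MutationEvent]]:
    """One mutagenic replication: parent genome -> child genome + event log.

    Event counts are Binomial(L_parent, rate) per type; rearrangements are
    applied first (random interleaved order), then local mutations, with
    positions drawn on the genome as it currently stands.  Sequential
    replay of the returned events on the parent reproduces the child.
    """
    L = len(g)
    schedule: list[str] = []
    for group in (_REARR_KINDS, _LOCAL_KINDS):
        kinds: list[str] = []
        for kind in group:
            n = int(rng.binomial(L, getattr(rates, _RATE_FIELD[kind])))
            kinds.extend([kind] * n)
        if len(kinds) > 1:
            kinds = [kinds[i] for i in rng.permutation(len(kinds))]
        schedule.extend(kinds)

    child = g
    events: list[MutationEvent] = []
    for kind in schedule:
        arr = child.seq
        if kind in _REARR_KINDS:
            if arr.size < 2:
                continue
            ev = _draw_rearrangement(arr, kind, rng, length_ceiling)
        else:
            ev = _draw_local(arr, kind, rng)
        child = ev.apply(child)
        events.append(ev)
    return child, events


def replay(origin: Genome, events: list[MutationEvent]) -> Genome:
    """Re-apply a logged event sequence (bit-exact reconstruction)."""
    g = origin
    for ev in events:
        g = ev.apply(g)
    return g


def write_event_log(
    handle: TextIO, rows: list[tuple[int, int, MutationEvent]]
) -> None:
    """Append (generation, individual id, event) records as TSV."""
    for gen, ind, ev in rows:
        detail = {
            k: v
            for k, v in ev.__dict__.items()
            if not k.startswith("_") and k != "rejected"
        }
        handle.write(
            f"{gen}\t{ind}\t{ev.kind}\t{detail}\t{ev.length_delta}\t{int(ev.rejected)}\n"
        )
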