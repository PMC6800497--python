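"""Circular binary genomes.

The unit of heredity is a circular double-stranded sequence over the
alphabet {0, 1}.  Only the leading strand is stored; the lagging strand is
its base-wise complement read in reverse.  All coordinates are 0-based and
interpreted modulo the genome length ``L``; segments are half-open
``[start, start + length)`` on the circle.
"""

from __future__ import annotations

from typing import Iterable, Iterator, TextIO

import numpy as np

__all__ = [
    "Genome",
    "GenomeExtinctionError",
    "reverse_complement",
    "extract_segment",
    "splice",
    "read_genomes",
    "write_genomes",
]


class GenomeExtinctionError(ValueError):
    """An edit would have produced an empty genome; replication must abort."""


def _as_bits(seq) -> np.ndarray:
    """Coerce a str/iterable/array of 0s and 1s to a uint8 array."""
    if isinstance(seq, Genome):
        return seq.seq
    if isinstance(seq, str):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(seq, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("genome sequence must be one-dimensional")
    if arr.size and arr.max() > 1:
        raise ValueError("genome sequence must contain only 0 and 1")
    return arr


class Genome:
    """Immutable circular binary sequence (leading strand).

    Parameters
    ----------
    seq
        Bits as a string (``"0101"``), an iterable of ints, or a numpy array.
    """

    __slots__ = ("_seq",)

    def __init__(self, seq) -> None:
        arr = _as_bits(seq)
        if arr.size < 1:
            raise ValueError("genome length must be >= 1")
        arr = arr.copy()
        arr.setflags(write=False)
        self._seq = arr

    @property
    def seq(self) -> np.ndarray:
        """The leading strand as a read-only uint8 array."""
        return self._seq

    def __len__(self) -> int:
        return int(self._seq.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self._seq.size == other._seq.size and bool(
            np.array_equal(self._seq, other._seq)
        )

    def __hash__(self) -> int:
        return hash(self._seq.tobytes())

    def __repr__(self) -> str:
        s = self.to_string()
        if len(s) > 60:
            s = s[:57] + "..."
        return f"Genome(L={len(self)}, seq={s!r})"

    def to_string(self) -> str:
        return "".join("01"[b] for b in self._seq)

    def tobytes(self) -> bytes:
        return self._seq.tobytes()

    def rotated(self, offset: int) -> "Genome":
        """The same circle read from a different origin."""
        off = offset % len(self)
        return Genome(np.concatenate([self._seq[off:], self._seq[:off]]))

    def lagging(self) -> np.ndarray:
        """The lagging strand: base-wise complement of the circle, reversed.

        Lagging-strand position ``i`` corresponds to leading-strand
        position ``L - 1 - i``.
        """
        return (1 - self._seq[::-1]).astype(np.uint8)


def reverse_complement(segment) -> np.ndarray:
    """Complement (0 <-> 1) a segment and reverse it.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    arr = _as_bits(segment)
    if arr.size == 0:
        raise ValueError("cannot reverse-complement an empty segment")
    return (1 - arr[::-1]).astype(np.uint8)


def extract_segment(g: Genome | np.ndarray, start: int, length: int) -> np.ndarray:
    """Circular substring of ``length`` bases beginning at ``start``."""
    arr = g.seq if isinstance(g, Genome) else np.asarray(g, dtype=np.uint8)
    L = arr.size
    if not 1 <= length <= L:
        raise ValueError(f"segment length must be in [1, {L}], got {length}")
    idx = (start + np.arange(length)) % L
    return arr[idx].astype(np.uint8)


def splice(
    g: Genome,
    delete_start: int = 0,
    delete_len: int = 0,
    insert_at: int | None = None,
    insert_seq=(),
) -> Genome:
    """Delete a circular segment and/or insert a sequence.

    The deletion ``[delete_start, delete_start + delete_len)`` is applied
    first.  For a non-wrapping deletion the origin is preserved and
    positions past the cut shift left; a wrapping deletion removes the
    origin, and the result is re-linearized from the first retained base.
    ``insert_at`` then indexes the post-deletion sequence (the inserted
    bases appear immediately before it).  A deletion may never empty the
    genome.
    """
    arr = g.seq
    L = arr.size
    if delete_len < 0:
        raise ValueError("delete_len must be >= 0")
    if delete_len >= L and delete_len > 0:
        raise GenomeExtinctionError(
            f"deleting {delete_len} bp of a {L} bp genome would empty it"
        )
    if delete_len > 0:
        s = delete_start % L
        e = s + delete_len
        if e <= L:
            new = np.concatenate([arr[:s], arr[e:]])
        else:  # wraps past the origin
            new = arr[e - L : s]
    else:
        new = arr
    ins = _as_bits(insert_seq)
    if ins.size:
        if insert_at is None:
            insert_at = 0
        p = insert_at % new.size if new.size else 0
        new = np.concatenate([new[:p], ins, new[p:]])
    if new.size == 0:
        raise GenomeExtinctionError("splice produced an empty genome")
    return Genome(new)


# ---------------------------------------------------------------------------
# FASTA-like serialization (alphabet {0,1})


def write_genomes(handle: TextIO, records: Iterable[tuple[str, Genome]], width: int = 80) -> None:
    """Write ``(header, genome)`` records as FASTA-like text."""
    for header, genome in records:
        handle.write(f">{header}\n")
        s = genome.to_string()
        for i in range(0, len(s), width):
            handle.write(s[i : i + width] + "\n")


def read_genomes(handle: TextIO) -> Iterator[tuple[str, Genome]]:
    """Parse FASTA-like binary-genome records."""
    header: str | None = None
    chunks: list[str] = []
    for line in handle:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, Genome("".join(chunks))
            header = line[1:]
            chunks = []
        else:
            chunks.append(line)
    if header is not None:
        yield header, Genome("".join(chunks))
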