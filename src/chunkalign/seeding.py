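"""Seed patterns and the reference seed index.

The default seeding scheme is the pigeonhole partition: a read aligned with
at most k substitutions is split into k+1 disjoint contiguous segments, so at
least one segment must match the reference exactly. That segment is found by
exact lookup in a hash index over all reference windows. Spaced ('1'/'0')
masks in the style of RMAP are accepted as an opt-in alternative; they do not
carry the pigeonhole full-sensitivity guarantee.

Bisulfite key spaces: in C->T space every C (in both the reference window and
the read) is rewritten to T before the key is formed, so that unmethylated-C
conversions never break a seed; G->A space mirrors this for reads whose
reverse complement is being matched.
"""

from __future__ import annotations

import logging
import threading
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ParameterError
from .io_formats import ReferenceSeq

__all__ = [
    "SeedPattern",
    "SeedIndex",
    "IndexCache",
    "pigeonhole_patterns",
    "spaced_pattern",
    "seed_key",
    "build_index",
    "lookup",
    "KEYSPACES",
]

logger = logging.getLogger(__name__)

KEYSPACES = ("plain", "bisulfite_ct", "bisulfite_ga")
_CT = str.maketrans("C", "T")
_GA = str.maketrans("G", "A")


def rewrite_keyspace(seq: str, keyspace: str) -> str:
    if keyspace == "plain":
        return seq
    if keyspace == "bisulfite_ct":
        return seq.translate(_CT)
    if keyspace == "bisulfite_ga":
        return seq.translate(_GA)
    raise ParameterError(f"unknown keyspace {keyspace!r}")


@dataclass(frozen=True)
class SeedPattern:
    """A care/don't-care mask applied to a read starting at ``offset``.

    ``mask`` is a tuple of booleans (True = care). The seed key is the
    concatenation of the bases under the care positions.
    """

    offset: int
    mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ParameterError("pattern offset must be >= 0")
        if self.weight < 1:
            raise ParameterError("pattern must have at least one care position")

    @property
    def span(self) -> int:
        return len(self.mask)

    @property
    def weight(self) -> int:
        return sum(self.mask)

    @property
    def contiguous(self) -> bool:
        return all(self.mask)

    @property
    def shape(self) -> tuple[bool, ...]:
        """Identity of the window shape, ignoring the read offset."""
        return self.mask


def pigeonhole_patterns(read_len: int, k: int) -> list[SeedPattern]:
    """k+1 contiguous all-care seeds of span floor(read_len/(k+1)) tiling a
    prefix of the read.

    Any placement of the read with <= k substitutions (and no N under a
    seed) matches at least one of these seeds exactly.
    """
    if k < 0:
        raise ParameterError("k must be >= 0")
    if read_len < k + 1:
        raise ParameterError(
            f"read length {read_len} too short for k={k} (need >= {k + 1})")
    span = read_len // (k + 1)
    mask = (True,) * span
    return [SeedPattern(offset=i * span, mask=mask) for i in range(k + 1)]


def spaced_pattern(mask_text: str, offset: int = 0) -> SeedPattern:
    """Build a pattern from a '1'/'0' string ('1' = care position)."""
    if not mask_text:
        raise ParameterError("empty seed mask")
    if set(mask_text) - {"0", "1"}:
        raise ParameterError(f"seed mask {mask_text!r} must be '0'/'1' only")
    if "1" not in mask_text:
        raise ParameterError("seed mask must contain at least one '1'")
    return SeedPattern(offset=offset, mask=tuple(c == "1" for c in mask_text))


def seed_key(seq: str, pattern: SeedPattern, at: int) -> Optional[str]:
    """Extract the seed key of ``pattern`` anchored at position ``at``.

    Returns None ("unusable") when any care position holds N. The caller is
    responsible for any keyspace rewrite (apply it to ``seq`` first).
    """
    if at < 0 or at + pattern.span > len(seq):
        raise ParameterError(
            f"seed window [{at}, {at + pattern.span}) out of range for "
            f"sequence of length {len(seq)}")
    if pattern.contiguous:
        key = seq[at:at + pattern.span]
    else:
        window = seq[at:at + pattern.span]
        key = "".join(b for b, care in zip(window, pattern.mask) if care)
    return None if "N" in key else key


@dataclass
class SeedIndex:
    """Exact-match index: seed key -> list of (reference name, 0-based
    window start) over the forward reference, for one window shape and one
    keyspace. Windows with N under a care position are never indexed."""

    shape: tuple[bool, ...]
    keyspace: str
    table: dict[str, list[tuple[str, int]]]

    @property
    def span(self) -> int:
        return len(self.shape)

    def lookup(self, key: str) -> list[tuple[str, int]]:
        return self.table.get(key, [])

    @property
    def n_windows(self) -> int:
        return sum(len(v) for v in self.table.values())


def build_index(refs: Sequence[ReferenceSeq], pattern: SeedPattern,
                keyspace: str = "plain") -> SeedIndex:
    """Index every usable window of every reference under ``pattern``'s
    shape (the pattern's read offset is irrelevant on the reference side).

    Positions are appended in (reference order, position) order, so the
    index is deterministic for a given input.
    """
    if not refs:
        raise ParameterError("empty reference set")
    if keyspace not in KEYSPACES:
        raise ParameterError(f"unknown keyspace {keyspace!r}")
    span = pattern.span
    table: dict[str, list[tuple[str, int]]] = {}
    for ref in refs:
        seq = rewrite_keyspace(ref.seq, keyspace)
        if pattern.contiguous:
            # fast path: plain substring keys
            for p in range(len(seq) - span + 1):
                key = seq[p:p + span]
                if "N" in key:
                    continue
                table.setdefault(key, []).append((ref.name, p))
        else:
            care = [i for i, c in enumerate(pattern.mask) if c]
            for p in range(len(seq) - span + 1):
                key = "".join(seq[p + i] for i in care)
                if "N" in key:
                    continue
                table.setdefault(key, []).append((ref.name, p))
    return SeedIndex(shape=pattern.shape, keyspace=keyspace, table=table)


def lookup(index: SeedIndex, key: str) -> list[tuple[str, int]]:
    """Occurrence list for ``key``; an absent key yields an empty list."""
    return index.lookup(key)


class IndexCache:
    """Lazily built, thread-safe cache of seed indexes over one reference
    set, keyed by (window shape, keyspace).

    Reads of different lengths use pigeonhole seeds of different spans, so
    one mapping run may need several indexes; each is built once and shared
    read-only across worker chunks.
    """

    def __init__(self, refs: Sequence[ReferenceSeq]):
        if not refs:
            raise ParameterError("empty reference set")
        self.refs = list(refs)
        self._indexes: dict[tuple[tuple[bool, ...], str], SeedIndex] = {}
        self._lock = threading.Lock()

    def get(self, pattern: SeedPattern, keyspace: str = "plain") -> SeedIndex:
        key = (pattern.shape, keyspace)
        with self._lock:
            idx = self._indexes.get(key)
            if idx is None:
                idx = build_index(self.refs, pattern, keyspace)
                self._indexes[key] = idx
            return idx
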