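"""Independent brute-force alignment oracle used by the test suite.

Exhaustive Hamming scan over every placement of the read on both strands of
every reference, vectorised with numpy — deliberately sharing no code path
with the seed-and-extend implementation under test.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from chunkalign.io_formats import Read, ReferenceSeq, revcomp

_N = ord("N")
_C = ord("C")
_T = ord("T")
_G = ord("G")
_A = ord("A")


def _enc(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def brute_force_hits(read: Read, refs: Sequence[ReferenceSeq], k: int,
                     mode: str = "plain",
                     qual_cutoff: Optional[int] = None
                     ) -> list[tuple[str, int, str, int]]:
    """Every (ref_name, start, strand, mismatches) with mismatches <= k."""
    L = len(read.seq)
    out = []
    for ref in refs:
        if ref.length < L:
            continue
        windows = sliding_window_view(_enc(ref.seq), L)
        for strand in ("+", "-"):
            oriented = read.seq if strand == "+" else revcomp(read.seq)
            r = _enc(oriented)
            qual = read.qual
            if qual is not None and strand == "-":
                qual = qual[::-1]
            bad = (windows == _N) | (r == _N)
            if qual_cutoff is not None and qual is not None:
                phred = _enc(qual).astype(np.int32) - 33
                bad = bad | (phred < qual_cutoff)
            if mode == "plain":
                diff = windows != r
            elif mode == "bisulfite" and strand == "+":
                diff = ~((windows == r) | ((windows == _C) & (r == _T)))
            elif mode == "bisulfite" and strand == "-":
                diff = ~((windows == r) | ((windows == _G) & (r == _A)))
            else:
                raise ValueError(mode)
            mm = (bad | diff).sum(axis=1)
            for start in np.nonzero(mm <= k)[0]:
                out.append((ref.name, int(start), strand, int(mm[start])))
    return out


def brute_force_best(read: Read, refs: Sequence[ReferenceSeq], k: int,
                     mode: str = "plain", qual_cutoff: Optional[int] = None
                     ) -> tuple[str, Optional[int],
                                set[tuple[str, int, str]]]:
    """(status, best_mismatches, best placement set) per the same
    minimum-stratum uniqueness convention as the aligner."""
    hits = brute_force_hits(read, refs, k, mode=mode, qual_cutoff=qual_cutoff)
    if not hits:
        return "unmapped", None, set()
    best = min(h[3] for h in hits)
    places = {(h[0], h[1], h[2]) for h in hits if h[3] == best}
    status = "unique" if len(places) == 1 else "ambiguous"
    return status, best, places
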