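"""Composition/transition (CT) descriptor over the 20xN binary profile.

Each residue type defines a binary indicator track along the sequence
(1 where that residue occurs).  Every track is cut into ``L`` near-equal
segments and five statistics are taken per segment, all in percent:

* composition: frequency of ``0``, of ``1``, of overlapping ``11`` pairs
  and of overlapping ``111`` triples;
* transition: frequency of adjacent unequal bits (``01`` or ``10``).

With ``L = 4`` this yields a 20 x 4 x 5 = 400-dimensional vector.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RESIDUE_ORDER",
    "binary_profile",
    "segment_stats",
    "split_segments",
    "ct_vector",
]

#: Fixed residue row order of the binary profile matrix.
RESIDUE_ORDER = "ARNDCEQGHILKMFPSTWYV"

_ROW_INDEX = {c: i for i, c in enumerate(RESIDUE_ORDER)}


def binary_profile(seq: str) -> np.ndarray:
    """20 x n 0/1 matrix; row i, column j is 1 iff ``seq[j] == RESIDUE_ORDER[i]``."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    profile = np.zeros((20, n), dtype=np.uint8)
    for j, c in enumerate(seq):
        try:
            profile[_ROW_INDEX[c], j] = 1
        except KeyError:
            raise ValueError(f"non-standard residue {c!r} at position {j}") from None
    return profile


def segment_stats(bits) -> tuple[float, float, float, float, float]:
    """Five percent-scale statistics of a bit string / 0-1 array.

    Returns ``(freq0, freq1, freq11, freq111, trans)``.  Substring counts
    are overlapping ("111" contains two "11").  A statistic whose
    denominator would be non-positive (m-1 for pairs and transitions,
    m-2 for triples) is defined as 0.
    """
    if isinstance(bits, str):
        arr = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("bit string must contain only '0' and '1'")
    else:
        arr = np.asarray(bits, dtype=np.uint8)
    m = arr.size
    if m == 0:
        raise ValueError("empty segment")
    ones = int(arr.sum())
    freq0 = 100.0 * (m - ones) / m
    freq1 = 100.0 * ones / m
    if m >= 2:
        pair = arr[:-1] & arr[1:]
        freq11 = 100.0 * int(pair.sum()) / (m - 1)
        trans = 100.0 * int((arr[:-1] != arr[1:]).sum()) / (m - 1)
    else:
        freq11 = trans = 0.0
    if m >= 3:
        freq111 = 100.0 * int((arr[:-2] & arr[1:-1] & arr[2:]).sum()) / (m - 2)
    else:
        freq111 = 0.0
    return freq0, freq1, freq11, freq111, trans


def split_segments(bits, L: int) -> list:
    """Cut a track of length n into L contiguous near-equal pieces.

    Segment i (1-based) covers the half-open index range
    ``[floor((i-1) n / L), floor(i n / L))``; lengths differ by at most one
    and the concatenation reproduces the input.
    """
    n = len(bits)
    if L < 1:
        raise ValueError("L must be >= 1")
    if n < L:
        raise ValueError(f"sequence too short: length {n} < {L} segments")
    bounds = [(i * n) // L for i in range(L + 1)]
    return [bits[bounds[i] : bounds[i + 1]] for i in range(L)]


def ct_vector(seq: str, L: int = 4) -> np.ndarray:
    """CT descriptor of a cleaned sequence: 20 residues x L segments x 5 stats.

    Ordered residue-major: for each residue in :data:`RESIDUE_ORDER`, for each
    segment 1..L, the five statistics of :func:`segment_stats`.
    """
    profile = binary_profile(seq)
    out = np.empty(20 * L * 5)
    pos = 0
    for row in profile:
        for segment in split_segments(row, L):
            out[pos : pos + 5] = segment_stats(segment)
            pos += 5
    return out
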