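"""Unit-circle F-vector descriptor.

A protein sequence is rewritten over a four-letter alphabet ``{B, J, O, U}``
using a reduced amino-acid alphabet (six physicochemical classes regrouped
into four super-groups), each letter is assigned one quadrant of the unit
circle, and successive occurrences of a letter are spread evenly along its
quadrant arc.  The first and second moments (Mx, My, Vx, Vy) of the resulting
point cloud, computed for each of ten regroupings, form a 40-dimensional
descriptor of the sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "SIX_CLASSES",
    "RESIDUE_CLASS",
    "CombinationPattern",
    "COMBINATION_PATTERNS",
    "clean_sequence",
    "reduce_sequence",
    "circle_map",
    "pattern_moments",
    "f_vector",
]

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Six physicochemical residue classes: aliphatic, aromatic, polar,
#: positively charged, negatively charged, and special-conformation.
SIX_CLASSES: dict[str, str] = {
    "A1": "AVLIMC",  # aliphatic
    "A2": "FWYH",    # aromatic
    "A3": "STNQ",    # polar
    "A4": "KR",      # positive
    "A5": "DE",      # negative
    "A6": "GP",      # special conformations
}

#: Residue letter -> class label (each residue belongs to exactly one class).
RESIDUE_CLASS: dict[str, str] = {
    res: name for name, members in SIX_CLASSES.items() for res in members
}


@dataclass(frozen=True)
class CombinationPattern:
    """One regrouping of the six residue classes into the four letters B/J/O/U.

    ``b_classes`` holds the three classes merged into the super-group B
    (always containing the aliphatic class A1); ``j_class``, ``o_class`` and
    ``u_class`` are the remaining singleton classes.
    """

    id: int
    b_classes: frozenset[str]
    j_class: str
    o_class: str
    u_class: str

    def __post_init__(self) -> None:
        used = set(self.b_classes) | {self.j_class, self.o_class, self.u_class}
        if len(self.b_classes) != 3 or used != set(SIX_CLASSES):
            raise ValueError("pattern must partition the six classes into 3+1+1+1")
        if "A1" not in self.b_classes:
            raise ValueError("A1 must belong to the B group")

    def letter_of(self, class_label: str) -> str:
        if class_label in self.b_classes:
            return "B"
        if class_label == self.j_class:
            return "J"
        if class_label == self.o_class:
            return "O"
        return "U"


_PATTERN_ROWS = [
    ({"A1", "A2", "A3"}, "A4", "A5", "A6"),
    ({"A1", "A2", "A4"}, "A3", "A5", "A6"),
    ({"A1", "A2", "A5"}, "A3", "A4", "A6"),
    ({"A1", "A2", "A6"}, "A3", "A4", "A5"),
    ({"A1", "A3", "A4"}, "A2", "A5", "A6"),
    ({"A1", "A3", "A5"}, "A2", "A4", "A6"),
    ({"A1", "A3", "A6"}, "A2", "A4", "A5"),
    ({"A1", "A4", "A5"}, "A2", "A3", "A6"),
    ({"A1", "A4", "A6"}, "A2", "A3", "A5"),
    ({"A1", "A5", "A6"}, "A2", "A3", "A4"),
]

#: The ten regroupings v1..v10 used for the 40-dimensional descriptor.
COMBINATION_PATTERNS: tuple[CombinationPattern, ...] = tuple(
    CombinationPattern(i + 1, frozenset(b), j, o, u)
    for i, (b, j, o, u) in enumerate(_PATTERN_ROWS)
)

#: Quadrant base angles for the four super-group letters.
_BASE_ANGLE = {"B": 0.0, "J": np.pi / 2, "O": np.pi, "U": 3 * np.pi / 2}


def clean_sequence(raw: str) -> str:
    """Uppercase ``raw`` and drop every character that is not a standard residue.

    Non-standard letters (X, B, Z, U, O ambiguity codes, ``*``, gaps) are
    stripped with a warning rather than raising, since real FASTA records
    routinely contain them.

    Raises
    ------
    ValueError
        If nothing encodable remains.
    """
    seq = "".join(raw.split()).upper()
    kept = [c for c in seq if c in RESIDUE_CLASS]
    removed = sorted({c for c in seq if c not in RESIDUE_CLASS})
    if removed:
        warnings.warn(
            f"removed non-standard characters {removed} from sequence",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("unencodable sequence: no standard residues remain")
    return "".join(kept)


def reduce_sequence(seq: str, pattern: CombinationPattern) -> str:
    """Rewrite a cleaned residue string over the alphabet ``{B, J, O, U}``."""
    try:
        return "".join(pattern.letter_of(RESIDUE_CLASS[c]) for c in seq)
    except KeyError as exc:  # pragma: no cover - guarded by clean_sequence
        raise ValueError(f"non-standard residue {exc} in sequence") from exc


def circle_map(rs: str) -> np.ndarray:
    """Place each position of a reduced sequence on the unit circle.

    The q-th occurrence (out of ``X_n`` total) of letter X is put at angle
    ``base(X) + (pi/2) * q / (X_n + 1)``, i.e. occurrences of a letter are
    spread evenly over the open quadrant arc assigned to it.

    Returns an ``(n, 2)`` array of (x, y) coordinates.
    """
    if len(rs) == 0:
        raise ValueError("empty reduced sequence")
    totals = {c: rs.count(c) for c in "BJOU"}
    seen = dict.fromkeys("BJOU", 0)
    angles = np.empty(len(rs))
    for q, c in enumerate(rs):
        if c not in _BASE_ANGLE:
            raise ValueError(f"invalid reduced letter {c!r}")
        seen[c] += 1
        angles[q] = _BASE_ANGLE[c] + (np.pi / 2) * seen[c] / (totals[c] + 1)
    return np.column_stack([np.cos(angles), np.sin(angles)])


def pattern_moments(points: np.ndarray) -> tuple[float, float, float, float]:
    """Means and sample variances (denominator n-1) of the circle points.

    For a single point the variance is defined as 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("expected a non-empty (n, 2) point array")
    mx, my = pts.mean(axis=0)
    if pts.shape[0] == 1:
        vx = vy = 0.0
    else:
        vx, vy = pts.var(axis=0, ddof=1)
    return float(mx), float(my), float(vx), float(vy)


def f_vector(seq: str) -> np.ndarray:
    """40-dimensional descriptor: (Mx, My, Vx, Vy) for each pattern v1..v10.

    ``seq`` may be a raw residue string; it is cleaned first.
    """
    cleaned = clean_sequence(seq)
    out = np.empty(40)
    for i, pattern in enumerate(COMBINATION_PATTERNS):
        pts = circle_map(reduce_sequence(cleaned, pattern))
        out[4 * i : 4 * i + 4] = pattern_moments(pts)
    return out
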