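"""Trimer features of β-matrices.

A *trimer* is a path of three pairwise-adjacent residue cells in a β-matrix,
shaped either as a corner (**L**), a vertical run in one column (**V**), or a
horizontal run in one row (**H**). Trimers are the features by which
β-matrices are indexed and queried.

Conventions (fixing what the reading order and orientation numbering must
satisfy — the XOR reflection law and the equivalence groups):

* **Reading order** — V-trimers are read top-to-bottom, H-trimers
  left-to-right, L-trimers as (vertical-arm endpoint, corner,
  horizontal-arm endpoint).
* **Orientation** — for L-trimers, bit 0 is set iff the horizontal arm
  extends left of the corner, bit 1 iff the vertical arm extends up; for
  V-trimers orient is 0 if ``seq[0] <= seq[2]`` else 2; for H-trimers 0 if
  ``seq[0] <= seq[2]`` else 1. With these choices a y-axis flip maps orient
  to ``orient ^ 1`` and an x-axis flip to ``orient ^ 2``, up to the
  equivalence encoded in ``eq_orients``.
* **Canonical id** — V/H trimers share one id with their reverse reading
  (lexicographic minimum); L-trimer ids use the physical reading order, all
  four orientations being geometrically distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .core import BetaMatrix

#: Trimer class values: L; V asymmetric; H asymmetric; V symmetric
#: (seq[0] == seq[2]); H symmetric. The class doubles as the bitmask template
#: for orientation equivalence.
CLASS_L = 1
CLASS_V = 3
CLASS_H = 5
CLASS_V_SYM = 15
CLASS_H_SYM = 31

V_CLASSES = frozenset({CLASS_V, CLASS_V_SYM})
H_CLASSES = frozenset({CLASS_H, CLASS_H_SYM})

ROW_SPAN = "row"
COL_SPAN = "col"


def classify(shape: str, seq: str) -> int:
    """Class value of a trimer given its shape letter ('L', 'V', 'H')."""
    if shape == "L":
        return CLASS_L
    symmetric = seq[0] == seq[2]
    if shape == "V":
        return CLASS_V_SYM if symmetric else CLASS_V
    if shape == "H":
        return CLASS_H_SYM if symmetric else CLASS_H
    raise ValueError(f"unknown trimer shape {shape!r}")


def reflect_orient(orient: int, axis_mask: int) -> int:
    """Orientation after reflection: XOR 1 for the y-axis, 2 for the x-axis."""
    if orient not in (0, 1, 2, 3):
        raise ValueError(f"orient must be in 0..3, got {orient}")
    return orient ^ axis_mask


def compute_eq_orients(cls: int, seq: str, orient: int) -> int:
    """4-bit mask of orientations indistinguishable from ``orient``.

    Bit ``i`` is set iff orientation ``i`` produces the same physical trimer:
    L-trimers are asymmetric (singleton mask); asymmetric V-trimers are blind
    to y-flips ({0,1} or {2,3}), asymmetric H-trimers to x-flips ({0,2} or
    {1,3}); symmetric V/H trimers are blind to everything (mask 15).
    """
    if cls == CLASS_L:
        return 1 << orient
    if cls == CLASS_V:
        return 3 if seq[0] < seq[2] else 12
    if cls == CLASS_H:
        return 5 if seq[0] < seq[2] else 10
    return 15


@dataclass(frozen=True)
class Trimer:
    """One trimer feature with its location and span geometry.

    ``span1``/``span2`` are ordered scalar-coordinate pairs ``(i, j)`` with
    ``i`` the middle residue's row (row-span) or column (col-span) and
    ``|i - j| = 1``. L-trimers carry one row-span (span1, toward ``seq[0]``)
    and one col-span (span2, toward ``seq[2]``); V-trimers two row-spans;
    H-trimers two col-spans.
    """

    seq: str
    cls: int
    orient: int
    eq_orients: int
    row: int
    col: int
    span1: tuple[int, int]
    span2: tuple[int, int]
    matrix_id: str = ""

    @property
    def id(self) -> tuple[int, str]:
        """Reflection-invariant identity: (class, canonical seq)."""
        if self.cls == CLASS_L:
            return (self.cls, self.seq)
        return (self.cls, min(self.seq, self.seq[::-1]))

    @property
    def coord(self) -> tuple[int, int]:
        return (self.row, self.col)

    @property
    def shape(self) -> str:
        if self.cls == CLASS_L:
            return "L"
        return "V" if self.cls in V_CLASSES else "H"

    def spans(self) -> tuple[tuple[str, int, tuple[int, int], int], ...]:
        """Spans as ``(kind, line, (i, j), span_num)`` tuples.

        ``line`` locates the span: the column for a row-span, the row for a
        col-span. ``span_num`` is 1 or 2.
        """
        if self.cls == CLASS_L:
            return (
                (ROW_SPAN, self.col, self.span1, 1),
                (COL_SPAN, self.row, self.span2, 2),
            )
        if self.cls in V_CLASSES:
            return (
                (ROW_SPAN, self.col, self.span1, 1),
                (ROW_SPAN, self.col, self.span2, 2),
            )
        return (
            (COL_SPAN, self.row, self.span1, 1),
            (COL_SPAN, self.row, self.span2, 2),
        )


def _make(shape, seq, orient, r, c, span1, span2, matrix_id) -> Trimer:
    cls = classify(shape, seq)
    return Trimer(
        seq=seq,
        cls=cls,
        orient=orient,
        eq_orients=compute_eq_orients(cls, seq, orient),
        row=r,
        col=c,
        span1=span1,
        span2=span2,
        matrix_id=matrix_id,
    )


def extract_trimers(m: BetaMatrix, matrix_id: str | None = None) -> list[Trimer]:
    """Enumerate every trimer of a β-matrix.

    Each L/V/H-shaped path of three pairwise-adjacent residue cells yields
    exactly one trimer; wildcard cells never participate. Any single cell is
    the middle residue of at most six trimers (four L, one V, one H). Output
    order is deterministic: row-major by middle-cell coordinate, then class,
    then orientation.
    """
    mid = m.sheet_id if matrix_id is None else matrix_id
    out: list[Trimer] = []
    res = m.is_residue
    for r in range(m.n_rows):
        for c in range(m.n_cols):
            if not res(r, c):
                continue
            up = r > 0 and res(r - 1, c)
            down = r + 1 < m.n_rows and res(r + 1, c)
            left = c > 0 and res(r, c - 1)
            right = c + 1 < m.n_cols and res(r, c + 1)
            cell = m.cell
            if up and down:
                seq = cell(r - 1, c) + cell(r, c) + cell(r + 1, c)
                orient = 0 if seq[0] <= seq[2] else 2
                out.append(
                    _make("V", seq, orient, r, c, (r, r - 1), (r, r + 1), mid)
                )
            if left and right:
                seq = cell(r, c - 1) + cell(r, c) + cell(r, c + 1)
                orient = 0 if seq[0] <= seq[2] else 1
                out.append(
                    _make("H", seq, orient, r, c, (c, c - 1), (c, c + 1), mid)
                )
            for dv, vert_ok in ((-1, up), (1, down)):
                if not vert_ok:
                    continue
                for dh, horiz_ok in ((-1, left), (1, right)):
                    if not horiz_ok:
                        continue
                    seq = cell(r + dv, c) + cell(r, c) + cell(r, c + dh)
                    orient = (1 if dh < 0 else 0) | (2 if dv < 0 else 0)
                    out.append(
                        _make(
                            "L", seq, orient, r, c,
                            (r, r + dv), (c, c + dh), mid,
                        )
                    )
    out.sort(key=lambda t: (t.row, t.col, t.cls, t.orient))
    return out


def iter_trimer_ids(m: BetaMatrix) -> Iterator[tuple[int, str]]:
    for t in extract_trimers(m):
        yield t.id
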