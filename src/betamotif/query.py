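"""Query preprocessing, two-stage filtering, and candidate verification.

The pipeline for one concrete (wildcard-free) query:

1. **Preprocess** — enumerate the query trimers and build the *query graph*,
   whose vertices are trimers and whose edges record span overlaps between
   adjacent trimers.
2. **First filter** — intersect the ``D`` postings sets of all query trimer
   ids, smallest set first, giving candidates ``C1`` that contain every
   query feature.
3. **Second filter** — keep only candidates *congruent* to the query: there
   must exist a single global reflection ``g`` in {0,1,2,3} reconciling
   every query trimer's orientation with some same-id candidate trimer.
   All set operations are 4-bit bitmasks, so this never enumerates
   reflected copies of anything.
4. **Verify** — for each surviving candidate and each feasible ``g``
   (ascending), require that every query-graph edge is matched by a
   candidate trimer pair with the same span-overlap geometry after
   reflecting the query's relative offsets by ``g``. Quadratic in the
   number of query trimers; no subgraph-isomorphism test.

Queries with a single trimer are fully decided by filtering and skip
verification. :func:`naive_match` is the independent sliding-window oracle
used in strict mode and throughout the test/benchmark harness.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    AMINO_ACIDS,
    BetaMatrix,
    GAP,
    REFLECTIONS,
    WILDCARD,
    parse_beta_matrix,
)
from .errors import BetaMotifError, MalformedQueryError
from .index import IndexTriple, TrimerId
from .trimers import Trimer, extract_trimers

logger = logging.getLogger(__name__)

#: Default cap on the number of concrete queries one wildcard query may
#: expand into (20 per wildcard position, multiplicative).
MAX_EXPANSIONS = 400


@dataclass(frozen=True)
class OverlapDescriptor:
    """Geometry of one query-graph edge between trimers ``a`` and ``b``.

    ``overlaps`` lists every span-line overlap as ``(kind, span_num_a,
    span_num_b)``; ``rel_orient`` is the XOR of the two orientations and
    ``rel_offset`` the (Δrow, Δcol) between middle-residue coordinates
    (magnitudes are at most 2 for overlapping trimers).
    """

    overlaps: frozenset[tuple[str, int, int]]
    rel_orient: int
    rel_offset: tuple[int, int]


@dataclass
class Query:
    """A preprocessed query: its matrix, trimers, ids, and query graph."""

    matrix: BetaMatrix
    trimers: list[Trimer]
    trimer_ids: frozenset[TrimerId]
    edges: list[tuple[int, int, OverlapDescriptor]]

    @property
    def has_wildcards(self) -> bool:
        return self.matrix.has_wildcards


@dataclass
class CandidateSets:
    """Per-query pipeline trace: hits ⊆ C2 ⊆ C1, plus work counters."""

    C1: set[str] = field(default_factory=set)
    C2: set[str] = field(default_factory=set)
    hits: set[str] = field(default_factory=set)
    n_match_pairs: int = 0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def span_overlaps(a: Trimer, b: Trimer) -> frozenset[tuple[str, int, int]]:
    """All span-line overlaps between two trimers.

    Two spans overlap when they are of the same kind, lie on the same line
    (same column for row-spans, same row for col-spans), and their two-cell
    intervals share at least one cell.
    """
    out = []
    for kind_a, line_a, (i_a, j_a), num_a in a.spans():
        for kind_b, line_b, (i_b, j_b), num_b in b.spans():
            if kind_a != kind_b or line_a != line_b:
                continue
            if {i_a, j_a} & {i_b, j_b}:
                out.append((kind_a, num_a, num_b))
    return frozenset(out)


def _descriptor(a: Trimer, b: Trimer) -> OverlapDescriptor | None:
    overlaps = span_overlaps(a, b)
    if not overlaps:
        return None
    return OverlapDescriptor(
        overlaps=overlaps,
        rel_orient=a.orient ^ b.orient,
        rel_offset=(b.row - a.row, b.col - a.col),
    )


def make_query_graph(
    trimers: Sequence[Trimer],
) -> list[tuple[int, int, OverlapDescriptor]]:
    """Build the query-graph edges over a trimer list.

    Spans are bucketed by the cells they cover, so each trimer only meets
    the constant-size set of trimers sharing a cell with one of its spans;
    construction is linear in the number of trimers. Raises
    :class:`MalformedQueryError` if the resulting graph is disconnected.
    """
    if not trimers:
        raise MalformedQueryError("query contains no trimers")
    buckets: dict[tuple[str, int, int], set[int]] = {}
    for idx, t in enumerate(trimers):
        for kind, line, (i, j), _num in t.spans():
            for coord_on_line in (i, j):
                if kind == "row":
                    cell = (kind, coord_on_line, line)
                else:
                    cell = (kind, line, coord_on_line)
                buckets.setdefault(cell, set()).add(idx)
    pairs = {
        pair
        for members in buckets.values()
        for pair in itertools.combinations(sorted(members), 2)
    }
    edges = []
    parent = list(range(len(trimers)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in sorted(pairs):
        desc = _descriptor(trimers[i], trimers[j])
        if desc is None:
            continue
        edges.append((i, j, desc))
        parent[find(i)] = find(j)
    if len({find(i) for i in range(len(trimers))}) > 1:
        raise MalformedQueryError("query trimer graph is disconnected")
    return edges


def preprocess_query(m: BetaMatrix | str) -> Query:
    """Validate a query β-matrix and enumerate its trimers and graph.

    Accepts a record string or a matrix; wildcards are allowed and produce
    no trimers themselves (expansion handles them). Raises
    :class:`MalformedQueryError` for structurally invalid queries —
    split strands, too few residues to form a trimer, or a disconnected
    trimer graph.
    """
    if isinstance(m, str):
        try:
            m = parse_beta_matrix(m)
        except BetaMotifError as exc:
            raise MalformedQueryError(str(exc)) from exc
    trimers = extract_trimers(m)
    if m.has_wildcards:
        # Wildcard queries are validated on the cell graph; each concrete
        # expansion re-runs full preprocessing.
        _check_cells_connected(m)
        return Query(
            matrix=m,
            trimers=trimers,
            trimer_ids=frozenset(t.id for t in trimers),
            edges=[],
        )
    edges = make_query_graph(trimers)
    return Query(
        matrix=m,
        trimers=trimers,
        trimer_ids=frozenset(t.id for t in trimers),
        edges=edges,
    )


def _check_cells_connected(m: BetaMatrix) -> None:
    cells = {
        (r, c)
        for r in range(m.n_rows)
        for c in range(m.n_cols)
        if m.cell(r, c) != GAP
    }
    if len(cells) < 3:
        raise MalformedQueryError("query has fewer than three residue cells")
    seen = set()
    stack = [next(iter(cells))]
    while stack:
        r, c = stack.pop()
        if (r, c) in seen:
            continue
        seen.add((r, c))
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in cells and nb not in seen:
                stack.append(nb)
    if seen != cells:
        raise MalformedQueryError("query cells are disconnected")


def expand_wildcards(
    q: Query, alphabet: str = AMINO_ACIDS, cap: int = MAX_EXPANSIONS
) -> list[Query]:
    """Concrete queries obtained by substituting every wildcard cell.

    The Cartesian product over wildcard positions of the canonical
    20-residue alphabet; a query with no wildcards expands to itself.
    """
    if not q.has_wildcards:
        return [q]
    positions = [
        (r, c)
        for r in range(q.matrix.n_rows)
        for c in range(q.matrix.n_cols)
        if q.matrix.cell(r, c) == WILDCARD
    ]
    total = len(alphabet) ** len(positions)
    if total > cap:
        raise ValueError(
            f"wildcard expansion would produce {total} queries (cap {cap})"
        )
    out = []
    for combo in itertools.product(alphabet, repeat=len(positions)):
        rows = [list(row) for row in q.matrix.rows]
        for (r, c), aa in zip(positions, combo):
            rows[r][c] = aa
        concrete = BetaMatrix(
            sheet_id=q.matrix.sheet_id,
            rows=tuple("".join(row) for row in rows),
            source=q.matrix.source,
        )
        out.append(preprocess_query(concrete))
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def first_filter(q: Query, ix: IndexTriple) -> set[str]:
    """Candidates containing every query trimer id (postings intersection).

    Iterates smallest postings set first, so cost is bounded by the smallest
    set times the number of distinct query ids.
    """
    postings = []
    for tid in q.trimer_ids:
        p = ix.D.get(tid)
        if not p:
            return set()
        postings.append(p)
    postings.sort(key=len)
    c1 = set(postings[0])
    for p in postings[1:]:
        c1 &= p
        if not c1:
            break
    return c1


def congruent(q: Query, c: str, ix: IndexTriple) -> int:
    """Feasible global-reflection bitmask of candidate ``c`` (0 = incongruent).

    For each query trimer the feasible reflections are the ``g`` for which
    some same-id candidate trimer accepts orientation ``q.orient ^ g``
    (a bit test against its equivalent-orientations mask); the candidate is
    congruent iff the intersection of these 4-bit masks over all query
    trimers is nonempty.
    """
    groups = ix.per_matrix[c]
    feasible = 0b1111
    for qt in q.trimers:
        mask = 0
        for t in groups.get(qt.id, ()):
            for g in REFLECTIONS:
                if t.eq_orients >> (qt.orient ^ g) & 1:
                    mask |= 1 << g
            if mask == 0b1111:
                break
        feasible &= mask
        if not feasible:
            return 0
    return feasible


def second_filter(
    q: Query, c1: Iterable[str], ix: IndexTriple
) -> dict[str, int]:
    """Candidates congruent to the query, with their feasible masks."""
    out = {}
    for c in sorted(c1):
        mask = congruent(q, c, ix)
        if mask:
            out[c] = mask
    return out


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------

def _transform_overlaps(
    overlaps: frozenset[tuple[str, int, int]],
    a: Trimer,
    b: Trimer,
    g: int,
) -> frozenset[tuple[str, int, int]]:
    """Span-number relabelling of an overlap set under global reflection g.

    Candidate trimers are re-read in their own matrix, so a V-trimer's
    span1 always points up and an H-trimer's span1 always points left;
    an x-flip therefore swaps the span numbers of V-trimers and a y-flip
    those of H-trimers. L-trimer arms keep their reading-order identity.
    """

    def map_num(t: Trimer, num: int) -> int:
        if t.shape == "V" and g & 2:
            return 3 - num
        if t.shape == "H" and g & 1:
            return 3 - num
        return num

    return frozenset(
        (kind, map_num(a, na), map_num(b, nb)) for kind, na, nb in overlaps
    )


def match_pairs(
    q_src: Trimer,
    q_des: Trimer,
    t_src: Trimer,
    t_des: Trimer,
    g: int,
    desc: OverlapDescriptor | None = None,
) -> bool:
    """Does candidate pair (t_src, t_des) match query pair (q_src, q_des)
    under global reflection ``g``?

    Requires same ids, per-trimer orientation feasibility under ``g``, the
    g-transformed relative offset, and identical span-overlap descriptors
    (relative orientation compared modulo orientation equivalence).
    """
    if t_src.id != q_src.id or t_des.id != q_des.id:
        return False
    if not (t_src.eq_orients >> (q_src.orient ^ g) & 1):
        return False
    if not (t_des.eq_orients >> (q_des.orient ^ g) & 1):
        return False
    if desc is None:
        desc = _descriptor(q_src, q_des)
        if desc is None:
            return False
    dr, dc = desc.rel_offset
    if g & 2:
        dr = -dr
    if g & 1:
        dc = -dc
    if (t_des.row - t_src.row, t_des.col - t_src.col) != (dr, dc):
        return False
    expected = _transform_overlaps(desc.overlaps, q_src, q_des, g)
    return span_overlaps(t_src, t_des) == expected


def verify_candidate(
    q: Query,
    c: str,
    ix: IndexTriple,
    feasible: int | None = None,
    stats: CandidateSets | None = None,
) -> bool:
    """Confirm a congruent candidate by per-edge pair matching.

    For each feasible global reflection (tried in ascending order), every
    query-graph edge must be matched by some candidate trimer pair; the
    partner trimer is located by an (id, coordinate) lookup, so each edge
    costs a constant amount of work per same-id source trimer. Single-trimer
    queries are already decided by filtering and verify trivially.
    """
    if feasible is None:
        feasible = congruent(q, c, ix)
    if not feasible:
        return False
    if not q.edges:
        return True
    groups = ix.per_matrix[c]
    coords = ix.by_id_coord[c]
    for g in REFLECTIONS:
        if not (feasible >> g & 1):
            continue
        if all(
            _edge_matched(q, i, j, desc, groups, coords, g, stats)
            for i, j, desc in q.edges
        ):
            return True
    return False


def _edge_matched(q, i, j, desc, groups, coords, g, stats) -> bool:
    q_src, q_des = q.trimers[i], q.trimers[j]
    dr, dc = desc.rel_offset
    if g & 2:
        dr = -dr
    if g & 1:
        dc = -dc
    for t_src in groups.get(q_src.id, ()):
        target = (q_des.id, (t_src.row + dr, t_src.col + dc))
        for t_des in coords.get(target, ()):
            if stats is not None:
                stats.n_match_pairs += 1
            if match_pairs(q_src, q_des, t_src, t_des, g, desc):
                return True
    return False


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def search_detailed(q: Query, ix: IndexTriple) -> CandidateSets:
    """Run the filter/verify pipeline for one concrete query."""
    if q.has_wildcards:
        raise ValueError("search_detailed requires a concrete query")
    cs = CandidateSets()
    cs.C1 = first_filter(q, ix)
    masks = second_filter(q, cs.C1, ix)
    cs.C2 = set(masks)
    cs.hits = {
        c for c, mask in masks.items() if verify_candidate(q, c, ix, mask, cs)
    }
    return cs


def search(
    q: Query | BetaMatrix | str,
    ix: IndexTriple,
    strict: bool = False,
) -> list[str]:
    """Sheet ids matching a query, sorted; wildcards expanded transparently.

    With ``strict=True`` every reported hit is re-confirmed against the
    sliding-window oracle; discrepancies (which would indicate a defect in
    the pair-matching relaxation) are logged and dropped.
    """
    if not isinstance(q, Query):
        q = preprocess_query(q)
    hits: set[str] = set()
    for concrete in expand_wildcards(q):
        hits |= search_detailed(concrete, ix).hits
    if strict:
        confirmed = {c for c in hits if naive_match(q.matrix, ix.matrices[c])}
        for c in sorted(hits - confirmed):
            logger.warning(
                "strict mode: dropping unconfirmed hit %s (pair-matching "
                "admitted a non-embedding)", c,
            )
        hits = confirmed
    return sorted(hits)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def naive_match(q: BetaMatrix | Query, m: BetaMatrix) -> bool:
    """Exhaustive sliding-window matching oracle.

    True iff some reflection of the query grid, placed at some offset,
    has every residue cell equal to the candidate cell beneath it; wildcard
    cells match any residue (but not a gap), gap cells are unconstrained.
    Independent of the trimer/index machinery by design.
    """
    if isinstance(q, Query):
        q = q.matrix
    qa = q.codes()
    ma = m.codes()
    for g in (0, 1, 2, 3):
        qg = qa
        if g & 1:
            qg = qg[:, ::-1]
        if g & 2:
            qg = qg[::-1, :]
        if qg.shape[0] > ma.shape[0] or qg.shape[1] > ma.shape[1]:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ma, qg.shape)
        is_gap = qg == 0
        is_wild = qg == 27
        ok = (
            is_gap
            | (is_wild & (windows != 0))
            | (~is_wild & (windows == qg))
        )
        if ok.all(axis=(2, 3)).any():
            return True
    return False
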