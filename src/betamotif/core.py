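"""β-matrix and β-graph data model.

A β-sheet is modelled as a 2D grid of amino-acid cells (a *β-matrix*): each
β-strand occupies one row, and bridge-partner residues (interstrand hydrogen
bonding) share a column. The equivalent graph view (a *β-graph*) has one node
per residue and edges typed ``peptide`` (backbone neighbours, horizontal
adjacency) or ``bridge`` (interstrand partners, vertical adjacency).

This module owns the text serialization (``.bmat`` records), validation,
the reflection algebra of the grid, and the conversions between the two views.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .errors import (
    AlphabetError,
    FormatError,
    UnprojectableError,
    ValidationError,
)

GAP = "."
WILDCARD = "*"
#: Characters allowed in a residue cell. Uppercase A-Z rather than the
#: canonical 20 so that nonstandard one-letter codes (B, X, Z) survive
#: extraction; generation and wildcard expansion use AMINO_ACIDS.
RESIDUE_CHARS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
#: The canonical 20-residue alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PEPTIDE = "peptide"
BRIDGE = "bridge"

# Reflection states form the Klein four-group {0, 1, 2, 3}: bit 0 set means
# reflected in the y-axis (column order reversed), bit 1 set means reflected
# in the x-axis (row order reversed). Composition is bitwise XOR.
IDENTITY = 0
REFLECT_Y = 1
REFLECT_X = 2
REFLECTIONS = (0, 1, 2, 3)


@dataclass(frozen=True)
class BetaMatrix:
    """A validated β-matrix.

    Parameters
    ----------
    sheet_id:
        Identifier of the sheet (e.g. ``1UBQA_SHEET_000``).
    rows:
        Tuple of equal-length strings over residue letters, ``.`` (gap) and
        ``*`` (wildcard).
    source:
        Optional provenance note (structure id, chain, ...).
    """

    sheet_id: str
    rows: tuple[str, ...]
    source: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))
        _validate_rows(self.rows)

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def cell(self, row: int, col: int) -> str:
        return self.rows[row][col]

    def is_residue(self, row: int, col: int) -> bool:
        c = self.rows[row][col]
        return c != GAP and c != WILDCARD

    @property
    def n_cells(self) -> int:
        """Number of non-gap cells (residues plus wildcards)."""
        return sum(len(r) - r.count(GAP) for r in self.rows)

    @property
    def has_wildcards(self) -> bool:
        return any(WILDCARD in r for r in self.rows)

    def codes(self) -> np.ndarray:
        """uint8 encoding of the grid: gap=0, A..Z=1..26, wildcard=27."""
        out = np.zeros((self.n_rows, self.n_cols), dtype=np.uint8)
        for r, row in enumerate(self.rows):
            for c, ch in enumerate(row):
                if ch == GAP:
                    continue
                out[r, c] = 27 if ch == WILDCARD else ord(ch) - 64
        return out

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return write_beta_matrix(self)


def _validate_rows(rows: tuple[str, ...]) -> None:
    if not rows:
        raise ValidationError("a β-matrix needs at least one row")
    width = len(rows[0])
    if width == 0:
        raise ValidationError("a β-matrix needs at least one column")
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"ragged rows: row {i} has {len(row)} cells, expected {width}"
            )
        for ch in row:
            if ch not in RESIDUE_CHARS and ch != GAP and ch != WILDCARD:
                raise AlphabetError(f"illegal cell character {ch!r} in row {i}")
        run = row.strip(GAP)
        if not run:
            raise ValidationError(f"row {i} is entirely gaps")
        if GAP in run:
            # A β-strand is one contiguous backbone segment; a gap inside the
            # non-gap run would split the strand across one row.
            raise ValidationError(f"row {i} has a non-contiguous strand: {row!r}")
    for c in range(width):
        if all(row[c] == GAP for row in rows):
            raise ValidationError(f"column {c} is entirely gaps")


# ---------------------------------------------------------------------------
# Serialization: FASTA-like records, "> sheet_id" then the grid rows.
# ---------------------------------------------------------------------------

def parse_beta_matrix(text: str) -> BetaMatrix:
    """Parse a single β-matrix record."""
    records = list(iter_beta_matrices(text))
    if len(records) != 1:
        raise FormatError(f"expected exactly one record, found {len(records)}")
    return records[0]


def iter_beta_matrices(text: str) -> Iterator[BetaMatrix]:
    """Iterate over the records of a multi-record ``.bmat`` document."""
    header: str | None = None
    rows: list[str] = []
    for line in itertools.chain(text.splitlines(), [None]):
        if line is None or line.startswith(">"):
            if header is not None:
                if not rows:
                    raise FormatError(f"record {header!r} has no rows")
                yield BetaMatrix(sheet_id=header, rows=tuple(rows))
            elif rows:
                raise FormatError("matrix rows before any '>' header")
            if line is not None:
                header = line[1:].strip()
                if not header:
                    raise FormatError("empty sheet id in record header")
                rows = []
        elif line.strip():
            rows.append(line.strip())
    if header is None:
        raise FormatError("no β-matrix record found")


def write_beta_matrix(m: BetaMatrix) -> str:
    """Serialize one record; round-trips bit-exactly through the parser."""
    return "> " + m.sheet_id + "\n" + "\n".join(m.rows) + "\n"


def read_bmat(path) -> list[BetaMatrix]:
    with open(path, "r", encoding="utf-8") as fh:
        return list(iter_beta_matrices(fh.read()))


def write_bmat(matrices: Iterable[BetaMatrix], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in matrices:
            fh.write(write_beta_matrix(m))


# ---------------------------------------------------------------------------
# Reflection algebra
# ---------------------------------------------------------------------------

def reflect_matrix(m: BetaMatrix, reflection: int) -> BetaMatrix:
    """Apply one of the four reflection states (0..3) to a β-matrix.

    Bit 0 reverses column order (y-axis flip), bit 1 reverses row order
    (x-axis flip). Applying the same state twice is the identity.
    """
    if reflection not in REFLECTIONS:
        raise ValueError(f"reflection must be in 0..3, got {reflection}")
    rows = m.rows
    if reflection & REFLECT_Y:
        rows = tuple(r[::-1] for r in rows)
    if reflection & REFLECT_X:
        rows = rows[::-1]
    return BetaMatrix(sheet_id=m.sheet_id, rows=rows, source=m.source)


def reflect_coord(
    row: int, col: int, n_rows: int, n_cols: int, reflection: int
) -> tuple[int, int]:
    """Image of a cell coordinate under a reflection of the enclosing grid."""
    if reflection & REFLECT_Y:
        col = n_cols - 1 - col
    if reflection & REFLECT_X:
        row = n_rows - 1 - row
    return row, col


def canonicalize(m: BetaMatrix) -> BetaMatrix:
    """The reflection of ``m`` with the lexicographically smallest rows.

    Used as the deterministic output orientation of :func:`graph_to_matrix`;
    sheets are indexed in a single arbitrary-but-reproducible orientation.
    """
    return min((reflect_matrix(m, g) for g in REFLECTIONS), key=lambda x: x.rows)


# ---------------------------------------------------------------------------
# Graph <-> matrix conversion
# ---------------------------------------------------------------------------

def matrix_to_graph(m: BetaMatrix) -> nx.Graph:
    """Expand a wildcard-free β-matrix into its β-graph.

    Horizontal cell adjacency becomes a peptide edge, vertical adjacency
    (both cells non-gap) a bridge edge. Node attributes: ``aa`` (one-letter
    code), ``resnum`` (synthesized sequential numbering, row-major), and
    ``chain`` (empty for synthetic graphs).
    """
    if m.has_wildcards:
        raise ValidationError("cannot expand a β-matrix containing wildcards")
    g = nx.Graph()
    node_at: dict[tuple[int, int], int] = {}
    nid = 0
    for r, row in enumerate(m.rows):
        for c, ch in enumerate(row):
            if ch == GAP:
                continue
            g.add_node(nid, aa=ch, resnum=nid + 1, chain="")
            node_at[(r, c)] = nid
            nid += 1
    for (r, c), u in node_at.items():
        if (r, c + 1) in node_at:
            g.add_edge(u, node_at[(r, c + 1)], kind=PEPTIDE)
        if (r + 1, c) in node_at:
            g.add_edge(u, node_at[(r + 1, c)], kind=BRIDGE)
    return g


def _strand_paths(g: nx.Graph) -> list[list]:
    """Split a β-graph into strands: peptide-edge paths in residue order."""
    peptide = nx.Graph()
    peptide.add_nodes_from(g.nodes)
    peptide.add_edges_from(
        (u, v) for u, v, k in g.edges(data="kind") if k == PEPTIDE
    )
    strands = []
    for comp in nx.connected_components(peptide):
        if any(peptide.degree(n) > 2 for n in comp):
            raise UnprojectableError("branched peptide backbone in one strand")
        strand = sorted(comp, key=lambda n: g.nodes[n]["resnum"])
        strands.append(strand)
    strands.sort(key=lambda s: g.nodes[s[0]]["resnum"])
    return strands


def _order_strands(g: nx.Graph, strands: list[list]) -> list[int]:
    """Topologically order strands so bridged strands sit in adjacent rows.

    The strand-adjacency graph of a projectable (planar, non-bifurcated,
    non-barrel) sheet is a simple path; its traversal order is the row order.
    """
    adj = nx.Graph()
    adj.add_nodes_from(range(len(strands)))
    of_node = {n: i for i, strand in enumerate(strands) for n in strand}
    for u, v, k in g.edges(data="kind"):
        if k == BRIDGE:
            su, sv = of_node[u], of_node[v]
            if su == sv:
                raise UnprojectableError("bridge within a single strand")
            adj.add_edge(su, sv)
    if not nx.is_connected(adj):
        raise UnprojectableError("strands do not form a single sheet")
    if len(strands) == 1:
        return [0]
    ends = [n for n in adj.nodes if adj.degree(n) == 1]
    if any(adj.degree(n) > 2 for n in adj.nodes) or len(ends) != 2:
        # Degree > 2 means a bifurcated sheet; no ends means a barrel.
        raise UnprojectableError("bifurcated or barreled sheet")
    start = min(ends)
    order = [start]
    while len(order) < len(strands):
        nxt = [n for n in adj.neighbors(order[-1]) if n not in order]
        if len(nxt) != 1:
            raise UnprojectableError("strand adjacency is not a simple path")
        order.append(nxt[0])
    return order


def graph_to_matrix(g: nx.Graph, sheet_id: str = "sheet") -> BetaMatrix:
    """Project a β-graph onto a β-matrix (topological-sort flattening).

    Strands become rows (in strand-adjacency order); bridge partners are
    forced into the same column. Raises :class:`UnprojectableError` when no
    consistent column assignment exists (bifurcated sheets, barrels, register
    conflicts). The output orientation is canonicalized so that projection is
    deterministic and reflection-blind.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("empty β-graph")
    strands = _strand_paths(g)
    order = _order_strands(g, strands)

    bridges: set[frozenset] = {
        frozenset((u, v)) for u, v, k in g.edges(data="kind") if k == BRIDGE
    }
    col: dict[int, int] = {}
    prev: list | None = None
    for row_idx, si in enumerate(order):
        strand = strands[si]
        if prev is None:
            for k, n in enumerate(strand):
                col[n] = k
            prev = strand
            continue
        # Anchor this strand on its bridges to the already-placed row above.
        anchors = [
            (k, col[p])
            for k, n in enumerate(strand)
            for p in prev
            if frozenset((n, p)) in bridges
        ]
        if not anchors:
            raise UnprojectableError("no bridge to the preceding strand")
        placed = _place_strand(strand, anchors, prev, col, bridges)
        if placed is None:
            raise UnprojectableError(
                "conflicting column assignments (register conflict)"
            )
        col.update(placed)
        prev = strand

    # Assemble the grid; shift columns so the minimum is zero.
    cmin = min(col.values())
    width = max(col.values()) - cmin + 1
    grid = [[GAP] * width for _ in order]
    for row_idx, si in enumerate(order):
        for n in strands[si]:
            grid[row_idx][col[n] - cmin] = g.nodes[n]["aa"]
    m = BetaMatrix(sheet_id=sheet_id, rows=tuple("".join(r) for r in grid))
    return canonicalize(m)


def _place_strand(strand, anchors, prev, col, bridges):
    """Try both backbone directions for one strand; return its column map.

    Column positions within a strand are consecutive; a bridge anchor fixes
    the offset and (with two or more anchors) the direction. The placement is
    accepted only if, against the previous row, every bridge is a same-column
    vertical adjacency and every same-column vertical adjacency is a bridge.
    """
    k0, c0 = anchors[0]
    directions = []
    for d in (1, -1):
        if all(c == c0 + d * (k - k0) for k, c in anchors):
            directions.append(d)
    prev_cols = {col[p]: p for p in prev}
    for d in directions:
        cand = {n: c0 + d * (k - k0) for k, n in enumerate(strand)}
        ok = True
        for n, c in cand.items():
            p = prev_cols.get(c)
            is_bridge = p is not None and frozenset((n, p)) in bridges
            has_partner = any(frozenset((n, p2)) in bridges for p2 in prev)
            if has_partner and not is_bridge:
                ok = False  # the bridge partner is not directly above
                break
            if p is not None and not is_bridge:
                ok = False  # spurious vertical adjacency with no bridge
                break
        if ok:
            return cand
    return None
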