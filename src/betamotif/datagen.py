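"""Synthetic β-matrix and query generation.

The generator emulates the statistics of sheets extracted from structure
databases: a handful of strands (rows) of 4–12 residues whose registers are
jittered by a couple of columns against their neighbours, giving the
staggered, fully-bridged, bulge-free sheets the data model assumes. Residues
are drawn i.i.d., either uniformly over the canonical 20 or from a built-in
natural background frequency table.

Queries reproduce the benchmark protocol: a random breadth-first traversal
of a sheet's residue graph grown until the induced motif has a requested
number of edges (2–10), one randomly placed wildcard cell, and a guarantee
that the expanded query matches its source sheet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AMINO_ACIDS, GAP, WILDCARD, BetaMatrix
from .errors import ValidationError
from .query import Query, preprocess_query

#: Natural amino-acid background frequencies (Robinson–Robinson style table,
#: order matching AMINO_ACIDS); normalized at use.
NATURAL_FREQUENCIES = {
    "A": 0.0785, "C": 0.0246, "D": 0.0536, "E": 0.0497, "F": 0.0387,
    "G": 0.0892, "H": 0.0219, "I": 0.0462, "K": 0.0574, "L": 0.0762,
    "M": 0.0219, "N": 0.0447, "P": 0.0484, "Q": 0.0426, "R": 0.0512,
    "S": 0.0724, "T": 0.0624, "V": 0.0655, "W": 0.0133, "Y": 0.0339,
}

#: Query sizes (motif edge counts) used by the benchmark workload.
QUERY_SIZES = tuple(range(2, 11))


@dataclass(frozen=True)
class GenConfig:
    """Study conditions for the synthetic corpus.

    ``n_cols`` bounds per-strand length; total matrix width is emergent
    (strand length plus accumulated register jitter).
    """

    n_matrices: int = 200
    n_rows: tuple[int, int] = (2, 6)
    n_cols: tuple[int, int] = (4, 12)
    jitter: int = 2
    distribution: str = "uniform"  # "uniform" | "natural-frequency"
    seed: int = 42

    def __post_init__(self):
        for lo, hi in (self.n_rows, self.n_cols):
            if not (1 <= lo <= hi):
                raise ValueError("empty or invalid range in GenConfig")
        if self.n_cols[0] < 2:
            raise ValueError("strands need at least two residues")
        if self.distribution not in ("uniform", "natural-frequency"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    def residue_probs(self) -> np.ndarray:
        if self.distribution == "uniform":
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        p = np.array([NATURAL_FREQUENCIES[a] for a in AMINO_ACIDS])
        return p / p.sum()


def gen_random_matrix(
    cfg: GenConfig,
    rng: np.random.Generator,
    sheet_id: str = "SYN_SHEET_000",
) -> BetaMatrix:
    """One random valid β-matrix under the configured conditions."""
    probs = cfg.residue_probs()
    n_rows = int(rng.integers(cfg.n_rows[0], cfg.n_rows[1] + 1))
    intervals: list[tuple[int, int]] = []
    start = 0
    for r in range(n_rows):
        length = int(rng.integers(cfg.n_cols[0], cfg.n_cols[1] + 1))
        if r == 0:
            intervals.append((start, start + length - 1))
            continue
        ps, pe = intervals[-1]
        while True:
            s = ps + int(rng.integers(-cfg.jitter, cfg.jitter + 1))
            e = s + length - 1
            if e >= ps and s <= pe:  # neighbouring strands must overlap
                break
        intervals.append((s, e))
    cmin = min(s for s, _ in intervals)
    width = max(e for _, e in intervals) - cmin + 1
    aa = np.array(list(AMINO_ACIDS))
    rows = []
    for s, e in intervals:
        n = e - s + 1
        letters = "".join(rng.choice(aa, size=n, p=probs))
        rows.append(GAP * (s - cmin) + letters + GAP * (width - (e - cmin) - 1))
    return BetaMatrix(sheet_id=sheet_id, rows=tuple(rows))


def gen_matrices(cfg: GenConfig) -> list[BetaMatrix]:
    """The full seeded corpus; the seed fixes the entire output stream."""
    rng = np.random.default_rng(cfg.seed)
    return [
        gen_random_matrix(cfg, rng, sheet_id=f"SYN_SHEET_{i:05d}")
        for i in range(cfg.n_matrices)
    ]


def _cell_graph(m: BetaMatrix):
    cells = [
        (r, c)
        for r in range(m.n_rows)
        for c in range(m.n_cols)
        if m.cell(r, c) != GAP
    ]
    cellset = set(cells)
    adj = {
        cell: [
            nb
            for nb in (
                (cell[0] - 1, cell[1]), (cell[0] + 1, cell[1]),
                (cell[0], cell[1] - 1), (cell[0], cell[1] + 1),
            )
            if nb in cellset
        ]
        for cell in cells
    }
    return cells, adj


def _induced_edges(selected: set, adj) -> int:
    return sum(1 for c in selected for nb in adj[c] if nb in selected) // 2


def _crop(m: BetaMatrix, selected: set, wildcard_at=None) -> BetaMatrix:
    rmin = min(r for r, _ in selected)
    rmax = max(r for r, _ in selected)
    cmin = min(c for _, c in selected)
    cmax = max(c for _, c in selected)
    rows = []
    for r in range(rmin, rmax + 1):
        row = []
        for c in range(cmin, cmax + 1):
            if (r, c) not in selected:
                row.append(GAP)
            elif wildcard_at == (r, c):
                row.append(WILDCARD)
            else:
                row.append(m.cell(r, c))
        rows.append("".join(row))
    return BetaMatrix(sheet_id=f"q_{m.sheet_id}", rows=tuple(rows))


def gen_query(
    m: BetaMatrix,
    size: int,
    rng: np.random.Generator,
    wildcard: bool = True,
    max_attempts: int = 50,
) -> Query | None:
    """A random connected query motif with ``size`` edges from one sheet.

    Grown by a random breadth-first traversal from a random root cell until
    the induced residue graph has exactly the requested edge count and forms
    a well-formed query matrix; one randomly chosen cell becomes the
    wildcard. Returns ``None`` (skip) when the sheet has too few edges or no
    valid motif of that size was found within the attempt budget.
    """
    if not 2 <= size <= 10:
        raise ValueError(f"query size must be in 2..10, got {size}")
    cells, adj = _cell_graph(m)
    total_edges = _induced_edges(set(cells), adj)
    if total_edges < size:
        return None
    for _ in range(max_attempts):
        root = cells[int(rng.integers(len(cells)))]
        selected = {root}
        frontier = list(adj[root])
        while frontier and _induced_edges(selected, adj) < size:
            pick = frontier.pop(int(rng.integers(len(frontier))))
            if pick in selected:
                continue
            selected.add(pick)
            frontier.extend(nb for nb in adj[pick] if nb not in selected)
        if _induced_edges(selected, adj) != size:
            continue
        wc = None
        if wildcard:
            ordered = sorted(selected)
            wc = ordered[int(rng.integers(len(ordered)))]
        try:
            qm = _crop(m, selected, wildcard_at=wc)
            return preprocess_query(qm)
        except ValidationError:
            continue
    return None
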