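"""β-sheet extraction from DSSP output files.

DSSP assigns per-residue secondary structure and, for sheet residues, up to
two *bridge partners* (the interstrand hydrogen-bonding neighbours). Residues
assigned ``E`` (extended strand) or ``B``/``b`` (isolated β-bridge) are taken
as sheet members; consecutive sheet residues give peptide edges and the
bridge-partner columns give bridge edges. Connected components of the
resulting β-graph are sheets, each projected to a β-matrix and named
``<PDBID><CHAIN>_SHEET_<NNN>`` in residue order.

Only the classic fixed-column DSSP text format is read; running DSSP itself
is out of scope (callers supply its output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx

from .core import BRIDGE, PEPTIDE, BetaMatrix, graph_to_matrix
from .errors import DsspFormatError, UnprojectableError

logger = logging.getLogger(__name__)

#: Secondary-structure symbols treated as β-strand members. DSSP emits "B"
#: for isolated bridges (written "b" in some descriptions); matching is
#: case-insensitive.
STRAND_SYMBOLS = frozenset("EB")


@dataclass(frozen=True)
class DsspResidue:
    """One residue row of a DSSP file."""

    dssp_index: int
    resnum: int
    icode: str
    chain: str
    aa: str
    ss: str
    bp1: int  # dssp_index of bridge partner 1, 0 if none
    bp2: int
    sheet_label: str

    @property
    def is_strand(self) -> bool:
        return self.ss.upper() in STRAND_SYMBOLS


def parse_dssp(source) -> list[DsspResidue]:
    """Parse a classic-format DSSP file (path or open text handle).

    Chain-break rows (``!`` in the amino-acid column) are skipped; lowercase
    amino-acid codes (disulfide-bonded cysteines) are read as ``C``. Raises
    :class:`DsspFormatError` with the line number on malformed input.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8", errors="replace") as fh:
            lines = fh.read().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise DsspFormatError("no '#  RESIDUE' header found in DSSP file")
    residues: list[DsspResidue] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) < 38:
            raise DsspFormatError("residue row too short", lineno)
        aa = line[13]
        if aa == "!":
            continue  # chain break
        if aa.islower():
            aa = "C"
        try:
            residues.append(
                DsspResidue(
                    dssp_index=int(line[0:5]),
                    resnum=int(line[5:10]),
                    icode=line[10].strip(),
                    chain=line[11].strip(),
                    aa=aa.upper(),
                    ss=line[16],
                    bp1=int(line[25:29]),
                    bp2=int(line[29:33]),
                    sheet_label=line[33].strip(),
                )
            )
        except ValueError as exc:
            raise DsspFormatError(f"unparseable residue row: {exc}", lineno)
    known = {r.dssp_index for r in residues}
    for r in residues:
        for bp in (r.bp1, r.bp2):
            if bp and bp not in known:
                raise DsspFormatError(
                    f"bridge partner {bp} of residue {r.dssp_index} "
                    "does not resolve"
                )
    return residues


def build_beta_graphs(residues: Sequence[DsspResidue]) -> list[nx.Graph]:
    """β-graphs (one per sheet) from parsed DSSP residues.

    Nodes are strand residues (``E``/``B``); peptide edges join residues at
    consecutive DSSP indices in the same chain, bridge edges come from the
    bridge-partner assignments. Connected components are returned in order
    of their first residue.
    """
    g = nx.Graph()
    by_index = {}
    for r in residues:
        if not r.is_strand:
            continue
        g.add_node(r.dssp_index, aa=r.aa, resnum=r.resnum, chain=r.chain)
        by_index[r.dssp_index] = r
    for idx, r in by_index.items():
        nxt = by_index.get(idx + 1)
        if nxt is not None and nxt.chain == r.chain:
            g.add_edge(idx, idx + 1, kind=PEPTIDE)
        for bp in (r.bp1, r.bp2):
            if bp and bp in by_index:
                g.add_edge(idx, bp, kind=BRIDGE)
    comps = sorted(nx.connected_components(g), key=min)
    return [g.subgraph(c).copy() for c in comps]


def extract_beta_matrices(
    graphs: Iterable[nx.Graph],
    pdb_id: str,
    chain: str,
    min_strands: int = 1,
    max_strands: int | None = None,
    keep: Callable[[nx.Graph], bool] | None = None,
) -> list[BetaMatrix]:
    """Project sheets to β-matrices with the standard sheet-id convention.

    Ids are ``<PDBID><CHAIN>_SHEET_<NNN>`` with a zero-padded 3-digit counter
    over the emitted sheets in residue order. Unprojectable sheets (bifurcated
    or barreled) are logged and skipped, never fatal. ``keep`` is an optional
    user-supplied sheet filter (e.g. a planarity criterion); by default all
    projectable sheets within the strand-count bounds are kept.
    """
    out: list[BetaMatrix] = []
    counter = 0
    for g in graphs:
        if keep is not None and not keep(g):
            continue
        sheet_id = f"{pdb_id.upper()}{chain}_SHEET_{counter:03d}"
        try:
            m = graph_to_matrix(g, sheet_id=sheet_id)
        except UnprojectableError as exc:
            logger.warning(
                "skipping unprojectable sheet in %s%s (%d residues): %s",
                pdb_id, chain, g.number_of_nodes(), exc,
            )
            continue
        if m.n_rows < min_strands:
            continue
        if max_strands is not None and m.n_rows > max_strands:
            continue
        m = BetaMatrix(
            sheet_id=sheet_id, rows=m.rows, source=f"{pdb_id.upper()}:{chain}"
        )
        out.append(m)
        counter += 1
    return out


def extract_from_dssp(
    source,
    pdb_id: str,
    chain: str | None = None,
    min_strands: int = 1,
    max_strands: int | None = None,
) -> list[BetaMatrix]:
    """End-to-end: DSSP file to β-matrices, optionally restricted to a chain."""
    residues = parse_dssp(source)
    if chain is not None:
        residues = [r for r in residues if r.chain == chain]
    graphs = build_beta_graphs(residues)
    out = []
    by_chain: dict[str, list[nx.Graph]] = {}
    for g in graphs:
        first = min(g.nodes)
        by_chain.setdefault(g.nodes[first]["chain"], []).append(g)
    for ch in sorted(by_chain):
        out.extend(
            extract_beta_matrices(
                by_chain[ch], pdb_id, ch,
                min_strands=min_strands, max_strands=max_strands,
            )
        )
    return out
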