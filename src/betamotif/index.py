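"""Construction and persistence of the D/R/C trimer indices.

Three mappings drive the search:

* ``D`` — inverted index from trimer id to the set of sheet ids containing
  at least one trimer with that id (the postings sets of the first filter).
* ``R`` — compound-key index over *row-spans*: one entry per row-span of
  every L- and V-trimer, keyed ``(matrix_id, id, eq_orients, coord, span)``.
  H-trimers have no row-spans and never appear here.
* ``C`` — the col-span counterpart: L- and H-trimers only.

``per_matrix`` keeps each sheet's trimers grouped by id (with an
``(id, coord)`` lookup) so candidate verification can locate a partner
trimer in constant time.

Persistence is a single JSON file storing the β-matrix records plus a
versioned manifest; the derived mappings are rebuilt deterministically on
load and checked against the manifest, so the index is limited only by disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

from .core import BetaMatrix, iter_beta_matrices, write_beta_matrix
from .errors import DuplicateSheetIdError, IndexIOError
from .trimers import H_CLASSES, V_CLASSES, Trimer, extract_trimers

FORMAT_NAME = "betamotif.index"
FORMAT_VERSION = 1

TrimerId = tuple[int, str]
SpanKey = tuple[str, TrimerId, int, tuple[int, int], tuple[int, int]]


@dataclass
class IndexTriple:
    """The D, R, C mappings plus per-matrix trimer listings and a manifest."""

    D: dict[TrimerId, set[str]] = field(default_factory=dict)
    R: dict[SpanKey, Trimer] = field(default_factory=dict)
    C: dict[SpanKey, Trimer] = field(default_factory=dict)
    per_matrix: dict[str, dict[TrimerId, list[Trimer]]] = field(default_factory=dict)
    by_id_coord: dict[str, dict[tuple[TrimerId, tuple[int, int]], list[Trimer]]] = field(
        default_factory=dict
    )
    matrices: dict[str, BetaMatrix] = field(default_factory=dict)
    order: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def n_matrices(self) -> int:
        return len(self.matrices)

    @property
    def n_trimers(self) -> int:
        return sum(
            len(ts) for groups in self.per_matrix.values() for ts in groups.values()
        )

    @property
    def n_distinct_ids(self) -> int:
        return len(self.D)

    def trimers_of(self, matrix_id: str) -> dict[TrimerId, list[Trimer]]:
        return self.per_matrix[matrix_id]


def build_indices(matrices: Iterable[BetaMatrix]) -> IndexTriple:
    """Index a collection of wildcard-free β-matrices.

    One pass per matrix over its trimers (each cell anchors at most six), so
    construction is linear in total sheet size. Duplicate sheet ids are
    rejected by name.
    """
    ix = IndexTriple()
    for m in matrices:
        if m.sheet_id in ix.matrices:
            raise DuplicateSheetIdError(f"duplicate sheet id {m.sheet_id!r}")
        if m.has_wildcards:
            raise ValueError(
                f"matrix {m.sheet_id!r} contains wildcards and cannot be indexed"
            )
        ix.matrices[m.sheet_id] = m
        ix.order.append(m.sheet_id)
        groups: dict[TrimerId, list[Trimer]] = {}
        coords: dict[tuple[TrimerId, tuple[int, int]], list[Trimer]] = {}
        for t in extract_trimers(m):
            tid = t.id
            ix.D.setdefault(tid, set()).add(m.sheet_id)
            groups.setdefault(tid, []).append(t)
            coords.setdefault((tid, t.coord), []).append(t)
            for kind, _line, span, _num in t.spans():
                key = (m.sheet_id, tid, t.eq_orients, t.coord, span)
                if kind == "row":
                    if t.cls not in H_CLASSES:
                        ix.R[key] = t
                else:
                    if t.cls not in V_CLASSES:
                        ix.C[key] = t
        ix.per_matrix[m.sheet_id] = groups
        ix.by_id_coord[m.sheet_id] = coords
    ix.manifest = _manifest(ix)
    return ix


def _manifest(ix: IndexTriple) -> dict:
    digest = hashlib.sha256("\n".join(ix.order).encode()).hexdigest()
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "n_matrices": ix.n_matrices,
        "n_trimers": ix.n_trimers,
        "n_distinct_ids": ix.n_distinct_ids,
        "n_row_entries": len(ix.R),
        "n_col_entries": len(ix.C),
        "order_sha256": digest,
    }


def save_indices(ix: IndexTriple, path) -> None:
    """Write the index to a single JSON file (records + manifest)."""
    payload = {
        "manifest": ix.manifest,
        "records": [write_beta_matrix(ix.matrices[i]) for i in ix.order],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=0, sort_keys=True)
        fh.write("\n")


def load_indices(path) -> IndexTriple:
    """Load an index file, rebuilding D/R/C and verifying the manifest."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except FileNotFoundError:
        raise IndexIOError(f"index file not found: {path}") from None
    except (OSError, json.JSONDecodeError) as exc:
        raise IndexIOError(f"unreadable index file {path}: {exc}") from exc
    manifest = payload.get("manifest")
    if not isinstance(manifest, dict) or manifest.get("format") != FORMAT_NAME:
        raise IndexIOError(f"{path} is not a betamotif index file")
    if manifest.get("version") != FORMAT_VERSION:
        raise IndexIOError(
            f"index version {manifest.get('version')} unsupported "
            f"(expected {FORMAT_VERSION})"
        )
    matrices = []
    for rec in payload.get("records", []):
        matrices.extend(iter_beta_matrices(rec))
    ix = build_indices(matrices)
    if ix.manifest != manifest:
        raise IndexIOError(f"corrupt index file {path}: manifest mismatch")
    return ix
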