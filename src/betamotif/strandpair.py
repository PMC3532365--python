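"""β-strand pairing prediction by 4-mer hit scoring.

Which strands of a sheet pair with which? Each candidate strand pair is
scored by sliding one strand along the other and, for every *4-mer* (a 2×2
β-matrix: two consecutive bridge-paired residue columns) of every alignment,
counting how many indexed sheets contain that 4-mer in parallel
(``h_P``, rows as read) and antiparallel (``h_A``, second row reversed)
register. Hit counts are averaged per 4-mer and penalized by the logarithm
of the sequence separation:

    S_P(i,j) = (Σ h_P) / M − ln(seq_sep(i,j))
    S_A(i,j) = (Σ h_A) / M − ln(seq_sep(i,j))
    score(i,j) = S_P(i,j) + S_A(i,j)

where ``M`` is the number of 4-mers evaluated. For an n-strand planar,
non-barreled, non-bifurcated sheet the top ``n − 1`` scores are the
predicted pairings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import BetaMatrix
from .index import IndexTriple
from .query import search

#: Minimum aligned overlap (in columns) for an alignment to contribute.
MIN_OVERLAP = 2


@dataclass(frozen=True)
class StrandPairScore:
    """Pairing evidence for one strand pair (i, j)."""

    i: int
    j: int
    s_p: float  #: parallel score after normalization
    s_a: float  #: antiparallel score after normalization
    m: int  #: number of 4-mers evaluated across all alignments
    h_p: int  #: accumulated parallel hit count
    h_a: int  #: accumulated antiparallel hit count
    seq_sep: int

    @property
    def has_evidence(self) -> bool:
        return self.m > 0

    @property
    def total(self) -> float:
        """score(i, j); ``-inf`` when no 4-mer was evaluable (ranked last)."""
        if not self.has_evidence:
            return float("-inf")
        return self.s_p + self.s_a


def extract_4mers(row1: str, row2: str) -> list[tuple[str, str]]:
    """The 4-mers of two aligned equal-length residue strings.

    One 4-mer per consecutive column pair: ``("ABC", "DEF")`` yields
    ``[("AB", "DE"), ("BC", "EF")]``; an overlap of length L yields L − 1.
    """
    if len(row1) != len(row2):
        raise ValueError("aligned strand segments must have equal length")
    return [(row1[k:k + 2], row2[k:k + 2]) for k in range(len(row1) - 1)]


def sequence_separation(start_i: int, len_i: int, start_j: int, len_j: int) -> int:
    """Residues strictly between two strands in chain order, floored at 1."""
    if start_i > start_j:
        start_i, len_i, start_j, len_j = start_j, len_j, start_i, len_i
    return max(1, start_j - (start_i + len_i))


def _query_4mer(top: str, bottom: str, ix: IndexTriple, cache: dict) -> int:
    key = (top, bottom)
    hits = cache.get(key)
    if hits is None:
        q = BetaMatrix(sheet_id="4mer", rows=(top, bottom))
        hits = len(search(q, ix))
        cache[key] = hits
    return hits


def score_strand_pair(
    strand_i: str,
    strand_j: str,
    start_i: int,
    start_j: int,
    ix: IndexTriple,
    pair: tuple[int, int] = (0, 1),
    _cache: dict | None = None,
) -> StrandPairScore:
    """Score one candidate strand pair against an index.

    Every integer offset of ``strand_j`` against ``strand_i`` with an
    aligned overlap of at least two columns is enumerated; the antiparallel
    register is probed inside each 4-mer query by reversing the second row
    rather than by enumerating reversed alignments. ``start_i``/``start_j``
    are the strands' first residue positions in the chain (for the
    sequence-separation penalty).
    """
    if _cache is None:
        _cache = {}
    li, lj = len(strand_i), len(strand_j)
    sum_p = sum_a = m_count = 0
    for offset in range(-(lj - MIN_OVERLAP), li - MIN_OVERLAP + 1):
        lo = max(0, offset)
        hi = min(li, offset + lj)
        if hi - lo < MIN_OVERLAP:
            continue
        top = strand_i[lo:hi]
        bottom = strand_j[lo - offset:hi - offset]
        for t4, b4 in extract_4mers(top, bottom):
            sum_p += _query_4mer(t4, b4, ix, _cache)
            sum_a += _query_4mer(t4, b4[::-1], ix, _cache)
            m_count += 1
    sep = sequence_separation(start_i, li, start_j, lj)
    if m_count == 0:
        return StrandPairScore(
            i=pair[0], j=pair[1], s_p=math.nan, s_a=math.nan,
            m=0, h_p=0, h_a=0, seq_sep=sep,
        )
    penalty = math.log(sep)
    return StrandPairScore(
        i=pair[0], j=pair[1],
        s_p=sum_p / m_count - penalty,
        s_a=sum_a / m_count - penalty,
        m=m_count, h_p=sum_p, h_a=sum_a, seq_sep=sep,
    )


def predict_pairs(
    strands: list[tuple[str, int]],
    ix: IndexTriple,
) -> list[tuple[StrandPairScore, bool]]:
    """Score all strand pairs and flag the predicted pairings.

    ``strands`` is a list of ``(sequence, start_position)`` in chain order.
    All n·(n−1)/2 pairs are scored; the top n − 1 by total score are flagged
    as predictions (one pairing per strand adjacency in a planar sheet).
    Ties and no-evidence pairs rank by pair index, deterministically.
    """
    n = len(strands)
    if n < 2:
        raise ValueError("need at least two strands")
    cache: dict = {}
    scores = []
    for i in range(n):
        for j in range(i + 1, n):
            si, pi = strands[i]
            sj, pj = strands[j]
            scores.append(
                score_strand_pair(si, sj, pi, pj, ix, pair=(i, j), _cache=cache)
            )
    ranked = sorted(scores, key=lambda s: (-s.total, s.i, s.j))
    predicted = {(s.i, s.j) for s in ranked[: n - 1]}
    return [(s, (s.i, s.j) in predicted) for s in scores]
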