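"""Filtering, congruence, pair matching, verification, and the oracle."""

import numpy as np
import pytest

import betamotif as bm
from betamotif import MalformedQueryError
from betamotif.datagen import GenConfig, gen_matrices, gen_query
from betamotif.query import (
    CandidateSets,
    expand_wildcards,
    first_filter,
    make_query_graph,
    match_pairs,
    naive_match,
    preprocess_query,
    search,
    search_detailed,
    second_filter,
    span_overlaps,
    verify_candidate,
)
from betamotif.trimers import extract_trimers

from conftest import bmat


class TestPreprocess:
    def test_single_trimer_query(self):
        q = preprocess_query(bmat("GAV"))
        assert len(q.trimers) == 1 and q.edges == []

    def test_dense_2x3_connected(self):
        q = preprocess_query(bmat("ABC", "DEF"))
        assert len(q.trimers) == 10
        assert len(q.edges) > 0  # connectivity asserted by construction

    def test_split_strand_rejected(self):
        with pytest.raises(MalformedQueryError):
            preprocess_query("> q\nA.C\n")

    def test_too_small_query_rejected(self):
        with pytest.raises(MalformedQueryError):
            preprocess_query(bmat("AC"))

    def test_record_text_accepted(self):
        q = preprocess_query("> q\nGAV\n")
        assert q.matrix.sheet_id == "q"


class TestWildcardExpansion:
    def test_one_wildcard_expands_to_twenty(self):
        q = preprocess_query(bmat("G*V"))
        expanded = expand_wildcards(q)
        assert len(expanded) == 20
        assert {e.matrix.rows[0][1] for e in expanded} == set(bm.AMINO_ACIDS)

    def test_no_wildcard_is_identity(self):
        q = preprocess_query(bmat("GAV"))
        assert expand_wildcards(q) == [q]

    def test_expansion_cap(self):
        q = preprocess_query(bmat("A**", "***"))
        with pytest.raises(ValueError, match="cap"):
            expand_wildcards(q)

    def test_union_equals_wildcard_oracle(self, small_corpus, small_index):
        rng = np.random.default_rng(11)
        checked = 0
        for m in small_corpus[:8]:
            q = gen_query(m, 6, rng, wildcard=True)
            if q is None:
                continue
            union = set()
            for concrete in expand_wildcards(q):
                union |= search_detailed(concrete, small_index).hits
            oracle = {
                c.sheet_id for c in small_corpus if naive_match(q.matrix, c)
            }
            assert union == oracle
            checked += 1
        assert checked >= 4


class TestFirstFilter:
    def test_verbatim_query_is_candidate(self, small_corpus, small_index):
        m = small_corpus[0]
        q = preprocess_query(m)
        assert m.sheet_id in first_filter(q, small_index)

    def test_unknown_trimer_id_empties_c1(self, small_index):
        q = preprocess_query(bmat("WWW", "WWW"))
        if not any(t.id in small_index.D for t in q.trimers):
            assert first_filter(q, small_index) == set()

    def test_intersection_by_hand(self):
        # m1 has ids of both GAV and AVL windows; m2 only GAV.
        ix = bm.build_indices(
            [bmat("GAVL", sheet_id="m1"), bmat("GAV", sheet_id="m2")]
        )
        q = preprocess_query(bmat("GAVL"))
        assert first_filter(q, ix) == {"m1"}


class TestCongruence:
    def test_identity_reflection_feasible_on_source(self):
        m = bmat("ACD", "EFG", sheet_id="src")
        ix = bm.build_indices([m])
        q = preprocess_query(m)
        mask = bm.congruent(q, "src", ix)
        assert mask & 1

    @pytest.mark.parametrize("g", [1, 2, 3])
    def test_reflected_candidate_feasible(self, g):
        m = bmat("ACD", "EFG", sheet_id="src")
        ix = bm.build_indices([bm.reflect_matrix(m, g)])
        q = preprocess_query(m)
        mask = bm.congruent(q, "src", ix)
        assert mask >> g & 1

    def test_incompatible_orientations_rejected(self):
        # Candidate contains both query trimer ids but in mutually
        # incompatible orientations: no single global reflection works.
        q = preprocess_query(bmat("AC", "DF"))
        # The L-trimers of the query pin down the relative orientation;
        # build a candidate with the same trimer ids arranged differently.
        cand = bmat("CA", "DF", sheet_id="c")
        ix = bm.build_indices([cand])
        c1 = first_filter(q, ix)
        if "c" in c1:
            assert bm.congruent(q, "c", ix) == 0

    def test_second_filter_subset_and_identity(self, small_corpus, small_index):
        m = small_corpus[3]
        q = preprocess_query(m)
        c1 = first_filter(q, small_index)
        c2 = second_filter(q, c1, small_index)
        assert set(c2) <= c1
        assert m.sheet_id in c2


class TestQueryGraph:
    def test_single_vertex_no_edges(self):
        assert make_query_graph(extract_trimers(bmat("GAV"))) == []

    def test_two_h_trimers_share_colspan(self):
        trimers = extract_trimers(bmat("GAVL"))
        edges = make_query_graph(trimers)
        assert len(trimers) == 2 and len(edges) == 1
        (_, _, desc) = edges[0]
        assert all(kind == "col" for kind, *_ in desc.overlaps)

    def test_edges_match_all_pairs_overlap_oracle(self):
        trimers = extract_trimers(bmat("ABC", "DEF"))
        edges = {(i, j) for i, j, _ in make_query_graph(trimers)}
        brute = {
            (i, j)
            for i in range(len(trimers))
            for j in range(i + 1, len(trimers))
            if span_overlaps(trimers[i], trimers[j])
        }
        assert edges == brute

    def test_rel_offset_bounded(self):
        for _, _, desc in make_query_graph(extract_trimers(bmat("ACDE", "FGHI"))):
            dr, dc = desc.rel_offset
            assert abs(dr) <= 2 and abs(dc) <= 2


class TestMatchPairs:
    def _pair(self, m):
        trimers = extract_trimers(m)
        edges = make_query_graph(trimers)
        i, j, desc = edges[0]
        return trimers[i], trimers[j], desc

    def test_pair_matches_itself_identity(self):
        a, b, desc = self._pair(bmat("ACD", "EFG"))
        assert match_pairs(a, b, a, b, 0, desc)

    @pytest.mark.parametrize("g", [1, 2, 3])
    def test_pair_matches_reflected_image(self, g):
        m = bmat("ACD", "EFG", sheet_id="src")
        q = preprocess_query(m)
        ix = bm.build_indices([bm.reflect_matrix(m, g)])
        assert verify_candidate(q, "src", ix)

    def test_different_overlap_type_rejected(self):
        a, b, desc = self._pair(bmat("GAVL"))
        # Vertical arrangement of the same residues: same ids, col-spans
        # replaced by row-spans.
        col = bmat("G", "A", "V", "L")
        ta, tb = extract_trimers(col)[:2]
        for g in range(4):
            assert not match_pairs(a, b, ta, tb, g, desc)


class TestVerification:
    def test_source_matrix_verifies(self, small_corpus, small_index):
        m = small_corpus[5]
        q = preprocess_query(m)
        assert verify_candidate(q, m.sheet_id, small_index)

    def test_filtered_nonmatches_rejected_by_verification(self):
        # Oracle-guided counterexample search on random small sheets over a
        # narrow alphabet: collect candidates that contain every query
        # trimer id congruently (surviving both filters) yet contain no
        # actual occurrence; verification must reject each of them.
        rng = np.random.default_rng(4)
        aa = np.array(list("ADG"))
        found = 0
        for trial in range(300):
            rows = tuple(
                "".join(rng.choice(aa, size=4)) for _ in range(3)
            )
            cand = bmat(*rows, sheet_id="c")
            ix = bm.build_indices([cand])
            qm = gen_query(cand, int(rng.integers(3, 8)), rng, wildcard=False)
            if qm is None:
                continue
            # Mutate one query cell so the motif usually no longer occurs.
            r = int(rng.integers(qm.matrix.n_rows))
            row = qm.matrix.rows[r]
            idx = [i for i, ch in enumerate(row) if ch != bm.GAP]
            i = idx[int(rng.integers(len(idx)))]
            mutated = bmat(
                *(
                    row[:i] + str(rng.choice(aa)) + row[i + 1:] if rr == r else x
                    for rr, x in enumerate(qm.matrix.rows)
                ),
                sheet_id="q",
            )
            try:
                q = preprocess_query(mutated)
            except MalformedQueryError:
                continue
            masks = second_filter(q, first_filter(q, ix), ix)
            if "c" not in masks or naive_match(mutated, cand):
                continue
            found += 1
            assert not verify_candidate(q, "c", ix, masks["c"])
        assert found >= 5  # the filter alone really does admit non-matches

    def test_single_trimer_query_short_circuits(self):
        m = bmat("GAV", sheet_id="s")
        ix = bm.build_indices([m])
        q = preprocess_query(bmat("GAV"))
        cs = CandidateSets()
        assert verify_candidate(q, "s", ix, stats=cs)
        assert cs.n_match_pairs == 0  # no pair checks for 2-edge queries


class TestSearch:
    def test_absent_query_returns_empty(self, small_index):
        assert search(bmat("WYW", "YWY"), small_index) in ([], list())

    def test_monotone_pipeline(self, small_corpus, small_index):
        rng = np.random.default_rng(23)
        for m in small_corpus[:10]:
            q = gen_query(m, 6, rng, wildcard=False)
            if q is None:
                continue
            cs = search_detailed(q, small_index)
            assert cs.hits <= cs.C2 <= cs.C1
            assert m.sheet_id in cs.hits

    def test_agreement_with_oracle_on_random_instances(self):
        # Many small random datasets and queries; search must equal the
        # sliding-window oracle exactly (soundness and completeness).
        rng = np.random.default_rng(99)
        mismatches = 0
        n_checked = 0
        for trial in range(60):
            cfg = GenConfig(
                n_matrices=12, n_rows=(2, 4), n_cols=(3, 7),
                seed=int(rng.integers(2**31)),
            )
            mats = gen_matrices(cfg)
            ix = bm.build_indices(mats)
            for m in mats[:3]:
                size = int(rng.integers(2, 11))
                q = gen_query(m, size, rng, wildcard=bool(rng.integers(2)))
                if q is None:
                    continue
                hits = set(search(q, ix))
                truth = {c.sheet_id for c in mats if naive_match(q.matrix, c)}
                n_checked += 1
                if hits != truth:
                    mismatches += 1
        assert n_checked > 100
        assert mismatches == 0

    def test_strict_mode_equals_default_here(self, small_corpus, small_index):
        m = small_corpus[7]
        q = preprocess_query(m)
        assert search(q, small_index, strict=True) == search(q, small_index)

    def test_work_scaling_quadratic_bound(self, small_corpus, small_index):
        rng = np.random.default_rng(31)
        for m in small_corpus[:10]:
            q = gen_query(m, 8, rng, wildcard=False)
            if q is None:
                continue
            cs = search_detailed(q, small_index)
            n = len(q.trimers)
            # At most |feasible g| * |edges| * same-id collisions; on random
            # residues collisions are rare, so 8 n^2 is a generous constant.
            assert cs.n_match_pairs <= 8 * n * n * max(1, len(cs.C2))


class TestNaiveMatch:
    def test_submatrix_matches(self):
        m = bmat("ACDE", "FGHI")
        assert naive_match(bmat("CD", "GH"), m)

    def test_oversized_query_rejected(self):
        assert not naive_match(bmat("ACDE", "FGHI", "ACDE"), bmat("AC", "DE"))

    def test_wildcard_matches_residue_not_gap(self):
        m = bmat("AC.", ".DE")
        assert naive_match(bmat("A*"), m)
        assert not naive_match(bmat("*", "*", "*"), m)

    @pytest.mark.parametrize("g", [0, 1, 2, 3])
    def test_reflections_matched(self, g):
        m = bmat("ACD", "EFG")
        assert naive_match(bm.reflect_matrix(m, g), m)
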