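# Methods

## Sheet model and its assumptions

A β-sheet is modelled as a bulge-free planar grid: each strand is one row
of contiguous cells, and the bridge-partner relation is exactly vertical
adjacency between non-gap cells of neighbouring rows. The equivalent graph
view (peptide + bridge edges, degree ≤ 4) is convertible both ways:
`matrix_to_graph` expands adjacency into typed edges, and
`graph_to_matrix` performs the topological-sort projection — strands are
ordered along the strand-adjacency path and each strand is anchored on its
bridges to the previous row, trying both backbone directions and accepting
a placement only if bridges and vertical adjacencies coincide exactly.
Sheets violating the model are *unprojectable* and are skipped (never
fatal): bifurcated sheets (a strand with three or more bridged
neighbours), barrels (cyclic strand adjacency), and register conflicts
(two bridges implying two different columns for one residue). β-bulges
are not given special treatment; a bulged sheet survives extraction iff
its bridge pattern still projects consistently.

Matrices are indexed in a single canonical orientation: among the four
reflection states, the one with the lexicographically smallest rows. Any
deterministic choice would do — filtering and verification are
reflection-blind — but canonicalization makes index construction and tests
reproducible regardless of extraction orientation.

Cell alphabet: uppercase A–Z. The canonical 20 amino acids are what the
generator emits and what wildcard expansion substitutes, but parsing and
indexing deliberately accept the wider range so nonstandard one-letter
codes coming out of structure pipelines (B, X, Z, lowercase SS-bonded
cysteines mapped to C) do not abort extraction.

## Trimer conventions

The orientation numbering of trimers is not uniquely determined by the
algebra it must satisfy (the XOR reflection law and the equivalence
groups); the convention fixed and test-locked here is:

* reading order — V: top-to-bottom; H: left-to-right; L: vertical-arm
  endpoint, corner, horizontal-arm endpoint;
* L-trimer orientation — bit 0 set iff the horizontal arm extends left,
  bit 1 set iff the vertical arm extends up, which makes the reflection
  law (`⊕1` for y-flips, `⊕2` for x-flips) hold by construction;
* V/H orientation — 0 if `seq[0] ≤ seq[2]`, else 2 (V) or 1 (H), matching
  the lexicographic branches of the equivalence-mask table
  ({0,1}/{2,3} for V, {0,2}/{1,3} for H, singleton for L, 15 for
  symmetric trimers);
* canonical id — V/H use `min(seq, reversed seq)`; L uses the reading
  order itself (its four orientations are geometrically distinct).
  Ids are therefore reflection-invariant, which is what makes the first
  filter reflection-blind.

Lexicographic comparisons are plain ASCII on uppercase letters.

Matrices with fewer than three residue cells index no trimers and are
consequently unreachable by queries; they are stored but inert.

## Index layout

`R` holds one entry per row-span (so L-trimers once, V-trimers twice) and
`C` one entry per col-span (L once, H twice); H-trimers never enter `R`
nor V-trimers `C`, since they have no spans of that kind. Persistence
writes the β-matrix records and a versioned manifest (counts plus an
order checksum) to one JSON file and rebuilds the derived mappings on
load; a manifest mismatch is reported as corruption. Verification reaches
candidate trimers through per-sheet listings grouped by id with an
`(id, coordinate)` lookup — the same content as the `R`/`C` compound keys,
arranged for O(1) partner location.

## Verification semantics

Pair matching is implemented literally as per-edge existential matching:
for a fixed global reflection `g` (feasible values tried in ascending
order), every query-graph edge must be matched by *some* candidate trimer
pair with the right orientations (a bit test against `eq-orients`), the
`g`-transformed relative offset (Δcol negated when `g` has bit 0, Δrow
when bit 1), and the same span-overlap descriptor (span numbers relabelled
per class, since an x-flip swaps a V-trimer's spans and a y-flip an
H-trimer's). This is weaker in principle than exhibiting one consistent
embedding, so `search(..., strict=True)` re-confirms every hit against
the sliding-window oracle and logs any discrepancy. Across all seeded
test workloads (tens of thousands of query/candidate decisions, plus an
adversarial narrow-alphabet counterexample search) no discrepancy has
been observed; the strict mode remains as the safety net.

Degenerate cases: single-trimer queries (2-edge motifs) are fully decided
by filtering and verify trivially; disconnected queries are rejected as
malformed (a motif is by definition connected, and a disconnected query
graph would make the per-edge conjunction vacuous); wildcard cells take
part in connectivity but never in trimers — each of the ≤ 400 concrete
expansions (configurable cap) is preprocessed and searched independently
and the hit set is their union.

## Synthetic data: what it emulates, what it does not

`GenConfig` defaults are the study conditions used throughout the tests
and the acceptance script: 200 sheets per corpus, 2–6 strands, strand
lengths 4–12 (the `n_cols` range bounds per-strand length; total width is
emergent from the ±2-column register jitter), residues i.i.d. uniform
over the 20 amino acids (a natural-frequency mode with a built-in
background table is available), seed 42. Queries follow the benchmark
protocol: a random breadth-first traversal from a random root grown until
the induced motif has the requested edge count (2–10), one randomly
placed wildcard, guaranteed by construction to match its source sheet.

The generator emulates the size and register statistics of extracted
sheets but not their biology: no residue-pairing correlations, no
β-bulges, no barrels, no homology-induced redundancy between sheets.
Passing the retrieval acceptance (F1 = 1.0 vs the oracle) therefore
demonstrates algorithmic exactness of filter + verify, not anything about
biological discrimination; conversely the strand-pairing recovery test
plants its signal explicitly and shows the scorer retrieves enrichment,
not that natural pairing preferences are learned.

## Strand-pairing scorer choices

Open details fixed here, documented and test-locked: the logarithm is
natural; `seq_sep` is the count of residues strictly between the two
strands in chain order, floored at 1 (so the penalty is ≥ 0 and defined);
alignments enumerate all integer offsets with overlap ≥ 2 without
reversal, the antiparallel register being probed inside each 4-mer query
by reversing the second row (querying both orientations of the 4-mer
rather than doubling the alignment set); a hit count is the number of
distinct matching sheets returned by search. Pairs with no evaluable
4-mer (`M = 0`) carry no evidence and rank last. `predict_pairs` returns
the top n−1 of the n(n−1)/2 scored pairs — the correct pairing count for
a planar, non-barreled, non-bifurcated sheet, which is the only topology
the predictor targets.

## Numerical and engineering choices

* All randomness flows through `numpy.random.Generator`; a config seed
  fixes the full output stream, and derived streams use `SeedSequence`
  spawning so corpus and workload are independently reproducible.
* Benchmark reports serialize deterministically (sorted keys, timings
  excluded unless requested) and are byte-identical across runs with one
  seed; timings are measured but reported separately.
* Filtering precision is accounted per concrete query (wildcard
  expansions counted individually, as when expansion is done for the
  benchmark protocol): total verified hits over total candidates
  surviving both filters.
* Problem sizes in the shipped tests — 200-sheet corpora for retrieval,
  10,000 sheets for the geometry sweep, 1,000 reflection-invariance
  trials, 100 planted-pairing trials — were chosen as the smallest scales
  at which the properties are meaningfully exercised while keeping the
  default suite comfortably interactive.

## Known limitations

* Sheets that defeat the planar bulge-free model (barrels, bifurcations,
  severe bulges) are skipped at extraction; there is no planarity score,
  only a structural projection test plus an optional user-supplied sheet
  filter and strand-count bounds.
* Exact matching only: no substitution-matrix similarity, no gapped or
  approximate queries, no ranking of hits.
* The per-edge existential verification could in principle admit a
  non-embedding candidate (see above); strict mode exists for users who
  need a hard guarantee.
* The DSSP reader supports the classic fixed-column format only, not
  mmCIF-style DSSP output.
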