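# betamotif

Exact-match indexing and querying of **β-residue motifs** — connected
clusters of β-sheet residues linked by peptide bonds and interstrand
bridge-partner (hydrogen-bond) relationships.

β-sheets are nearly planar, so instead of treating motif search as subgraph
isomorphism over residue graphs, `betamotif` flattens each sheet onto a 2D
grid of amino acids (a *β-matrix*): every strand is a row and bridge
partners share a column. Motifs become submatrices, and search reduces to
2D pattern matching under the sheet's four reflection symmetries — which
this package performs with an inverted index over 3-residue path features
(*trimers*), bitwise orientation filtering, and a quadratic-time
verification step. No subgraph-isomorphism test is ever run.

Intended users: structural bioinformaticians doing high-volume exploratory
querying of sheet substructures (binding-site motifs, ladder motifs,
strand-register patterns) across large structure collections, and anyone
needing a fast strand-pairing prior.

## Method

**Trimers.** Every L-, V-, or H-shaped path of three mutually adjacent
residue cells is a feature `t` with

- `t.seq` — the three residues in reading order;
- `t.class ∈ {1, 3, 5, 15, 31}` — L; asymmetric V; asymmetric H; symmetric
  V (`seq[0] = seq[2]`); symmetric H;
- `t.orient ∈ {0..3}` — a 2-bit orientation chosen so that reflecting the
  sheet in the y-axis maps `orient → orient ⊕ 1` and in the x-axis
  `orient → orient ⊕ 2`;
- `t.eq-orients` — a 4-bit mask of orientations physically
  indistinguishable for that trimer (e.g. a symmetric V-trimer is blind to
  every reflection: mask 15);
- row/column spans — the unit-length intervals its arms cover, used for
  geometric verification.

**Indices.** `D` maps each trimer id to the set of sheets containing it;
`R` and `C` key every row-span and col-span of each trimer by
`(sheet, id, eq-orients, coordinate, span)`. Each cell anchors at most six
trimers, so indexing is linear in total sheet size.

**Search.** A query β-matrix is filtered by (1) intersecting the postings
of all its trimer ids, smallest set first, and (2) *congruence*: a single
global reflection `g` must reconcile every query trimer's orientation with
a same-id candidate trimer, computed purely with 4-bit masks — neither the
index nor the query ever enumerates reflected copies. Survivors are
verified edge-by-edge on the query's trimer-overlap graph: each edge must
be realized by a candidate trimer pair with the same span-overlap geometry
after transforming offsets by `g`. Queries may contain `*` wildcard cells,
expanded over the 20 amino acids.

**Strand pairing.** Candidate strand pairs (i, j) are scored by sliding one
strand along the other and counting indexed occurrences of every *4-mer*
(two consecutive bridge-paired columns) in parallel (`h_P`) and
antiparallel (`h_A`) register:

    S^P_ij = (Σ h_P)/M_ij − ln seq_sep(i,j)
    S^A_ij = (Σ h_A)/M_ij − ln seq_sep(i,j)
    score(i,j) = S^P_ij + S^A_ij

with `M_ij` the number of 4-mers evaluated. For an n-strand planar sheet
the top n−1 scores are the predicted pairings.

## Worked example

```python
import betamotif as bm

sheet = bm.parse_beta_matrix("> demo\nABC\nDEF\n")
print(len(bm.extract_trimers(sheet)))   # 10   (8 L + 2 H trimers)

ix = bm.build_indices([sheet])
print(len(ix.D))                        # 10   distinct trimer ids

flipped = bm.reflect_matrix(sheet, 3)   # index stores one arbitrary
ix2 = bm.build_indices([flipped])       # orientation per sheet...
print(bm.search("> q\nBC\nEF\n", ix2))  # ['demo']  ...hits are unchanged
```

The query `BC/EF` is a 2×2 submatrix of the sheet; it is retrieved even
though the indexed copy was stored rotated 180°, because filtering and
verification reason over reflections with bitmasks rather than stored
copies.

From the shell:

```sh
betamotif gen --n 200 --seed 42 -o corpus.bmat
betamotif index -i corpus.bmat -o corpus.index
# indexed 200 matrices, 19425 trimers, 10595 distinct trimer ids -> corpus.index
betamotif query -d corpus.index -q queries.bmat --stats
betamotif extract --dssp protein.dssp --pdb-id 1UBQ -o sheets.bmat
betamotif pairs -d corpus.index --sheet corpus.bmat:SYN_SHEET_00007
betamotif bench --seed 42
```

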