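import numpy as np
import pytest

from betamotif import BetaMatrix, GenConfig, build_indices, gen_matrices


def bmat(*rows, sheet_id="m"):
    """Shorthand matrix constructor for tests."""
    return BetaMatrix(sheet_id=sheet_id, rows=tuple(rows))


def dssp_line(idx, resnum, chain, aa, ss, bp1=0, bp2=0, sheet=" "):
    """Render one residue row in classic DSSP fixed columns.

    Synthetic fixture helper; columns follow the standard layout the parser
    reads (index 0:5, resnum 5:10, chain 11, aa 13, ss 16, bp1 25:29,
    bp2 29:33, sheet label 33).
    """
    line = f"{idx:5d}{resnum:5d} {chain} {aa}  {ss}" + " " * 8
    line += f"{bp1:4d}{bp2:4d}{sheet}"
    return line + " " * 6


def make_dssp(rows):
    """A minimal synthetic classic-format DSSP document."""
    header = [
        "==== Secondary Structure Definition (synthetic fixture) ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  SHEET",
    ]
    return "\n".join(header + rows) + "\n"


@pytest.fixture(scope="session")
def small_corpus():
    """A seeded 40-sheet synthetic corpus shared across tests."""
    return gen_matrices(GenConfig(n_matrices=40, seed=1234))


@pytest.fixture(scope="session")
def small_index(small_corpus):
    return build_indices(small_corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
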