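import numpy as np
import pytest

from terminome.alphabet import AMINO_ACIDS, N_AA, N_POSITIONS
from terminome.specificity import SpecificityMatrix
from terminome.terminome import CleavageEvent, TerminomeMatrix


def random_specificity(rng, protease_id="px", concentration=0.5):
    """A random valid specificity matrix with Dirichlet columns."""
    cols = rng.dirichlet(np.full(N_AA, concentration), size=N_POSITIONS).T
    return SpecificityMatrix(protease_id=protease_id, matrix=cols)


def random_terminome(rng, group="G"):
    cols = rng.dirichlet(np.ones(N_AA), size=N_POSITIONS).T
    return TerminomeMatrix(group=group, matrix=cols)


def sample_contexts(rng, matrix, n, weight=1.0):
    """Independent oracle: n iid cleavage contexts drawn column-wise from a matrix.

    Residues at the four positions are sampled independently from the matrix's
    position columns, which is exactly the product model the frequency
    accumulation should invert.
    """
    idx = [rng.choice(N_AA, size=n, p=matrix[:, j]) for j in range(N_POSITIONS)]
    return [
        CleavageEvent(
            protein_id="oracle",
            cleaved_bond_position=2,
            p2=AMINO_ACIDS[idx[0][e]],
            p1=AMINO_ACIDS[idx[1][e]],
            p1prime=AMINO_ACIDS[idx[2][e]],
            p2prime=AMINO_ACIDS[idx[3][e]],
            weight=weight,
        )
        for e in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
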