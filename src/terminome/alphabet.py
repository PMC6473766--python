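"""Canonical residue alphabet and cleavage-site position labels.

All matrices in this package are indexed by the 20 canonical amino acids in
alphabetical one-letter order (rows) and by the four positions flanking a
cleaved peptide bond (columns). Following the Schechter-Berger convention,
positions P2 and P1 lie N-terminal of the scissile bond and P1' and P2'
C-terminal of it; the bond is cleaved between P1 and P1'. Primes are
serialized as a trailing ``p`` (``P1p``, ``P2p``) so files stay ASCII.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = len(AMINO_ACIDS)

POSITIONS: tuple[str, str, str, str] = ("P2", "P1", "P1p", "P2p")
POSITION_INDEX: dict[str, int] = {p: i for i, p in enumerate(POSITIONS)}
N_POSITIONS: int = len(POSITIONS)

#: Letters that appear in real sequence data but have no row in a 20x4 matrix.
NONSTANDARD_LETTERS: frozenset[str] = frozenset("BJOUXZ")


def is_canonical(seq: str) -> bool:
    """Return True if every letter of ``seq`` is one of the 20 canonical residues."""
    return bool(seq) and all(c in AA_INDEX for c in seq)


def encode(seq: str) -> "list[int]":
    """Map a residue string to row indices; raises ``KeyError`` on unknown letters."""
    return [AA_INDEX[c] for c in seq]
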