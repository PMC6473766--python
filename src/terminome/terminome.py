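"""Observed cleavage contexts and the abundance-weighted terminome matrix.

Each quantified peptide implies up to two cleavage events: one at the bond
that released its N-terminus and one at the bond that released its
C-terminus. The four residues around each bond (P2, P1 | P1', P2') form a
cleavage context; weighting contexts by normalized peptide abundance and
accumulating residue frequencies per position gives the group-level observed
matrix that the deconvolution stage fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, N_POSITIONS, POSITION_INDEX, POSITIONS
from .peptidome import QuantTable
from .specificity import COLUMN_SUM_TOL, normalize_columns

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleavageEvent:
    """One inferred cleavage with its Schechter-Berger context.

    ``cleaved_bond_position`` is the 1-based index p of the bond between
    residues p and p+1; P1 is residue p and P1' is residue p+1. ``terminus``
    records which peptide end generated the event ("N" or "C").
    """

    protein_id: str
    cleaved_bond_position: int
    p2: str
    p1: str
    p1prime: str
    p2prime: str
    weight: float
    terminus: str = "N"

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("cleavage event weight must be nonnegative")
        if self.terminus not in ("N", "C"):
            raise ValueError(f"terminus must be 'N' or 'C', got {self.terminus!r}")
        for residue in (self.p2, self.p1, self.p1prime, self.p2prime):
            if residue not in AA_INDEX:
                raise ValueError(f"non-canonical residue {residue!r} in cleavage context")

    @property
    def context(self) -> tuple[str, str, str, str]:
        """Residues in column order (P2, P1, P1', P2')."""
        return (self.p2, self.p1, self.p1prime, self.p2prime)


@dataclass(frozen=True)
class TerminomeMatrix:
    """Observed 20x4 cleavage-context frequency matrix for one sample group."""

    group: str
    matrix: np.ndarray
    total_weight: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_AA, N_POSITIONS):
            raise ValueError(f"terminome matrix has shape {m.shape}, expected {(N_AA, N_POSITIONS)}")
        if (m < 0).any():
            raise ValueError("negative entries in terminome matrix")
        if not np.allclose(m.sum(axis=0), 1.0, rtol=0.0, atol=COLUMN_SUM_TOL):
            raise ValueError("terminome matrix columns must sum to 1")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(AMINO_ACIDS), columns=list(POSITIONS))


def map_peptide(protein_seq: str, peptide_seq: str) -> list[tuple[int, int]]:
    """All exact occurrences of the peptide, as 1-based inclusive spans.

    Overlapping occurrences are all reported; an absent peptide yields [].
    """
    spans: list[tuple[int, int]] = []
    start = protein_seq.find(peptide_seq)
    while start != -1:
        spans.append((start + 1, start + len(peptide_seq)))
        start = protein_seq.find(peptide_seq, start + 1)
    return spans


def extract_contexts(
    protein_seq: str, start: int, end: int, weight: float, *, protein_id: str = ""
) -> list[CleavageEvent]:
    """Cleavage events implied by a peptide occupying [start, end] (1-based).

    The N-terminal event sits at the bond (start-1, start), the C-terminal
    event at (end, end+1). An event is emitted only when all four context
    residues lie inside the protein, so contexts truncated by the protein
    terminus are dropped (a mature terminus is not a cleavage observation).
    """
    n = len(protein_seq)
    if not (1 <= start <= end <= n):
        raise ValueError(f"span ({start}, {end}) out of range for protein of length {n}")
    events: list[CleavageEvent] = []
    # N-terminal bond: P2 = start-2, P1 = start-1, P1' = start, P2' = start+1
    if start - 2 >= 1 and start + 1 <= n:
        events.append(
            CleavageEvent(
                protein_id=protein_id,
                cleaved_bond_position=start - 1,
                p2=protein_seq[start - 3],
                p1=protein_seq[start - 2],
                p1prime=protein_seq[start - 1],
                p2prime=protein_seq[start],
                weight=weight,
                terminus="N",
            )
        )
    # C-terminal bond: P2 = end-1, P1 = end, P1' = end+1, P2' = end+2
    if end - 1 >= 1 and end + 2 <= n:
        events.append(
            CleavageEvent(
                protein_id=protein_id,
                cleaved_bond_position=end,
                p2=protein_seq[end - 2],
                p1=protein_seq[end - 1],
                p1prime=protein_seq[end],
                p2prime=protein_seq[end + 1],
                weight=weight,
                terminus="C",
            )
        )
    return events


def compute_terminome_matrix(
    events: Sequence[CleavageEvent], group: str
) -> TerminomeMatrix:
    """Accumulate weighted context frequencies into the group's observed matrix."""
    if not events:
        raise ValueError(f"no cleavage events for group {group!r}")
    counts = np.zeros((N_AA, N_POSITIONS))
    total = 0.0
    for ev in events:
        for j, residue in enumerate(ev.context):
            counts[AA_INDEX[residue], j] += ev.weight
        total += ev.weight
    if total == 0.0:
        raise ValueError(f"zero total event weight for group {group!r}")
    return TerminomeMatrix(group=group, matrix=normalize_columns(counts, label=group), total_weight=total)


class _ProteomeFinder:
    """Exact-occurrence lookup across a proteome, seeded by a k-mer prefix index.

    Equivalent to running :func:`map_peptide` against every protein, but the
    prefix index avoids scanning the full proteome per peptide. Peptides
    shorter than the index k fall back to the exhaustive scan.
    """

    K = 5

    def __init__(self, proteins: Mapping[str, str]):
        self.proteins = proteins
        self.index: dict[str, list[tuple[str, int]]] = {}
        for pid, seq in proteins.items():
            for i in range(len(seq) - self.K + 1):
                self.index.setdefault(seq[i : i + self.K], []).append((pid, i))

    def find(self, peptide: str) -> list[tuple[str, int, int]]:
        """All (protein_id, start, end) occurrences, 1-based inclusive spans."""
        if len(peptide) < self.K:
            return [
                (pid, start, end)
                for pid, seq in self.proteins.items()
                for start, end in map_peptide(seq, peptide)
            ]
        hits = []
        for pid, i in self.index.get(peptide[: self.K], ()):
            if self.proteins[pid].startswith(peptide, i):
                hits.append((pid, i + 1, i + len(peptide)))
        return hits


def events_from_quant_table(
    table: QuantTable,
    proteins: Mapping[str, str],
    *,
    exclude_multimapped: bool = True,
) -> dict[str, list[CleavageEvent]]:
    """Map every peptide row to its parent protein and extract cleavage events.

    ``proteins`` maps protein_id to sequence. Peptide weights are the (already
    normalized) areas; replicate runs of a group are pooled by summing the
    weights of identical events before column normalization downstream.

    By default a peptide that maps to more than one position (in its named
    parent or across all proteins) is excluded, mirroring the exclusion of
    shared peptides; set ``exclude_multimapped=False`` to split its weight
    evenly over all its occurrences instead. Exclusions are logged.
    """
    events: dict[str, list[CleavageEvent]] = {}
    n_excluded = 0
    finder = _ProteomeFinder(proteins)
    cache: dict[str, list[tuple[str, int, int]]] = {}
    for row in table.frame.itertuples():
        pep = row.peptide_seq
        if pep not in cache:
            cache[pep] = finder.find(pep)
        hits = cache[pep]
        if not hits:
            logger.warning("peptide %r not found in any protein; skipped", pep)
            continue
        if len(hits) > 1:
            if exclude_multimapped:
                n_excluded += 1
                continue
            share = row.area / len(hits)
        else:
            share = row.area
        for pid, start, end in hits:
            evs = extract_contexts(proteins[pid], start, end, share, protein_id=pid)
            events.setdefault(row.group, []).extend(evs)
    if n_excluded:
        logger.warning("excluded %d multi-mapping peptide rows from terminome", n_excluded)
    return events


def terminome_matrices_from_quant_table(
    table: QuantTable,
    proteins: Mapping[str, str],
    *,
    exclude_multimapped: bool = True,
) -> dict[str, TerminomeMatrix]:
    """Convenience: per-group observed matrices straight from a quant table."""
    by_group = events_from_quant_table(
        table, proteins, exclude_multimapped=exclude_multimapped
    )
    return {g: compute_terminome_matrix(evs, g) for g, evs in sorted(by_group.items())}


def write_terminome_table(
    matrices: "Iterable[TerminomeMatrix]", path: str | Path
) -> None:
    """Serialize observed matrices as long-format TSV (group, position, residue, frequency)."""
    rows = []
    for tm in matrices:
        for j, pos in enumerate(POSITIONS):
            for i, aa in enumerate(AMINO_ACIDS):
                rows.append((tm.group, pos, aa, tm.matrix[i, j]))
    pd.DataFrame(rows, columns=["group", "position", "residue", "frequency"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_terminome_table(path: str | Path) -> dict[str, TerminomeMatrix]:
    df = pd.read_csv(path, sep="\t", dtype={"group": str})
    out: dict[str, TerminomeMatrix] = {}
    for group, sub in df.groupby("group", sort=True):
        m = np.zeros((N_AA, N_POSITIONS))
        for _, row in sub.iterrows():
            m[AA_INDEX[row["residue"]], POSITION_INDEX[row["position"]]] = row["frequency"]
        out[str(group)] = TerminomeMatrix(group=str(group), matrix=m)
    return out


def write_event_audit(
    events_by_group: Mapping[str, Sequence[CleavageEvent]], path: str | Path
) -> None:
    """Audit TSV of every cleavage event used to build the matrices."""
    rows = []
    for group, events in sorted(events_by_group.items()):
        for ev in events:
            rows.append(
                (group, ev.protein_id, ev.cleaved_bond_position, ev.terminus,
                 ev.p2, ev.p1, ev.p1prime, ev.p2prime, ev.weight)
            )
    pd.DataFrame(
        rows,
        columns=["group", "protein_id", "bond", "terminus", "P2", "P1", "P1p", "P2p", "weight"],
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
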