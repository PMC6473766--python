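"""Per-protease cleavage-site specificity matrices.

A specificity matrix records, for one protease, the appearance frequency of
each of the 20 amino acids at the four positions flanking its cleavage sites
(P2, P1, P1', P2'). Matrices are stored column-normalized: every position
column sums to 1. Tables are exchanged as long-format TSV with columns
``protease_id``, ``ec_number``, ``position``, ``residue``, ``value`` — the
flat dialect used for panels derived from curated protease databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    N_AA,
    N_POSITIONS,
    POSITION_INDEX,
    POSITIONS,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .terminome import CleavageEvent

logger = logging.getLogger(__name__)

COLUMN_SUM_TOL = 1e-9

_TABLE_COLUMNS = ["protease_id", "ec_number", "position", "residue", "value"]


@dataclass(frozen=True)
class SpecificityMatrix:
    """One protease's 20x4 amino-acid appearance-frequency matrix.

    Parameters
    ----------
    protease_id:
        Free-text identifier of the protease.
    matrix:
        Array of shape (20, 4); rows follow :data:`~terminome.alphabet.AMINO_ACIDS`,
        columns follow :data:`~terminome.alphabet.POSITIONS`. Each column must
        sum to 1 within ``1e-9`` and all entries must be nonnegative.
    ec_number:
        Enzyme Commission number, or empty when unknown.
    """

    protease_id: str
    matrix: np.ndarray
    ec_number: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_AA, N_POSITIONS):
            raise ValueError(
                f"specificity matrix for {self.protease_id!r} has shape "
                f"{m.shape}, expected {(N_AA, N_POSITIONS)}"
            )
        if (m < 0).any():
            raise ValueError(f"negative entries in specificity matrix {self.protease_id!r}")
        sums = m.sum(axis=0)
        if not np.allclose(sums, 1.0, rtol=0.0, atol=COLUMN_SUM_TOL):
            raise ValueError(
                f"columns of specificity matrix {self.protease_id!r} do not sum "
                f"to 1 (sums={sums})"
            )
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    def frequency(self, residue: str, position: str) -> float:
        """Frequency of ``residue`` at ``position`` (one of P2, P1, P1p, P2p)."""
        return float(self.matrix[AA_INDEX[residue], POSITION_INDEX[position]])

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a residues x positions DataFrame."""
        return pd.DataFrame(self.matrix, index=list(AMINO_ACIDS), columns=list(POSITIONS))


def normalize_columns(counts: np.ndarray, *, label: str = "") -> np.ndarray:
    """Convert a nonnegative 20x4 count/weight array to per-column frequencies.

    All-zero columns are replaced with the uniform distribution (0.05 per
    residue) so that sparse panels remain usable; this is logged as a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError(f"negative counts in specificity data {label!r}")
    sums = counts.sum(axis=0)
    out = np.empty_like(counts)
    for j, s in enumerate(sums):
        if s == 0.0:
            logger.warning(
                "all-zero %s column in specificity data %r: set to uniform (0.05)",
                POSITIONS[j],
                label,
            )
            out[:, j] = 1.0 / N_AA
        else:
            out[:, j] = counts[:, j] / s
    return out


def load_specificity_table(
    path: str | Path, *, normalize: bool = True
) -> list[SpecificityMatrix]:
    """Read a long-format specificity TSV into one matrix per protease.

    Rows with residue letters outside the canonical 20 (e.g. B, X, U) are
    rejected with a warning. When ``normalize`` is set (default), raw values
    are converted to per-column frequencies; unset it only for tables already
    known to be column-normalized.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protease_id": str, "ec_number": str})
    if df.empty:
        raise ValueError(f"empty specificity table: {path}")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns and c != "ec_number"]
    if missing:
        raise ValueError(f"specificity table {path} lacks columns {missing}")
    if "ec_number" not in df.columns:
        df["ec_number"] = ""
    df["ec_number"] = df["ec_number"].fillna("")

    bad_pos = ~df["position"].isin(POSITIONS)
    if bad_pos.any():
        raise ValueError(
            f"unknown position labels in {path}: {sorted(df.loc[bad_pos, 'position'].unique())}"
        )
    bad_res = ~df["residue"].isin(list(AMINO_ACIDS))
    if bad_res.any():
        for letter in sorted(df.loc[bad_res, "residue"].unique()):
            logger.warning(
                "rejecting %d row(s) with non-canonical residue %r in %s",
                int((df["residue"] == letter).sum()),
                letter,
                path,
            )
        df = df[~bad_res]
    if df.empty:
        raise ValueError(f"specificity table {path} has no canonical-residue rows")
    if (df["value"] < 0).any():
        raise ValueError(f"negative values in specificity table {path}")

    matrices: list[SpecificityMatrix] = []
    for pid, sub in df.groupby("protease_id", sort=True):
        counts = np.zeros((N_AA, N_POSITIONS))
        for _, row in sub.iterrows():
            counts[AA_INDEX[row["residue"]], POSITION_INDEX[row["position"]]] += row["value"]
        ecs = sub["ec_number"].unique()
        ec = next((e for e in ecs if e), "")
        freq = normalize_columns(counts, label=str(pid)) if normalize else counts
        matrices.append(SpecificityMatrix(protease_id=str(pid), matrix=freq, ec_number=ec))
    return matrices


def write_specificity_table(
    matrices: Sequence[SpecificityMatrix], path: str | Path
) -> None:
    """Serialize matrices to the long-format TSV dialect (frequencies)."""
    rows = []
    for m in matrices:
        for j, pos in enumerate(POSITIONS):
            for i, aa in enumerate(AMINO_ACIDS):
                rows.append((m.protease_id, m.ec_number, pos, aa, m.matrix[i, j]))
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def load_example_panel() -> list[SpecificityMatrix]:
    """Packaged synthetic example panel of 45 protease specificity matrices.

    Stands in for a panel derived from a curated protease database; ids carry
    EC-style numbers in the 3.4 (peptidase) class. Generated once with the
    synthetic panel generator and shipped as TSV.
    """
    from importlib import resources

    ref = resources.files("terminome.data").joinpath("example_specificity_panel.tsv")
    with resources.as_file(ref) as path:
        return load_specificity_table(path)


def build_specificity_from_cleavages(
    events: "Iterable[CleavageEvent]", protease_id: str, *, ec_number: str = ""
) -> SpecificityMatrix:
    """Build a specificity matrix from weighted cleavage events.

    Each event contributes its weight to the (residue, position) cells named by
    its P2/P1/P1'/P2' context; columns are then normalized. This is the same
    accumulation used for observed terminome matrices, so synthetic digests and
    observed peptidomes share one code path.
    """
    counts = np.zeros((N_AA, N_POSITIONS))
    n = 0
    for ev in events:
        if ev.weight < 0:
            raise ValueError("cleavage event with negative weight")
        for j, residue in enumerate(ev.context):
            counts[AA_INDEX[residue], j] += ev.weight
        n += 1
    if n == 0:
        raise ValueError("cannot build a specificity matrix from zero events")
    if counts.sum() == 0.0:
        raise ValueError("cannot build a specificity matrix from zero total weight")
    return SpecificityMatrix(
        protease_id=protease_id,
        matrix=normalize_columns(counts, label=protease_id),
        ec_number=ec_number,
    )
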