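"""Quantified peptidome handling: filters, run normalization, protein areas.

The quantification table emulates a label-free DIA peak-area export: one row
per (peptide, protein, group, replicate) with a summed fragment-ion XIC area,
an identification confidence in [0, 1], and a shared-peptide flag. Each
(group, replicate) pair is one acquisition run; runs are normalized so their
areas sum to 1 before any cross-run comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import is_canonical

logger = logging.getLogger(__name__)

QUANT_COLUMNS = [
    "peptide_seq",
    "protein_id",
    "group",
    "replicate",
    "area",
    "confidence",
    "shared",
]

DEFAULT_MIN_CONFIDENCE = 0.80
DEFAULT_FOLD_CHANGE_THRESHOLD = 2.0

#: Confidence tier edges for the textual coverage map: tier 1 is >= 0.95,
#: tier 2 is [0.50, 0.95), tier 3 is < 0.50.
COVERAGE_TIERS = (0.95, 0.50)
TIER_SYMBOLS = {1: "1", 2: "2", 3: "3", 0: "."}


@dataclass(frozen=True)
class PeptideRecord:
    """One quantified peptide observation in one run."""

    peptide_seq: str
    protein_id: str
    group: str
    replicate: int
    area: float
    confidence: float = 1.0
    shared: bool = False

    def __post_init__(self) -> None:
        if not is_canonical(self.peptide_seq):
            raise ValueError(f"peptide sequence {self.peptide_seq!r} is not canonical")
        if self.area < 0:
            raise ValueError(f"negative area for peptide {self.peptide_seq!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.replicate < 1:
            raise ValueError("replicate numbering starts at 1")


@dataclass
class QuantTable:
    """A peptide quantification table with group/replicate structure.

    Thin wrapper over a DataFrame with the columns in :data:`QUANT_COLUMNS`.
    Operations return new tables; the input frame is never mutated.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in QUANT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"quant table lacks columns {missing}")
        df = self.frame[QUANT_COLUMNS].copy()
        df["replicate"] = df["replicate"].astype(int)
        df["area"] = df["area"].astype(float)
        df["confidence"] = df["confidence"].astype(float)
        df["shared"] = df["shared"].astype(bool)
        if (df["area"] < 0).any():
            raise ValueError("negative peptide areas")
        self.frame = df.reset_index(drop=True)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[PeptideRecord]) -> "QuantTable":
        rows = [
            (r.peptide_seq, r.protein_id, r.group, r.replicate, r.area, r.confidence, r.shared)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=QUANT_COLUMNS))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "QuantTable":
        df = pd.read_csv(path, sep="\t", dtype={"peptide_seq": str, "protein_id": str, "group": str})
        df["shared"] = df["shared"].astype(int).astype(bool)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["shared"] = out["shared"].astype(int)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")

    # -- views -------------------------------------------------------------

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    @property
    def runs(self) -> list[tuple[str, int]]:
        """Distinct (group, replicate) acquisition runs."""
        return sorted(set(zip(self.frame["group"], self.frame["replicate"])))

    def records(self) -> list[PeptideRecord]:
        return [
            PeptideRecord(
                peptide_seq=r.peptide_seq,
                protein_id=r.protein_id,
                group=r.group,
                replicate=int(r.replicate),
                area=float(r.area),
                confidence=float(r.confidence),
                shared=bool(r.shared),
            )
            for r in self.frame.itertuples()
        ]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ProteinFoldChange:
    """Per-protein group areas, fold changes vs a reference, and significance."""

    protein_id: str
    area_by_group: dict[str, float] = field(default_factory=dict)
    fold_change_by_group: dict[str, float | None] = field(default_factory=dict)
    significant_by_group: dict[str, bool] = field(default_factory=dict)


def filter_peptides(
    table: QuantTable, min_confidence: float = DEFAULT_MIN_CONFIDENCE
) -> QuantTable:
    """Drop shared peptides and peptides below the confidence cutoff.

    The cutoff is inclusive: a record at exactly ``min_confidence`` is kept
    ("below 80%" excludes only strictly lower values).
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    df = table.frame
    keep = (~df["shared"]) & (df["confidence"] >= min_confidence)
    out = df[keep].reset_index(drop=True)
    if out.empty and not df.empty:
        logger.warning("all %d peptide records removed by filtering", len(df))
    return QuantTable(out)


def normalize_runs(table: QuantTable) -> QuantTable:
    """Scale areas so each (group, replicate) run sums to 1. Idempotent."""
    df = table.frame.copy()
    totals = df.groupby(["group", "replicate"])["area"].transform("sum")
    zero = totals == 0.0
    if zero.any():
        bad = sorted(set(zip(df.loc[zero, "group"], df.loc[zero, "replicate"])))
        raise ValueError(f"run(s) with zero total area: {bad}")
    df["area"] = df["area"] / totals
    return QuantTable(df)


def aggregate_protein_areas(table: QuantTable) -> list[ProteinFoldChange]:
    """Sum peptide areas to protein areas, then average across replicates.

    Within each run, a protein's area is the sum of its peptides' areas; the
    group-level area is the arithmetic mean of the per-replicate protein
    areas over all runs observed for that group (a protein absent from a run
    contributes 0 to the mean).
    """
    df = table.frame
    results: list[ProteinFoldChange] = []
    if df.empty:
        return results
    run_counts = df.groupby("group")["replicate"].nunique()
    per_run = (
        df.groupby(["protein_id", "group", "replicate"], sort=True)["area"].sum().reset_index()
    )
    per_group = per_run.groupby(["protein_id", "group"])["area"].sum().unstack(fill_value=0.0)
    groups = sorted(df["group"].unique())
    for pid, row in per_group.iterrows():
        areas = {g: float(row.get(g, 0.0)) / int(run_counts[g]) for g in groups}
        results.append(ProteinFoldChange(protein_id=str(pid), area_by_group=areas))
    return results


def fold_changes(
    proteins: Sequence[ProteinFoldChange],
    reference_group: str,
    threshold: float = DEFAULT_FOLD_CHANGE_THRESHOLD,
) -> list[ProteinFoldChange]:
    """Compute per-group fold changes relative to ``reference_group``.

    fold_change(group) = area(group) / area(reference). When the reference
    area is 0 the fold change is undefined (``None``) and never significant;
    significance is strict: fold change > ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("fold-change threshold must be positive")
    out: list[ProteinFoldChange] = []
    for p in proteins:
        if reference_group not in p.area_by_group:
            raise ValueError(
                f"reference group {reference_group!r} missing for protein {p.protein_id!r}"
            )
        ref = p.area_by_group[reference_group]
        fc: dict[str, float | None] = {}
        sig: dict[str, bool] = {}
        for g, area in p.area_by_group.items():
            if g == reference_group:
                continue
            if ref == 0.0:
                fc[g] = None
                sig[g] = False
            else:
                value = area / ref
                fc[g] = value
                sig[g] = value > threshold
        out.append(
            ProteinFoldChange(
                protein_id=p.protein_id,
                area_by_group=dict(p.area_by_group),
                fold_change_by_group=fc,
                significant_by_group=sig,
            )
        )
    return out


def fold_change_frame(proteins: Sequence[ProteinFoldChange]) -> pd.DataFrame:
    """Protein x group matrix of fold changes (NaN where undefined)."""
    rows = {}
    for p in proteins:
        rows[p.protein_id] = {
            g: (np.nan if v is None else v) for g, v in p.fold_change_by_group.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def count_significant(
    fold_change_matrix: pd.DataFrame, threshold: float = DEFAULT_FOLD_CHANGE_THRESHOLD
) -> dict[str, int]:
    """Count, per group column, the proteins with fold change strictly above threshold.

    NaN (undefined) entries never count.
    """
    counts = {}
    for col in fold_change_matrix.columns:
        vals = pd.to_numeric(fold_change_matrix[col], errors="coerce")
        counts[str(col)] = int((vals > threshold).sum())
    return counts


def load_published_fold_changes() -> pd.DataFrame:
    """Packaged fold-change matrix of cleaved fish-muscle proteins.

    135 proteins x 3 columns (AirEx1, AirEx5, AirEx10), each a fold change of
    the air-exposure group relative to the immediately-decapitated (Decap)
    reference, as printed to two decimals.
    """
    ref = resources.files("terminome.data").joinpath("cleaved_protein_fold_changes.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("protein_id")


def render_peptide_map(
    protein_seq: str,
    peptides: Iterable[PeptideRecord],
    *,
    width: int = 60,
) -> str:
    """Render a textual per-residue coverage map in three confidence tiers.

    Tier 1 covers residues backed by a peptide with confidence >= 0.95,
    tier 2 by [0.50, 0.95), tier 3 by < 0.50; uncovered residues show ``.``.
    Where tiers overlap the best (lowest-numbered) tier wins. Peptides that do
    not map to the protein are skipped with a warning. Output interleaves the
    sequence and the tier line, ``width`` residues per block.
    """
    n = len(protein_seq)
    tier = [0] * n  # 0 = uncovered
    for rec in peptides:
        spans = _find_occurrences(protein_seq, rec.peptide_seq)
        if not spans:
            logger.warning(
                "peptide %r does not map to the protein; skipped", rec.peptide_seq
            )
            continue
        t = 1 if rec.confidence >= COVERAGE_TIERS[0] else 2 if rec.confidence >= COVERAGE_TIERS[1] else 3
        for start, end in spans:
            for i in range(start - 1, end):
                if tier[i] == 0 or t < tier[i]:
                    tier[i] = t
    lines = []
    for off in range(0, n, width):
        seq_block = protein_seq[off : off + width]
        tier_block = "".join(TIER_SYMBOLS[t] for t in tier[off : off + width])
        lines.append(f"{off + 1:>6} {seq_block}")
        lines.append(f"{'':>6} {tier_block}")
    covered = sum(1 for t in tier if t > 0)
    lines.append(f"coverage: {covered}/{n} residues")
    return "\n".join(lines)


def _find_occurrences(protein_seq: str, peptide_seq: str) -> list[tuple[int, int]]:
    """All exact occurrences as 1-based inclusive (start, end) spans."""
    spans = []
    start = protein_seq.find(peptide_seq)
    while start != -1:
        spans.append((start + 1, start + len(peptide_seq)))
        start = protein_seq.find(peptide_seq, start + 1)
    return spans
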