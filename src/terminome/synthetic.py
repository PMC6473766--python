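"""Synthetic proteomes, protease panels, and simulated digests.

The generative model mirrors the mixture assumption of the deconvolution
stage: each sample group has a known contribution vector f* over a panel of
proteases; cleavage sites are drawn by first picking a protease with
probability f*_k and then picking a peptide bond with probability
proportional to the product of that protease's specificity frequencies over
the four residues flanking the bond. Every sampled site is paired with a
second site drawn the same way inside a fragment-length window, and the
peptide between the two bonds is emitted with log-normal abundance noise
per replicate. Because both peptide termini are genuine protease cleavage
sites, the observed terminome of a large noiseless digest converges to
sum_k f*_k X_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.stats import spearmanr

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from .deconvolution import fit_contributions
from .peptidome import QUANT_COLUMNS, QuantTable, filter_peptides, normalize_runs
from .specificity import SpecificityMatrix
from .terminome import terminome_matrices_from_quant_table

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("Decap", "AirEx1", "AirEx5", "AirEx10")

# stream tags for deterministic, independent RNG substreams
_STREAM_PROTEOME = 0
_STREAM_PANEL = 1
_STREAM_FSTAR = 2
_STREAM_EVENTS = 3
_STREAM_NOISE = 4


@dataclass
class SimulationConfig:
    """Parameters of one synthetic digestion experiment."""

    seed: int = 0
    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (200, 400)
    n_proteases: int = 5
    specificity_concentration: float = 0.1
    f_star: Optional[Mapping[str, Sequence[float]]] = None
    n_events_per_group: int = 5000
    abundance_noise_sigma: float = 0.2
    groups: tuple[str, ...] = DEFAULT_GROUPS
    replicates: int = 3
    fragment_length_range: tuple[int, int] = (5, 30)
    base_abundance: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"degenerate protein length range {self.protein_length_range}")
        flo, fhi = self.fragment_length_range
        if not (1 <= flo <= fhi):
            raise ValueError(f"degenerate fragment length range {self.fragment_length_range}")
        if self.n_proteins < 1 or self.n_proteases < 1:
            raise ValueError("need at least one protein and one protease")
        if self.n_events_per_group < 1:
            raise ValueError("n_events_per_group must be >= 1")
        if self.abundance_noise_sigma < 0:
            raise ValueError("abundance noise sigma must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.f_star is not None:
            for g, fs in self.f_star.items():
                fs = np.asarray(fs, dtype=float)
                if fs.shape != (self.n_proteases,):
                    raise ValueError(f"f_star for group {g!r} has wrong length")
                if (fs < 0).any() or abs(fs.sum() - 1.0) > 1e-9:
                    raise ValueError(f"f_star for group {g!r} is not a simplex vector")


@dataclass
class GroundTruth:
    """True mixture weights and event-level audit for a simulated digest."""

    protease_ids: tuple[str, ...]
    f_star: dict[str, np.ndarray]
    events: pd.DataFrame  # group, protease_id, protein_id, bond, weight


def _rng(cfg: SimulationConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, *tags)))


def generate_proteome(cfg: SimulationConfig) -> dict[str, str]:
    """Random proteins with i.i.d. uniform residues; reproducible per seed."""
    rng = _rng(cfg, _STREAM_PROTEOME)
    lo, hi = cfg.protein_length_range
    proteome: dict[str, str] = {}
    width = len(str(cfg.n_proteins))
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[j] for j in rng.integers(0, N_AA, size=length))
        proteome[f"prot{i + 1:0{width}d}"] = seq
    return proteome


def generate_protease_panel(cfg: SimulationConfig) -> list[SpecificityMatrix]:
    """Panel of proteases with Dirichlet-sampled position columns.

    Small concentration values give sharp, nearly one-hot specificities;
    large values approach the uniform 0.05 column.
    """
    rng = _rng(cfg, _STREAM_PANEL)
    alpha = np.full(N_AA, cfg.specificity_concentration)
    panel = []
    for k in range(cfg.n_proteases):
        cols = rng.dirichlet(alpha, size=4).T  # 20 x 4
        panel.append(SpecificityMatrix(protease_id=f"protease{k + 1}", matrix=cols))
    return panel


def _group_f_star(cfg: SimulationConfig) -> dict[str, np.ndarray]:
    if cfg.f_star is not None:
        return {g: np.asarray(cfg.f_star[g], dtype=float) for g in cfg.groups}
    rng = _rng(cfg, _STREAM_FSTAR)
    return {g: rng.dirichlet(np.ones(cfg.n_proteases)) for g in cfg.groups}


def _bond_weights(seq_codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Weight of every valid bond p (1-based, p in [2, L-2]) for one protease.

    The weight of a bond is the product of the protease's frequencies for the
    residues at P2, P1, P1', P2' around that bond.
    """
    if len(seq_codes) < 4:
        return np.zeros(0)
    p2 = matrix[seq_codes[:-3], 0]
    p1 = matrix[seq_codes[1:-2], 1]
    p1p = matrix[seq_codes[2:-1], 2]
    p2p = matrix[seq_codes[3:], 3]
    return p2 * p1 * p1p * p2p


def _window_sums(w: np.ndarray, flo: int, fhi: int) -> np.ndarray:
    """For each bond index q, the sum of w over indices at distance [flo, fhi].

    Bond indices map 1:1 onto bond positions, so index distance equals
    fragment length.
    """
    n = len(w)
    if n == 0:
        return w
    c = np.concatenate(([0.0], np.cumsum(w)))  # c[j] = sum(w[:j])
    q = np.arange(n)
    lo_l = np.clip(q - fhi, 0, n)
    hi_l = np.clip(q - flo + 1, 0, n)
    lo_r = np.clip(q + flo, 0, n)
    hi_r = np.clip(q + fhi + 1, 0, n)
    return (c[hi_l] - c[lo_l]) + (c[hi_r] - c[lo_r])


def simulate_digestion(
    proteome: Mapping[str, str],
    panel: Sequence[SpecificityMatrix],
    cfg: SimulationConfig,
) -> tuple[QuantTable, GroundTruth]:
    """Simulate a quantified peptidome digested by the panel with known f*.

    Returns the quantification table (every peptide observed in every
    replicate run of its group, with independent log-normal area noise) and
    the ground truth (per-group f* and an event audit whose per-group weights
    sum to ``n_events_per_group``).
    """
    if len(panel) != cfg.n_proteases:
        raise ValueError("panel size disagrees with config")
    prot_ids = list(proteome)
    seq_codes = {pid: np.array([AA_INDEX[c] for c in proteome[pid]]) for pid in prot_ids}
    f_star = _group_f_star(cfg)
    flo, fhi = cfg.fragment_length_range

    # Per-protease bond weights and pair-sampling tables. A digestion event is
    # a *pair* of cleavage sites (s, t) in one protein with fragment length
    # |t - s| inside the window, drawn with probability proportional to
    # w(s) * w(t); sampling s from the marginal r(s) = w(s) * (windowed sum of
    # w around s) and then t | s proportional to w keeps both peptide termini
    # distributed according to the protease's specificity.
    per_protein_w: dict[int, list[np.ndarray]] = {}
    global_r: list[np.ndarray] = []
    for k, spec in enumerate(panel):
        ws = [_bond_weights(seq_codes[pid], spec.matrix) for pid in prot_ids]
        per_protein_w[k] = ws
        rs = [w * _window_sums(w, flo, fhi) for w in ws]
        global_r.append(np.concatenate(rs) if rs else np.zeros(0))
    idx_protein: list[int] = []
    idx_pos: list[int] = []
    for i, pid in enumerate(prot_ids):
        nb = max(len(proteome[pid]) - 3, 0)
        idx_protein.extend([i] * nb)
        idx_pos.extend(range(2, 2 + nb))
    bond_protein = np.array(idx_protein, dtype=int)
    bond_pos = np.array(idx_pos, dtype=int)

    n_short = sum(1 for pid in prot_ids if len(proteome[pid]) < 4)
    if n_short:
        logger.warning("%d protein(s) too short for any cleavage bond; never sampled", n_short)

    quant_rows: list[tuple] = []
    audit_rows: list[tuple] = []
    for gi, group in enumerate(cfg.groups):
        rng_ev = _rng(cfg, _STREAM_EVENTS, gi)
        noise_rngs = [_rng(cfg, _STREAM_NOISE, gi, r) for r in range(1, cfg.replicates + 1)]
        fs = f_star[group]
        proteases = rng_ev.choice(cfg.n_proteases, size=cfg.n_events_per_group, p=fs)
        counts = np.bincount(proteases, minlength=cfg.n_proteases)
        for k in range(cfg.n_proteases):
            if counts[k] == 0:
                continue
            rk = global_r[k]
            total = rk.sum()
            if total == 0.0:
                raise ValueError(
                    f"protease {panel[k].protease_id!r} has no valid cleavage-site "
                    "pair in the proteome (proteins too short for the fragment window?)"
                )
            sites = rng_ev.choice(len(rk), size=int(counts[k]), p=rk / total)
            for site in sites:
                i = int(bond_protein[site])
                p = int(bond_pos[site])
                pid = prot_ids[i]
                seq = proteome[pid]
                w_local = per_protein_w[k][i]
                # second boundary t | s: proportional to w inside the window
                lo1 = max(p - fhi, 2)
                hi1 = p - flo
                lo2 = p + flo
                hi2 = min(p + fhi, len(seq) - 2)
                cand = []
                if hi1 >= lo1:
                    cand.append(np.arange(lo1, hi1 + 1))
                if hi2 >= lo2:
                    cand.append(np.arange(lo2, hi2 + 1))
                cand = np.concatenate(cand)
                weights = w_local[cand - 2]
                cum = np.cumsum(weights)
                c = np.searchsorted(cum, rng_ev.random() * cum[-1])
                t = int(cand[min(c, len(cand) - 1)])
                s, e = (t, p) if t < p else (p, t)
                pep = seq[s:e]  # residues s+1 .. e (1-based inclusive)
                for r, rng_noise in enumerate(noise_rngs, start=1):
                    noise = (
                        rng_noise.lognormal(0.0, cfg.abundance_noise_sigma)
                        if cfg.abundance_noise_sigma > 0
                        else 1.0
                    )
                    quant_rows.append(
                        (pep, pid, group, r, cfg.base_abundance * noise, 1.0, False)
                    )
                audit_rows.append((group, panel[k].protease_id, pid, p, 1.0))
    table = QuantTable(pd.DataFrame(quant_rows, columns=QUANT_COLUMNS))
    truth = GroundTruth(
        protease_ids=tuple(x.protease_id for x in panel),
        f_star={g: f_star[g].copy() for g in cfg.groups},
        events=pd.DataFrame(
            audit_rows, columns=["group", "protease_id", "protein_id", "bond", "weight"]
        ),
    )
    return table, truth


def write_proteome_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_proteome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_ground_truth(
    truth: GroundTruth, path: str | Path, *, events_path: Optional[str | Path] = None
) -> None:
    """Sidecar TSV of the true mixture weights (group, protease_id, f_star)."""
    rows = []
    for g, fs in truth.f_star.items():
        for pid, f in zip(truth.protease_ids, fs):
            rows.append((g, pid, f))
    pd.DataFrame(rows, columns=["group", "protease_id", "f_star"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
    if events_path is not None:
        truth.events.to_csv(events_path, sep="\t", index=False, float_format="%.12g")


def recovery_experiment(
    cfg: SimulationConfig, seeds: Optional[Sequence[int]] = None
) -> pd.DataFrame:
    """End-to-end parameter recovery: simulate, run the pipeline, compare to f*.

    For each seed the full path is exercised: digestion -> peptide filters ->
    run normalization -> terminome matrices -> contribution fitting. Returns a
    frame with one row per (seed, group): RMSE between fitted f and f*, and
    their Spearman rank correlation.
    """
    if seeds is None:
        seeds = [cfg.seed]
    rows = []
    for seed in seeds:
        c = replace(cfg, seed=int(seed))
        proteome = generate_proteome(c)
        panel = generate_protease_panel(c)
        table, truth = simulate_digestion(proteome, panel, c)
        table = normalize_runs(filter_peptides(table))
        matrices = terminome_matrices_from_quant_table(table, proteome)
        for group in c.groups:
            contrib = fit_contributions(matrices[group], panel)
            fs = truth.f_star[group]
            rmse = float(np.sqrt(np.mean((contrib.f - fs) ** 2)))
            rho = float(spearmanr(contrib.f, fs).statistic)
            rows.append((int(seed), group, rmse, rho))
    return pd.DataFrame(rows, columns=["seed", "group", "rmse", "spearman"])
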