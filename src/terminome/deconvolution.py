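"""Decompose an observed terminome matrix into protease contributions.

The observed 20x4 matrix X_p is modeled as a convex combination of the
protease specificity matrices X_k: X_p ~ sum_k f_k X_k with f on the
probability simplex (f_k >= 0, sum f_k = 1). The fit minimizes Z, the sum of
squared differences over all 80 cells, via an exact active-set quadratic
program; a brute-force simplex-lattice oracle is provided as an independent
check. Fitted contributions are compared across sample groups on a log10
scale after normalizing by the grand sum of all contributions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .specificity import SpecificityMatrix
from .terminome import TerminomeMatrix

logger = logging.getLogger(__name__)

SIMPLEX_SUM_TOL = 1e-9
DEFAULT_RIDGE = 1e-9
_COLLINEARITY_EPS = 1e-6
_MAX_LATTICE_POINTS = 5_000_000


@dataclass(frozen=True)
class ContributionVector:
    """Fitted protease contributions for one sample group.

    ``f`` lies on the probability simplex; ``objective_Z`` is the residual
    sum of squares over all 80 matrix cells at the optimum (ridge excluded).
    """

    group: str
    protease_ids: tuple[str, ...]
    f: np.ndarray
    objective_Z: float

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (len(self.protease_ids),):
            raise ValueError("f length does not match protease_ids")
        if (f < -1e-12).any():
            raise ValueError("negative contribution")
        if abs(f.sum() - 1.0) > SIMPLEX_SUM_TOL:
            raise ValueError(f"contributions sum to {f.sum()}, not 1")
        f = np.clip(f, 0.0, None)
        f.flags.writeable = False
        object.__setattr__(self, "f", f)

    def as_series(self) -> pd.Series:
        return pd.Series(self.f, index=list(self.protease_ids), name=self.group)


@dataclass(frozen=True)
class NormalizedContributions:
    """Cross-group log10-normalized contributions f' with a zero mask.

    ``fprime[k, s]`` = log10(N * f[k, s] / grand_sum) where grand_sum is the
    sum of f over all proteases and groups; entries where f = 0 are masked
    (True in ``mask``) rather than set to -inf.
    """

    groups: tuple[str, ...]
    protease_ids: tuple[str, ...]
    fprime: np.ndarray
    mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Proteases x groups frame with NaN at masked cells."""
        vals = np.where(self.mask, np.nan, self.fprime)
        return pd.DataFrame(vals, index=list(self.protease_ids), columns=list(self.groups))


def _design(xp: TerminomeMatrix, xks: Sequence[SpecificityMatrix]) -> tuple[np.ndarray, np.ndarray]:
    if len(xks) == 0:
        raise ValueError("need at least one specificity matrix")
    A = np.column_stack([x.matrix.ravel() for x in xks])
    b = xp.matrix.ravel()
    if A.shape[0] != b.shape[0]:
        raise ValueError("dimension mismatch between specificity and terminome matrices")
    return A, b


def _warn_collinear(xks: Sequence[SpecificityMatrix]) -> None:
    for (i, xi), (j, xj) in itertools.combinations(enumerate(xks), 2):
        if np.linalg.norm(xi.matrix - xj.matrix) < _COLLINEARITY_EPS:
            logger.warning(
                "specificity matrices %r and %r are (near-)identical; "
                "their contributions are not individually identifiable",
                xi.protease_id,
                xj.protease_id,
            )


def _solve_simplex_lsq(A: np.ndarray, b: np.ndarray, ridge: float) -> np.ndarray:
    """Minimize ||A f - b||^2 + ridge ||f||^2 s.t. sum(f) = 1, f >= 0.

    Exact active-set iteration on the KKT system: solve the equality-
    constrained problem on the current support; drop the most negative
    coordinate while infeasible; re-admit the coordinate with the most
    negative multiplier while suboptimal. Deterministic for fixed input order.
    """
    n = A.shape[1]
    H = A.T @ A + ridge * np.eye(n)
    g = A.T @ b
    support = list(range(n))
    f = np.zeros(n)
    for _ in range(8 * n + 16):
        s = np.array(support)
        k = len(s)
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = H[np.ix_(s, s)]
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.append(g[s], 1.0)
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:  # singular KKT: lean on lstsq
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        fs, lam = sol[:k], sol[k]
        if fs.min() < -1e-12:
            worst = support[int(np.argmin(fs))]
            support.remove(worst)
            if not support:  # cannot happen with sum=1, but guard anyway
                raise RuntimeError("active-set emptied the support")
            continue
        f = np.zeros(n)
        f[s] = fs
        # multipliers for excluded coordinates: mu_i = (H f - g)_i + lam >= 0
        grad = H @ f - g
        mu = grad + lam
        excluded = [i for i in range(n) if i not in support]
        if not excluded:
            return f
        mus = mu[excluded]
        if mus.min() >= -1e-12:
            return f
        support.append(excluded[int(np.argmin(mus))])
        support.sort()
    logger.warning("active-set solver hit iteration cap; returning last feasible point")
    return f


def fit_contributions(
    xp: TerminomeMatrix,
    xks: Sequence[SpecificityMatrix],
    *,
    ridge: float = DEFAULT_RIDGE,
) -> ContributionVector:
    """Fit simplex-constrained contributions of each protease to the observed matrix.

    Minimizes the 80-cell residual sum of squares subject to nonnegativity and
    sum-to-one. A tiny ridge term (default 1e-9) selects the minimal-norm
    solution when specificity matrices are collinear; near-identical matrices
    trigger a warning naming the proteases. Deterministic for fixed inputs.
    """
    A, b = _design(xp, xks)
    _warn_collinear(xks)
    f = _solve_simplex_lsq(A, b, ridge)
    f = np.clip(f, 0.0, None)
    f = f / f.sum()
    z = float(np.sum((A @ f - b) ** 2))
    return ContributionVector(
        group=xp.group,
        protease_ids=tuple(x.protease_id for x in xks),
        f=f,
        objective_Z=z,
    )


def _compositions(total: int, parts: int):
    """Yield nonnegative integer tuples of length ``parts`` summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head, *tail)


def grid_oracle(
    xp: TerminomeMatrix,
    xks: Sequence[SpecificityMatrix],
    step: float,
) -> tuple[np.ndarray, float]:
    """Brute-force minimum of Z over the simplex lattice with the given step.

    Independent verifier for :func:`fit_contributions`: enumerates every f
    with coordinates in {0, step, 2*step, ..., 1} summing to 1 and returns the
    best lattice point and its Z. Intended for small panels (N <= 5).
    """
    A, b = _design(xp, xks)
    n = A.shape[1]
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} does not divide 1")
    n_points = math.comb(m + n - 1, n - 1)
    if n_points > _MAX_LATTICE_POINTS:
        raise ValueError(
            f"lattice of {n_points} points (N={n}, step={step}) exceeds the budget"
        )
    F = np.array(list(_compositions(m, n)), dtype=float) * step
    resid = F @ A.T - b
    zs = np.einsum("ij,ij->i", resid, resid)
    best = int(np.argmin(zs))
    return F[best].copy(), float(zs[best])


def normalize_contributions(
    contribs: Sequence[ContributionVector],
) -> NormalizedContributions:
    """Log10-normalize contributions across sample groups.

    f'(k, s) = log10(N * f(k, s) / G) with G the grand sum of f over all
    groups and proteases (G equals the number of groups when every vector is
    simplex-normalized, but it is computed literally so partially fitted sets
    stay correct). Cells with f = 0 are masked.
    """
    if not contribs:
        raise ValueError("no contribution vectors to normalize")
    ids = contribs[0].protease_ids
    for c in contribs[1:]:
        if c.protease_ids != ids:
            raise ValueError("contribution vectors disagree on protease panel")
    n = len(ids)
    F = np.column_stack([c.f for c in contribs])  # proteases x groups
    grand = float(F.sum())
    if grand <= 0:
        raise ValueError("grand sum of contributions is zero")
    mask = F == 0.0
    with np.errstate(divide="ignore"):
        fprime = np.where(mask, np.nan, np.log10(np.where(mask, 1.0, n * F / grand)))
    return NormalizedContributions(
        groups=tuple(c.group for c in contribs),
        protease_ids=ids,
        fprime=fprime,
        mask=mask,
    )


def write_contributions(
    contribs: Sequence[ContributionVector], path: str | Path
) -> None:
    """Long-format TSV of fitted contributions (group, protease_id, f, Z)."""
    rows = []
    for c in contribs:
        for pid, fk in zip(c.protease_ids, c.f):
            rows.append((c.group, pid, fk, c.objective_Z))
    pd.DataFrame(rows, columns=["group", "protease_id", "f", "Z"]).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def export_heatmap(
    norm: NormalizedContributions,
    path: str | Path,
    *,
    image_path: Optional[str | Path] = None,
) -> None:
    """Write the f' matrix as TSV (5 decimals, ``NA`` where masked); optional PNG.

    Rows are proteases, columns are sample groups. The PNG rendering requires
    matplotlib and leaves the color scale unclipped.
    """
    frame = norm.to_frame()
    frame.round(5).to_csv(
        path, sep="\t", index_label="protease_id", na_rep="NA", float_format="%.5f"
    )
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.6 * len(norm.groups), 1 + 0.22 * len(norm.protease_ids))
        )
        data = np.ma.masked_invalid(frame.to_numpy())
        im = ax.imshow(data, aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(norm.groups)), norm.groups)
        ax.set_yticks(range(len(norm.protease_ids)), norm.protease_ids, fontsize=6)
        fig.colorbar(im, ax=ax, label="log10 normalized contribution")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)


def read_heatmap_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the f' TSV (NaN at ``NA`` cells)."""
    return pd.read_csv(path, sep="\t", index_col="protease_id", na_values=["NA"])
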