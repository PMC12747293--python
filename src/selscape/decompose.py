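"""Additive decomposition of lineage x gene log dN/dS matrices.

Fits ``r[L, G] = F[L] + R[G] + e[G, L]`` by iterative backfitting: each
iteration updates every lineage factor by the mean residual over its observed
genes, then every gene factor by the mean residual over its observed
lineages, until the sum of squared residuals stabilizes. The model is
identifiable only up to an additive constant, so a gauge fixing mean(R) = 0
is applied after convergence; F is then interpretable as a lineage's mean
log dN/dS level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from selscape.errors import InvalidArgumentError

__all__ = [
    "DndsMatrix",
    "DecompositionResult",
    "decompose",
    "remove_outliers_and_refit",
    "decompose_by_class",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class DndsMatrix:
    """Lineage x gene matrix of log(dN/dS) values with a missingness mask."""

    lineage_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.observed_mask, dtype=bool)
        n_l, n_g = len(self.lineage_ids), len(self.gene_ids)
        if values.shape != (n_l, n_g) or mask.shape != (n_l, n_g):
            raise InvalidArgumentError("matrix shape mismatch")
        if len(set(self.lineage_ids)) != n_l or len(set(self.gene_ids)) != n_g:
            raise InvalidArgumentError("duplicate lineage or gene ids")
        if n_l == 0 or n_g == 0:
            raise InvalidArgumentError("empty matrix")
        if not mask.any(axis=1).all():
            raise InvalidArgumentError("a lineage row has no observed cells")
        if not mask.any(axis=0).all():
            raise InvalidArgumentError("a gene column has no observed cells")
        if not np.isfinite(values[mask]).all():
            raise InvalidArgumentError("observed values must be finite")
        object.__setattr__(self, "lineage_ids", tuple(self.lineage_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observed_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def submatrix(
        self,
        lineages: Optional[Sequence[str]] = None,
        genes: Optional[Sequence[str]] = None,
    ) -> "DndsMatrix":
        rows = (
            [self.lineage_ids.index(l) for l in lineages]
            if lineages is not None
            else list(range(len(self.lineage_ids)))
        )
        cols = (
            [self.gene_ids.index(g) for g in genes]
            if genes is not None
            else list(range(len(self.gene_ids)))
        )
        return DndsMatrix(
            tuple(self.lineage_ids[i] for i in rows),
            tuple(self.gene_ids[j] for j in cols),
            self.values[np.ix_(rows, cols)],
            self.observed_mask[np.ix_(rows, cols)],
        )


@dataclass(frozen=True)
class DecompositionResult:
    """Fitted factors, residuals and fit diagnostics."""

    lineage_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    F: np.ndarray
    R: np.ndarray
    residuals: np.ndarray  # NaN at unobserved cells
    E: float
    n_iterations: int
    converged: bool
    E_trajectory: tuple[float, ...] = field(repr=False, default=())
    removed_cells: tuple[tuple[str, str], ...] = ()
    gauge: str = "mean(R)=0"

    def fitted(self) -> np.ndarray:
        return self.F[:, np.newaxis] + self.R[np.newaxis, :]

    def f_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lineage_id": self.lineage_ids, "F": self.F, "exp_F": np.exp(self.F)}
        )

    def r_table(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "R": self.R})


def decompose(
    matrix: DndsMatrix, tol: float = 1e-6, max_iter: int = 1000
) -> DecompositionResult:
    """Backfit lineage and gene factors by alternating residual means.

    Factors start at zero. Iteration stops when the change in the sum of
    squared residuals E drops below ``tol`` or after ``max_iter`` iterations
    (returned with ``converged=False``, not an error). E is checked to be
    non-increasing at every step. The gauge shift making mean(R) = 0 is
    absorbed into F after convergence.
    """
    mask = matrix.observed_mask
    values = np.where(mask, matrix.values, 0.0)
    row_n = mask.sum(axis=1)
    col_n = mask.sum(axis=0)
    n_l, n_g = matrix.shape

    f = np.zeros(n_l)
    r = np.zeros(n_g)

    def residual_matrix() -> np.ndarray:
        return np.where(mask, values - f[:, np.newaxis] - r[np.newaxis, :], 0.0)

    resid = residual_matrix()
    energy = float((resid**2).sum())
    trajectory = [energy]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        f = f + resid.sum(axis=1) / row_n
        resid = residual_matrix()
        r = r + resid.sum(axis=0) / col_n
        resid = residual_matrix()
        new_energy = float((resid**2).sum())
        if new_energy > energy + 1e-9 * max(1.0, energy):
            raise AssertionError("objective increased during backfitting")
        delta = energy - new_energy
        energy = new_energy
        trajectory.append(energy)
        if delta < tol:
            converged = True
            break

    shift = float(r.mean())
    r = r - shift
    f = f + shift

    residuals = np.where(mask, values - f[:, np.newaxis] - r[np.newaxis, :], np.nan)
    return DecompositionResult(
        matrix.lineage_ids,
        matrix.gene_ids,
        f,
        r,
        residuals,
        energy,
        iterations,
        converged,
        tuple(trajectory),
    )


def remove_outliers_and_refit(
    matrix: DndsMatrix,
    first_fit: DecompositionResult,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> DecompositionResult:
    """Mask cells with implausibly large residuals and refit once.

    Residuals are standardized by their sample standard deviation; a cell is
    an outlier when its two-sided normal tail probability falls below
    ``alpha / N`` (Bonferroni over the N observed cells). Removals that would
    empty a lineage row or gene column are skipped (most extreme cells take
    precedence). A single removal pass is performed.
    """
    if first_fit.lineage_ids != matrix.lineage_ids or (
        first_fit.gene_ids != matrix.gene_ids
    ):
        raise InvalidArgumentError("fit does not correspond to matrix")
    mask = matrix.observed_mask.copy()
    resid = first_fit.residuals
    observed = np.argwhere(mask)
    n_obs = len(observed)
    sd = float(np.nanstd(resid, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        return first_fit

    z = np.abs(resid) / sd
    p = 2.0 * norm.sf(z)
    candidates = np.argwhere(mask & (p < alpha / n_obs))
    # most extreme first, so skips hit the mildest outliers
    order = np.argsort(-z[tuple(candidates.T)]) if len(candidates) else []
    removed: list[tuple[str, str]] = []
    skipped: list[tuple[str, str]] = []
    row_n = mask.sum(axis=1)
    col_n = mask.sum(axis=0)
    for k in order:
        i, j = candidates[k]
        if row_n[i] <= 1 or col_n[j] <= 1:
            skipped.append((matrix.lineage_ids[i], matrix.gene_ids[j]))
            continue
        mask[i, j] = False
        row_n[i] -= 1
        col_n[j] -= 1
        removed.append((matrix.lineage_ids[i], matrix.gene_ids[j]))

    if not removed:
        return first_fit

    reduced = DndsMatrix(
        matrix.lineage_ids, matrix.gene_ids, matrix.values, mask
    )
    refit = decompose(reduced, tol=tol, max_iter=max_iter)
    return DecompositionResult(
        refit.lineage_ids,
        refit.gene_ids,
        refit.F,
        refit.R,
        refit.residuals,
        refit.E,
        refit.n_iterations,
        refit.converged,
        refit.E_trajectory,
        tuple(removed),
        refit.gauge,
    )


def decompose_by_class(
    matrix: DndsMatrix,
    class_of_gene: Mapping[str, str],
    min_genes_per_lineage: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[dict[str, DecompositionResult], pd.DataFrame]:
    """Decompose per functional class and report cross-class F concordance.

    Genes are partitioned by ``class_of_gene``; per class, lineages with
    fewer than ``min_genes_per_lineage`` observed genes in that class are
    dropped before fitting. The concordance table holds pairwise Spearman
    correlations between class-specific lineage factors over shared lineages.
    """
    missing = [g for g in matrix.gene_ids if g not in class_of_gene]
    if missing:
        raise InvalidArgumentError(
            f"genes without class assignment: {missing[:5]}"
        )

    classes = sorted(set(class_of_gene[g] for g in matrix.gene_ids))
    results: dict[str, DecompositionResult] = {}
    for cls in classes:
        genes = [g for g in matrix.gene_ids if class_of_gene[g] == cls]
        sub = matrix.submatrix(genes=genes)
        counts = sub.observed_mask.sum(axis=1)
        keep = [
            l
            for l, c in zip(sub.lineage_ids, counts)
            if c >= min_genes_per_lineage
        ]
        if not keep:
            import warnings

            warnings.warn(f"class {cls!r} has no qualifying lineage; skipped")
            continue
        sub = sub.submatrix(lineages=keep)
        # dropping lineages may orphan gene columns
        genes_kept = [
            g
            for g, any_obs in zip(sub.gene_ids, sub.observed_mask.any(axis=0))
            if any_obs
        ]
        sub = sub.submatrix(genes=genes_kept)
        results[cls] = decompose(sub, tol=tol, max_iter=max_iter)

    from selscape.stats import spearman

    rows = []
    fitted_classes = sorted(results)
    for a_idx, cls_a in enumerate(fitted_classes):
        for cls_b in fitted_classes[a_idx + 1 :]:
            fa = dict(zip(results[cls_a].lineage_ids, results[cls_a].F))
            fb = dict(zip(results[cls_b].lineage_ids, results[cls_b].F))
            shared = sorted(set(fa) & set(fb))
            if len(shared) < 3:
                continue
            rho, p = spearman(
                [fa[l] for l in shared], [fb[l] for l in shared]
            )
            rows.append(
                {
                    "class_a": cls_a,
                    "class_b": cls_b,
                    "n_shared": len(shared),
                    "spearman_rho": rho,
                    "p_value": p,
                }
            )
    concordance = pd.DataFrame(
        rows, columns=["class_a", "class_b", "n_shared", "spearman_rho", "p_value"]
    )
    return results, concordance


# ---------------------------------------------------------------------------
# TSV I/O (lineage rows, gene columns; empty cell = missing)


def read_matrix_tsv(path) -> DndsMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    return DndsMatrix(
        tuple(str(i) for i in frame.index),
        tuple(str(c) for c in frame.columns),
        np.where(mask, values, 0.0),
        mask,
    )


def write_matrix_tsv(matrix: DndsMatrix, path) -> None:
    values = np.where(matrix.observed_mask, matrix.values, np.nan)
    frame = pd.DataFrame(
        values, index=matrix.lineage_ids, columns=matrix.gene_ids
    )
    frame.to_csv(path, sep="\t", na_rep="")
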