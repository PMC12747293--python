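"""Synthetic-data generators for every input the pipeline consumes.

Provides random phylogenies with exact total-length control, lineage x gene
log dN/dS matrices with planted additive structure (factors, Gaussian
residuals, missing cells, outlier shifts), binary presence/absence evolution
under a two-state gain/loss Markov process, and lineage covariates with a
tunable rank correlation to the planted lineage factors. All generators are
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import norm

from selscape.decompose import DndsMatrix
from selscape.errors import GenerationError, InvalidArgumentError
from selscape.flux import AncestralStates, PresenceAbsenceMatrix
from selscape.trees import Node, Phylogeny

__all__ = [
    "PlantedMatrixTruth",
    "GainLossParams",
    "random_tree",
    "generate_dnds_matrix",
    "simulate_presence_absence",
    "generate_lineage_covariates",
    "write_truth_json",
]


@dataclass(frozen=True)
class PlantedMatrixTruth:
    """Ground truth behind a generated log dN/dS matrix."""

    true_F: np.ndarray
    true_R: np.ndarray
    residual_sd: float
    missing_fraction: float
    outlier_cells: tuple[tuple[int, int], ...]
    seed: int


@dataclass(frozen=True)
class GainLossParams:
    """Two-state gain/loss process parameters."""

    gain_rate_per_unit_length: float
    loss_rate_per_unit_length: float
    root_presence_prob: float
    n_families: int
    seed: int = 0

    def __post_init__(self):
        if self.gain_rate_per_unit_length < 0 or self.loss_rate_per_unit_length < 0:
            raise InvalidArgumentError("rates must be nonnegative")
        if self.gain_rate_per_unit_length == 0 and (
            self.loss_rate_per_unit_length == 0
        ):
            raise InvalidArgumentError("at least one rate must be positive")
        if not 0.0 <= self.root_presence_prob <= 1.0:
            raise InvalidArgumentError("root_presence_prob must be in [0, 1]")
        if self.n_families < 1:
            raise InvalidArgumentError("n_families must be positive")


# ---------------------------------------------------------------------------
# Trees


def random_tree(n_tips: int, total_length: float, seed: int) -> Phylogeny:
    """Random rooted binary tree whose branch lengths sum to ``total_length``.

    Topology comes from coalescent-style random pair merging with
    exponentially spaced internode depths; all branch lengths are then
    rescaled so their sum equals ``total_length`` exactly.
    """
    if n_tips < 2:
        raise InvalidArgumentError("n_tips must be at least 2")
    if total_length <= 0:
        raise InvalidArgumentError("total_length must be positive")
    rng = np.random.default_rng(seed)

    nodes: list[Node] = [Node(f"t{i + 1}") for i in range(n_tips)]
    height: dict[int, float] = {id(n): 0.0 for n in nodes}
    current = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        current += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = Node()
        for child in (a, b):
            child.length = current - height[id(child)]
            parent.add_child(child)
        height[id(parent)] = current
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)

    root = nodes[0]
    raw_total = _branch_sum(root)
    factor = total_length / raw_total
    stack = [root]
    while stack:
        node = stack.pop()
        if node.parent is not None:
            node.length *= factor
        stack.extend(node.children)
    return Phylogeny(root)


def _branch_sum(root: Node) -> float:
    total = 0.0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.parent is not None:
            total += node.length
        stack.extend(node.children)
    return total


# ---------------------------------------------------------------------------
# Additive matrices


def generate_dnds_matrix(
    n_lineages: int,
    n_genes: int,
    sd_F: float,
    sd_R: float,
    residual_sd: float,
    missing_fraction: float = 0.0,
    outlier_fraction: float = 0.0,
    outlier_shift: float = 0.0,
    seed: int = 0,
    mean_F: float = 0.0,
    max_mask_retries: int = 100,
) -> tuple[DndsMatrix, PlantedMatrixTruth]:
    """Generate a log dN/dS matrix with planted additive structure.

    Observed cells equal ``true_F[L] + true_R[G] + N(0, residual_sd)`` plus a
    sign-randomized ``outlier_shift`` on a random subset of observed cells.
    ``true_R`` is recentred to mean exactly zero (the decomposition gauge).
    The missingness mask is uniform over cells and resampled (up to
    ``max_mask_retries``) until every row and column keeps at least one
    observed cell.
    """
    if n_lineages < 1 or n_genes < 1:
        raise InvalidArgumentError("matrix dimensions must be positive")
    if not 0.0 <= missing_fraction < 1.0:
        raise InvalidArgumentError("missing_fraction must be in [0, 1)")
    if not 0.0 <= outlier_fraction < 1.0:
        raise InvalidArgumentError("outlier_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    true_f = mean_F + rng.normal(0.0, sd_F, size=n_lineages)
    true_r = rng.normal(0.0, sd_R, size=n_genes)
    true_r = true_r - true_r.mean()

    n_cells = n_lineages * n_genes
    n_missing = int(round(missing_fraction * n_cells))
    mask = np.ones((n_lineages, n_genes), dtype=bool)
    if n_missing > 0:
        for attempt in range(max_mask_retries):
            mask[:] = True
            drop = rng.choice(n_cells, size=n_missing, replace=False)
            mask.flat[drop] = False
            if mask.any(axis=1).all() and mask.any(axis=0).all():
                break
        else:
            raise GenerationError(
                f"could not draw a feasible mask in {max_mask_retries} tries "
                f"({n_lineages}x{n_genes}, missing {missing_fraction:.0%})"
            )

    values = (
        true_f[:, np.newaxis]
        + true_r[np.newaxis, :]
        + rng.normal(0.0, residual_sd, size=(n_lineages, n_genes))
    )

    outliers: list[tuple[int, int]] = []
    n_outliers = int(round(outlier_fraction * int(mask.sum())))
    if n_outliers > 0:
        observed = np.argwhere(mask)
        pick = rng.choice(len(observed), size=n_outliers, replace=False)
        signs = rng.choice((-1.0, 1.0), size=n_outliers)
        for (i, j), s in zip(observed[pick], signs):
            values[i, j] += s * outlier_shift
            outliers.append((int(i), int(j)))

    matrix = DndsMatrix(
        tuple(f"L{i:04d}" for i in range(n_lineages)),
        tuple(f"G{j:04d}" for j in range(n_genes)),
        np.where(mask, values, 0.0),
        mask,
    )
    truth = PlantedMatrixTruth(
        true_f, true_r, residual_sd, missing_fraction, tuple(outliers), seed
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Presence/absence evolution


def simulate_presence_absence(
    tree: Phylogeny,
    params: GainLossParams,
    return_event_counts: bool = False,
):
    """Evolve binary gene presence along ``tree`` by exact event sampling.

    Each family evolves independently under the two-state continuous-time
    process (0 -> 1 at the gain rate, 1 -> 0 at the loss rate). Both the tip
    matrix and the true internal states are returned; with
    ``return_event_counts`` the realized (gains, losses) event totals are
    appended, which downstream oracles compare against process expectations.
    """
    rng = np.random.default_rng(params.seed)
    n_fam = params.n_families
    rates = np.array(
        [params.gain_rate_per_unit_length, params.loss_rate_per_unit_length]
    )

    root_states = (
        rng.random(n_fam) < params.root_presence_prob
    ).astype(np.int8)
    states_at: dict[int, np.ndarray] = {id(tree.root): root_states}
    gains = losses = 0

    for node in tree.preorder():
        if node.parent is None:
            continue
        states = states_at[id(node.parent)].copy()
        t = node.length
        if t > 0 and rates.max() > 0:
            active = np.arange(n_fam)
            tleft = np.full(n_fam, t)
            while active.size:
                exit_rates = rates[states[active]]
                with np.errstate(divide="ignore"):
                    waits = np.where(
                        exit_rates > 0,
                        rng.exponential(1.0, size=active.size) / exit_rates,
                        np.inf,
                    )
                jumped = waits < tleft[active]
                hit = active[jumped]
                if hit.size:
                    flips = states[hit]
                    gains += int((flips == 0).sum())
                    losses += int((flips == 1).sum())
                    states[hit] = 1 - flips
                    tleft[hit] -= waits[jumped]
                active = hit
        states_at[id(node)] = states

    node_order = list(tree.preorder())
    family_ids = tuple(f"fam{i:05d}" for i in range(n_fam))
    ancestral = AncestralStates(
        tuple(n.label for n in node_order),
        family_ids,
        np.vstack([states_at[id(n)] for n in node_order]),
    )
    tips = tree.tips()
    pam = PresenceAbsenceMatrix(
        tuple(t.label for t in tips),
        family_ids,
        np.vstack([states_at[id(t)] for t in tips]),
    )
    if return_event_counts:
        return pam, ancestral, (gains, losses)
    return pam, ancestral


# ---------------------------------------------------------------------------
# Covariates


def generate_lineage_covariates(
    true_F, target_rho: float, seed: int = 0
) -> np.ndarray:
    """Positive covariates with Spearman correlation ~ ``target_rho`` to F.

    Uses a Gaussian-copula rank coupling: the normal scores of F's ranks are
    mixed with independent noise at the Pearson level ``2 sin(pi*rho/6)``
    that corresponds to the requested Spearman correlation, then mapped
    through ``exp`` to make values positive. ``target_rho = +-1`` yields an
    exact monotone transform.
    """
    true_F = np.asarray(true_F, dtype=float)
    if true_F.ndim != 1 or true_F.size < 3:
        raise InvalidArgumentError("true_F must be a vector of length >= 3")
    if not -1.0 <= target_rho <= 1.0:
        raise InvalidArgumentError("target_rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    n = true_F.size

    ranks = np.argsort(np.argsort(true_F)) + 1.0
    scores = norm.ppf((ranks - 0.5) / n)

    if abs(target_rho) == 1.0:
        z = np.sign(target_rho) * scores
    else:
        pearson = 2.0 * np.sin(np.pi * target_rho / 6.0)
        noise = rng.normal(size=n)
        z = pearson * scores + np.sqrt(1.0 - pearson**2) * noise
    return np.exp(z)


# ---------------------------------------------------------------------------
# Truth serialization


def write_truth_json(truth: PlantedMatrixTruth, path) -> None:
    payload = asdict(truth)
    payload["true_F"] = [float(v) for v in truth.true_F]
    payload["true_R"] = [float(v) for v in truth.true_R]
    payload["outlier_cells"] = [list(c) for c in truth.outlier_cells]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
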