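"""Codon-level simulation and dN/dS estimation.

Implements a GY94-style codon substitution model over the 61 sense codons of
the standard genetic code: rate-matrix construction, alignment simulation by
exact event sampling on a tree, maximum-likelihood estimation of dN/dS
(omega), transition/transversion ratio (kappa) and a global branch-length
scale with fixed topology, a Nei–Gojobori counting estimator as an
independent cross-check, and the mutation-count retention filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import minimize

from selscape.errors import EstimationDegenerateError, InvalidArgumentError
from selscape.trees import Phylogeny

__all__ = [
    "CODONS",
    "N_CODONS",
    "CodonAlignment",
    "CodonModelParams",
    "GeneFamilyEstimate",
    "RetentionResult",
    "build_codon_rate_matrix",
    "simulate_alignment",
    "estimate_dnds_ml",
    "is_boundary",
    "estimate_dnds_ng86",
    "count_mutations",
    "apply_retention_filters",
    "select_representative_paralog",
    "read_alignment",
    "write_alignment",
    "subset_alignment",
]

# ---------------------------------------------------------------------------
# Genetic code tables (standard code; identical to table 11 for sense codons)

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_NUCS = "ACGT"

CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
N_CODONS = len(CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(_TABLE.stop_codons)
AMINO_ACIDS: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in CODONS)

_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _build_step_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            transition[i, j] = _is_transition(ci[k], cj[k])
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, transition, nonsyn


_SINGLE_STEP, _TRANSITION, _NONSYN = _build_step_masks()

# optimizer bounds (natural scale)
OMEGA_BOUNDS = (1e-4, 20.0)
KAPPA_BOUNDS = (1e-2, 1e2)
SCALE_BOUNDS = (1e-3, 1e3)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class CodonModelParams:
    """Parameters of the GY94-style codon model."""

    omega: float
    kappa: float
    codon_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(N_CODONS, 1.0 / N_CODONS)
    )
    branch_scale: float = 1.0

    def __post_init__(self):
        if not self.omega >= 0:
            raise InvalidArgumentError("omega must be nonnegative")
        if not self.kappa > 0:
            raise InvalidArgumentError("kappa must be positive")
        if not self.branch_scale > 0:
            raise InvalidArgumentError("branch_scale must be positive")
        freqs = np.asarray(self.codon_frequencies, dtype=float)
        if freqs.shape != (N_CODONS,):
            raise InvalidArgumentError(f"need {N_CODONS} codon frequencies")
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("frequencies must be >=0 and sum to 1")
        object.__setattr__(self, "codon_frequencies", freqs)


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length, in-frame codon sequences over {A,C,G,T}."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise InvalidArgumentError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise InvalidArgumentError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InvalidArgumentError("sequences differ in length")
        (length,) = lengths or {0}
        if length == 0 or length % 3 != 0:
            raise InvalidArgumentError("length must be positive, divisible by 3")
        for taxon, seq in zip(self.taxa, self.sequences):
            for k in range(0, length, 3):
                codon = seq[k : k + 3]
                if codon in STOP_CODONS:
                    raise InvalidArgumentError(
                        f"in-frame stop codon {codon} in {taxon!r}"
                    )
                if codon not in CODON_INDEX:
                    raise InvalidArgumentError(
                        f"invalid codon {codon!r} in {taxon!r}"
                    )
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "sequences", tuple(self.sequences))

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0])

    @property
    def length_codons(self) -> int:
        return self.length_nt // 3

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_codons) array of codon indices."""
        out = np.empty((len(self.taxa), self.length_codons), dtype=np.int16)
        for r, seq in enumerate(self.sequences):
            out[r] = [
                CODON_INDEX[seq[k : k + 3]] for k in range(0, len(seq), 3)
            ]
        return out

    def take_codon_columns(self, columns: Sequence[int]) -> "CodonAlignment":
        seqs = []
        for seq in self.sequences:
            codons = [seq[3 * c : 3 * c + 3] for c in columns]
            seqs.append("".join(codons))
        return CodonAlignment(self.taxa, tuple(seqs))

    def truncate_codons(self, n_codons: int) -> "CodonAlignment":
        if not 1 <= n_codons <= self.length_codons:
            raise InvalidArgumentError("truncation length out of range")
        return CodonAlignment(
            self.taxa, tuple(s[: 3 * n_codons] for s in self.sequences)
        )


@dataclass(frozen=True)
class GeneFamilyEstimate:
    """Per-(lineage, gene) dN/dS estimate plus filter bookkeeping."""

    lineage_id: str
    gene_id: str
    dnds: float
    kappa: float
    n_sequences: int
    n_sites_nt: int
    tree_length: float
    log_likelihood: float
    boundary_flag: bool = False

    @property
    def mutation_count(self) -> float:
        return count_mutations(self.tree_length, self.n_sites_nt)


# ---------------------------------------------------------------------------
# Rate matrix


def build_codon_rate_matrix(params: CodonModelParams) -> np.ndarray:
    """Instantaneous 61x61 rate matrix of the GY94-style model.

    Off-diagonal rates are nonzero only for single-nucleotide codon changes:
    pi_j, multiplied by kappa for transitions and omega for nonsynonymous
    changes. The matrix is scaled so the expected substitution rate equals 1
    per NUCLEOTIDE site (3 per codon site), matching branch lengths expressed
    in substitutions per nucleotide column.
    """
    pi = params.codon_frequencies
    rates = np.where(_SINGLE_STEP, pi[np.newaxis, :], 0.0)
    rates = np.where(_TRANSITION, rates * params.kappa, rates)
    rates = np.where(_NONSYN, rates * params.omega, rates)
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))
    mean_rate = -float(pi @ np.diag(rates))
    if mean_rate <= 0:
        raise InvalidArgumentError("degenerate rate matrix (all rates zero)")
    return rates * (3.0 / mean_rate)


def _transition_probability_operator(params: CodonModelParams):
    """Eigendecomposition-backed P(t) for a reversible codon model.

    Returns a callable t -> P(t). Uses the symmetrized form
    B = D^{1/2} Q D^{-1/2} with D = diag(pi), which is symmetric for any
    GY94-style (reversible) parameterization.
    """
    q = build_codon_rate_matrix(params)
    pi = params.codon_frequencies
    sqrt_pi = np.sqrt(pi)
    b = (q * sqrt_pi[np.newaxis, :]) / sqrt_pi[:, np.newaxis]
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    left = eigvecs / sqrt_pi[:, np.newaxis]
    right = eigvecs.T * sqrt_pi[np.newaxis, :]

    def p_matrix(t: float) -> np.ndarray:
        p = (left * np.exp(eigvals * t)) @ right
        np.clip(p, 0.0, None, out=p)
        return p

    return p_matrix


# ---------------------------------------------------------------------------
# Simulation


def simulate_alignment(
    tree: Phylogeny,
    params: CodonModelParams,
    n_codons: int,
    seed: int,
    return_events: bool = False,
):
    """Evolve a codon alignment along ``tree`` by exact event sampling.

    The root sequence is drawn from the model's codon frequencies; each codon
    site then evolves independently down every branch under the instantaneous
    rate matrix, with per-branch durations ``length * branch_scale``. With
    ``return_events`` the realized substitution count is also returned, which
    serves as an oracle for the Poisson expectation of the process.
    """
    if n_codons < 1:
        raise InvalidArgumentError("n_codons must be positive")
    rng = np.random.default_rng(seed)
    q = build_codon_rate_matrix(params)
    exit_rate = -np.diag(q).copy()
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_cdf = np.cumsum(jump / exit_rate[:, np.newaxis], axis=1)

    root_states = rng.choice(N_CODONS, size=n_codons, p=params.codon_frequencies)
    states_at: dict[int, np.ndarray] = {id(tree.root): root_states}
    total_events = 0

    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states_at[id(node.parent)]
        states = parent_states.copy()
        duration = node.length * params.branch_scale
        if duration > 0:
            active = np.arange(n_codons)
            tleft = np.full(n_codons, duration)
            while active.size:
                rates = exit_rate[states[active]]
                waits = rng.exponential(1.0, size=active.size) / rates
                jumped = waits < tleft[active]
                hit = active[jumped]
                if hit.size:
                    u = rng.random(hit.size)
                    states[hit] = np.argmax(
                        u[:, np.newaxis] < jump_cdf[states[hit]], axis=1
                    )
                    tleft[hit] -= waits[jumped]
                    total_events += hit.size
                active = hit
        states_at[id(node)] = states

    taxa, seqs = [], []
    for tip in tree.tips():
        taxa.append(tip.label)
        idx = states_at[id(tip)]
        seqs.append("".join(CODONS[i] for i in idx))
    alignment = CodonAlignment(tuple(taxa), tuple(seqs))
    if return_events:
        return alignment, total_events
    return alignment


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation


def _pattern_table(alignment: CodonAlignment, taxa_order: Sequence[str]):
    idx = alignment.codon_indices()
    row_of = {t: i for i, t in enumerate(alignment.taxa)}
    rows = np.array([row_of[t] for t in taxa_order])
    matrix = idx[rows]
    patterns, counts = np.unique(matrix, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _log_likelihood(tree_nodes, tip_index, patterns, counts, params):
    """Felsenstein pruning over compressed site patterns, with scaling."""
    p_of = _transition_probability_operator(params)
    n_patterns = patterns.shape[1]
    partials: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_patterns)
    for node in tree_nodes:  # postorder
        if not node.children:
            continue
        partial = np.ones((n_patterns, N_CODONS))
        for child in node.children:
            p = p_of(child.length * params.branch_scale)
            if not child.children:
                contrib = p[:, patterns[tip_index[child.label]]].T
            else:
                contrib = partials.pop(id(child)) @ p.T
            partial *= contrib
        peak = partial.max(axis=1)
        peak[peak == 0] = 1.0
        partial /= peak[:, np.newaxis]
        log_scale += np.log(peak)
        partials[id(node)] = partial
    root_partial = partials.pop(id(tree_nodes[-1]))
    site_lik = root_partial @ params.codon_frequencies
    return float(np.dot(counts, np.log(site_lik) + log_scale))


_STARTS = ((0.2, 2.0, 1.0), (1.0, 1.0, 1.0), (0.05, 4.0, 0.5))


def estimate_dnds_ml(
    alignment: CodonAlignment, tree: Phylogeny
) -> tuple[CodonModelParams, float]:
    """Maximize the codon-model likelihood over (omega, kappa, branch_scale).

    Topology and relative branch lengths are fixed; only a global scale on
    branch lengths is free. Optimization runs in log-parameter space with
    bounded L-BFGS-B from several deterministic starts.

    Raises :class:`EstimationDegenerateError` for alignments with fewer than
    two variable codon columns.
    """
    tree_taxa = set(tree.tip_labels)
    if tree_taxa != set(alignment.taxa):
        raise InvalidArgumentError("alignment taxa do not match tree tips")

    taxa_order = tree.tip_labels
    patterns, counts = _pattern_table(alignment, taxa_order)
    variable = np.any(patterns != patterns[0], axis=0)
    if int(counts[variable].sum()) < 2:
        raise EstimationDegenerateError(
            "fewer than 2 variable codon columns; cannot estimate rates"
        )

    tip_index = {t: i for i, t in enumerate(taxa_order)}
    nodes = list(tree.postorder())
    freqs = np.full(N_CODONS, 1.0 / N_CODONS)

    lo = np.log([OMEGA_BOUNDS[0], KAPPA_BOUNDS[0], SCALE_BOUNDS[0]])
    hi = np.log([OMEGA_BOUNDS[1], KAPPA_BOUNDS[1], SCALE_BOUNDS[1]])

    def objective(theta: np.ndarray) -> float:
        omega, kappa, scale = np.exp(theta)
        params = CodonModelParams(omega, kappa, freqs, scale)
        return -_log_likelihood(nodes, tip_index, patterns, counts, params)

    best = None
    for start in _STARTS:
        theta0 = np.clip(np.log(start), lo, hi)
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    omega, kappa, scale = np.exp(best.x)
    params = CodonModelParams(float(omega), float(kappa), freqs, float(scale))
    return params, -float(best.fun)


def is_boundary(params: CodonModelParams, rel_tol: float = 1e-3) -> bool:
    """True if any ML estimate is pinned at an optimizer bound."""
    for value, (lo, hi) in (
        (params.omega, OMEGA_BOUNDS),
        (params.kappa, KAPPA_BOUNDS),
        (params.branch_scale, SCALE_BOUNDS),
    ):
        if value <= lo * (1 + rel_tol) or value >= hi * (1 - rel_tol):
            return True
    return False


# ---------------------------------------------------------------------------
# Nei–Gojobori counting estimator


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    Each position contributes syn/3 synonymous and nonsyn/3 nonsynonymous
    sites over its three possible changes; changes to stop codons contribute
    to neither class.
    """
    syn = 0.0
    nonsyn = 0.0
    aa = _TABLE.forward_table[codon]
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if _TABLE.forward_table[alt] == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


def _path_changes(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous change counts over minimal paths.

    All orderings of the differing positions are enumerated; paths passing
    through a stop codon are excluded (unless every path does).
    """
    diffs = [k for k in range(3) if codon_a[k] != codon_b[k]]
    if not diffs:
        return 0.0, 0.0

    import itertools

    paths = []
    for order in itertools.permutations(diffs):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            syn_step = _TABLE.forward_table[current] == _TABLE.forward_table[nxt]
            steps.append(syn_step)
            current = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # all paths stop-blocked; fall back to counting by position
        paths = [
            [
                _TABLE.forward_table.get(codon_a)
                == _TABLE.forward_table.get(codon_b)
            ]
            * len(diffs)
        ]
    syn = np.mean([sum(p) for p in paths])
    return float(syn), float(len(diffs) - syn)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return abs(-0.75 * math.log(1.0 - 4.0 * p / 3.0))


def estimate_dnds_ng86(
    seq_a: str, seq_b: str
) -> tuple[float, float, Optional[float]]:
    """Pairwise dN and dS by Nei–Gojobori counting with JC correction.

    Multi-step codon differences are averaged over all mutational pathways.
    Returns ``(dN, dS, dN/dS)`` with the ratio ``None`` when dS = 0.
    """
    if len(seq_a) != len(seq_b):
        raise InvalidArgumentError("sequences must have equal length")
    if len(seq_a) == 0 or len(seq_a) % 3 != 0:
        raise InvalidArgumentError("length must be positive, divisible by 3")

    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        for codon in (ca, cb):
            if codon in STOP_CODONS or codon not in CODON_INDEX:
                raise InvalidArgumentError(f"invalid or stop codon {codon!r}")
        sa, na = _codon_site_counts(ca)
        sb, nb = _codon_site_counts(cb)
        s_sites += (sa + sb) / 2
        n_sites += (na + nb) / 2
        sd, nd = _path_changes(ca, cb)
        s_diffs += sd
        n_diffs += nd

    p_s = s_diffs / s_sites if s_sites > 0 else 0.0
    p_n = n_diffs / n_sites if n_sites > 0 else 0.0
    d_s = _jukes_cantor(p_s)
    d_n = _jukes_cantor(p_n)
    if d_s == 0 or (math.isinf(d_s) and math.isinf(d_n)):
        ratio = None
    else:
        ratio = d_n / d_s  # 0 when dS is saturated but dN finite
    return d_n, d_s, ratio


# ---------------------------------------------------------------------------
# Retention filters


def count_mutations(tree_length: float, n_sites_nt: int) -> float:
    """Estimated mutation count: total tree length times alignment columns."""
    if tree_length < 0 or n_sites_nt < 0:
        raise InvalidArgumentError("inputs must be nonnegative")
    return float(tree_length) * float(n_sites_nt)


@dataclass(frozen=True)
class RetentionResult:
    lineages: tuple[str, ...]
    families: tuple[GeneFamilyEstimate, ...]
    exclusions: tuple[tuple[str, str, str], ...]  # (kind, identifier, reason)


def apply_retention_filters(
    estimates: Iterable[GeneFamilyEstimate],
    min_mutations: float = 32.0,
    min_fraction: float = 0.7,
) -> RetentionResult:
    """Retain families with enough mutations, inside lineages where enough
    families pass.

    A family passes iff ``mutation_count >= min_mutations``; a lineage is
    retained iff the passing fraction among its families is at least
    ``min_fraction``. Only passing families of retained lineages propagate.
    """
    estimates = list(estimates)
    if not estimates:
        raise InvalidArgumentError("no estimates supplied")

    by_lineage: dict[str, list[GeneFamilyEstimate]] = {}
    for est in estimates:
        by_lineage.setdefault(est.lineage_id, []).append(est)

    lineages: list[str] = []
    families: list[GeneFamilyEstimate] = []
    exclusions: list[tuple[str, str, str]] = []
    for lineage in sorted(by_lineage):
        members = by_lineage[lineage]
        passing = [m for m in members if m.mutation_count >= min_mutations]
        fraction = len(passing) / len(members)
        if fraction < min_fraction:
            exclusions.append(
                (
                    "lineage",
                    lineage,
                    f"only {len(passing)}/{len(members)} families with >= "
                    f"{min_mutations:g} mutations",
                )
            )
            continue
        lineages.append(lineage)
        for member in members:
            if member.mutation_count >= min_mutations:
                families.append(member)
            else:
                exclusions.append(
                    (
                        "family",
                        f"{lineage}/{member.gene_id}",
                        f"mutation count {member.mutation_count:g} < "
                        f"{min_mutations:g}",
                    )
                )
    return RetentionResult(tuple(lineages), tuple(families), tuple(exclusions))


def select_representative_paralog(
    groups: Mapping[str, Mapping[str, int]],
) -> dict[str, str]:
    """Pick one family per cross-lineage group: the one with most sequences,
    ties broken by lexicographically smallest family ID."""
    chosen: dict[str, str] = {}
    for group, members in groups.items():
        if not members:
            raise InvalidArgumentError(f"empty paralog group {group!r}")
        chosen[group] = min(members, key=lambda fam: (-members[fam], fam))
    return chosen


# ---------------------------------------------------------------------------
# FASTA I/O and alignment helpers


def read_alignment(path) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidArgumentError(f"no FASTA records in {path}")
    return CodonAlignment(
        tuple(r.id for r in records),
        tuple(str(r.seq).upper() for r in records),
    )


def write_alignment(alignment: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in zip(alignment.taxa, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def subset_alignment(
    alignment: CodonAlignment, taxa: Sequence[str]
) -> CodonAlignment:
    row_of = {t: i for i, t in enumerate(alignment.taxa)}
    missing = [t for t in taxa if t not in row_of]
    if missing:
        raise InvalidArgumentError(f"taxa not in alignment: {missing}")
    return CodonAlignment(
        tuple(taxa), tuple(alignment.sequences[row_of[t]] for t in taxa)
    )
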