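"""Gene gain/loss flux from presence/absence profiles on a rooted tree.

Ancestral presence/absence states are reconstructed by Fitch parsimony (a
transparent stand-in for probabilistic reconstruction; externally computed
state tables can be ingested instead). Gains and losses are then counted by
subtracting each branch's parent state from its child state, summed over all
gene families, and normalized by total tree length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from selscape.errors import FormatError, InvalidArgumentError
from selscape.trees import Phylogeny

__all__ = [
    "PresenceAbsenceMatrix",
    "AncestralStates",
    "FluxRates",
    "reconstruct_ancestral_states",
    "load_external_ancestral_states",
    "compute_flux",
    "read_presence_absence_fasta",
    "write_presence_absence_fasta",
    "write_ancestral_states_tsv",
]


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary genome x gene-family matrix."""

    genome_ids: tuple[str, ...]
    family_ids: tuple[str, ...]
    states: np.ndarray

    def __post_init__(self):
        states = np.asarray(self.states)
        if states.shape != (len(self.genome_ids), len(self.family_ids)):
            raise InvalidArgumentError("state matrix shape mismatch")
        if not np.isin(states, (0, 1)).all():
            raise InvalidArgumentError("states must be strictly binary")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise InvalidArgumentError("duplicate genome ids")
        object.__setattr__(self, "genome_ids", tuple(self.genome_ids))
        object.__setattr__(self, "family_ids", tuple(self.family_ids))
        object.__setattr__(self, "states", states.astype(np.int8))


@dataclass(frozen=True)
class AncestralStates:
    """Per-family binary state at every node (tips and internal)."""

    node_ids: tuple[str, ...]
    family_ids: tuple[str, ...]
    states: np.ndarray  # (n_nodes, n_families) in {0, 1}

    def __post_init__(self):
        states = np.asarray(self.states)
        if states.shape != (len(self.node_ids), len(self.family_ids)):
            raise InvalidArgumentError("ancestral state shape mismatch")
        if not np.isin(states, (0, 1)).all():
            raise InvalidArgumentError("states must be binary")
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        object.__setattr__(self, "family_ids", tuple(self.family_ids))
        object.__setattr__(self, "states", states.astype(np.int8))

    def state_of(self, node_id: str) -> np.ndarray:
        return self.states[self.node_ids.index(node_id)]


@dataclass(frozen=True)
class FluxRates:
    """Gain/loss totals and tree-length-normalized rates."""

    total_gains: int
    total_losses: int
    tree_length: float
    gain_rate: float
    loss_rate: float
    flux_ratio: Optional[float]  # None when no losses occurred

    @classmethod
    def from_counts(
        cls, gains: int, losses: int, tree_length: float
    ) -> "FluxRates":
        if tree_length <= 0:
            raise InvalidArgumentError("tree length must be positive")
        ratio = gains / losses if losses > 0 else None
        return cls(
            int(gains),
            int(losses),
            float(tree_length),
            gains / tree_length,
            losses / tree_length,
            ratio,
        )


# ---------------------------------------------------------------------------
# Fitch parsimony
#
# State sets are encoded as 2-bit masks: 1 = {absent}, 2 = {present},
# 3 = {either}; the up-pass intersects where possible else unions, the
# down-pass resolves ambiguity by inheriting the parent's state (root
# ambiguity resolves to present).


def reconstruct_ancestral_states(
    tree: Phylogeny, pam: PresenceAbsenceMatrix, method: str = "parsimony"
) -> AncestralStates:
    if method != "parsimony":
        raise InvalidArgumentError(f"unknown reconstruction method {method!r}")
    if set(tree.tip_labels) != set(pam.genome_ids):
        raise InvalidArgumentError(
            "tree tip labels do not match genome ids of the matrix"
        )

    n_fam = len(pam.family_ids)
    row_of = {g: i for i, g in enumerate(pam.genome_ids)}
    node_order = list(tree.preorder())
    postorder = list(tree.postorder())

    sets: dict[int, np.ndarray] = {}
    for node in postorder:
        if node.is_leaf:
            tip = pam.states[row_of[node.label]]
            sets[id(node)] = np.where(tip == 1, 2, 1).astype(np.int8)
        else:
            children = [sets[id(c)] for c in node.children]
            inter = children[0].copy()
            union = children[0].copy()
            for child in children[1:]:
                inter &= child
                union |= child
            sets[id(node)] = np.where(inter != 0, inter, union).astype(np.int8)

    states: dict[int, np.ndarray] = {}
    for node in node_order:
        own = sets[id(node)]
        if node.parent is None:
            resolved = np.where(own == 1, 0, 1)  # ambiguity (3) -> present
        else:
            parent = states[id(node.parent)]
            parent_bit = np.where(parent == 1, 2, 1)
            keep_parent = (own & parent_bit) != 0
            resolved = np.where(keep_parent, parent, np.where(own == 2, 1, 0))
        states[id(node)] = resolved.astype(np.int8)

    node_ids = [n.label for n in node_order]
    matrix = np.vstack([states[id(n)] for n in node_order])
    return AncestralStates(tuple(node_ids), pam.family_ids, matrix)


def load_external_ancestral_states(
    tree: Phylogeny, path
) -> AncestralStates:
    """Load a node x family TSV of states or presence probabilities.

    Probabilities >= 0.5 map to present. Every node of the tree must appear
    as a row (index column holds node labels).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    node_labels = tree.node_labels()
    missing = [n for n in node_labels if n not in frame.index]
    if missing:
        raise FormatError(f"ancestral state table missing node {missing[0]!r}")
    values = frame.loc[node_labels].to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = frame.columns[np.isnan(values).any(axis=0)][0]
        raise FormatError(f"missing state values for family {bad!r}")
    states = (values >= 0.5).astype(np.int8)
    return AncestralStates(
        tuple(node_labels), tuple(str(c) for c in frame.columns), states
    )


def compute_flux(tree: Phylogeny, ancestral: AncestralStates) -> FluxRates:
    """Count per-branch state changes and normalize by total tree length.

    For every branch and family, a 0→1 change counts toward gains and a 1→0
    change toward losses; the root has no parent branch and contributes no
    change. ``flux_ratio`` is ``None`` (undefined) when no losses occurred.
    """
    node_labels = set(tree.node_labels())
    if not node_labels.issubset(set(ancestral.node_ids)):
        missing = sorted(node_labels - set(ancestral.node_ids))
        raise InvalidArgumentError(f"ancestral states missing node {missing[0]!r}")

    index = {n: i for i, n in enumerate(ancestral.node_ids)}
    gains = losses = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        delta = (
            ancestral.states[index[node.label]].astype(int)
            - ancestral.states[index[node.parent.label]]
        )
        gains += int((delta > 0).sum())
        losses += int((delta < 0).sum())
    total = tree.total_length()
    return FluxRates.from_counts(gains, losses, total)


# ---------------------------------------------------------------------------
# I/O: presence/absence FASTA ('0'/'1' strings) + companion family map


def read_presence_absence_fasta(
    fasta_path, family_map_path=None
) -> PresenceAbsenceMatrix:
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no records in {fasta_path}")
    genome_ids = [r.id for r in records]
    rows = []
    for record in records:
        seq = str(record.seq)
        if set(seq) - {"0", "1"}:
            raise FormatError(f"non-binary characters in record {record.id!r}")
        rows.append([int(c) for c in seq])
    states = np.asarray(rows, dtype=np.int8)

    if family_map_path is not None:
        mapping = pd.read_csv(family_map_path, sep="\t")
        if not {"column", "family_id"}.issubset(mapping.columns):
            raise FormatError("family map needs 'column' and 'family_id'")
        mapping = mapping.sort_values("column")
        if len(mapping) != states.shape[1]:
            raise FormatError("family map length does not match sequences")
        family_ids = tuple(str(f) for f in mapping["family_id"])
    else:
        family_ids = tuple(f"fam{i:05d}" for i in range(states.shape[1]))
    return PresenceAbsenceMatrix(tuple(genome_ids), family_ids, states)


def write_presence_absence_fasta(
    pam: PresenceAbsenceMatrix, fasta_path, family_map_path=None
) -> None:
    records = [
        SeqRecord(Seq("".join(str(s) for s in row)), id=genome, description="")
        for genome, row in zip(pam.genome_ids, pam.states)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if family_map_path is not None:
        pd.DataFrame(
            {"column": range(len(pam.family_ids)), "family_id": pam.family_ids}
        ).to_csv(family_map_path, sep="\t", index=False)


def write_ancestral_states_tsv(ancestral: AncestralStates, path) -> None:
    frame = pd.DataFrame(
        ancestral.states, index=ancestral.node_ids, columns=ancestral.family_ids
    )
    frame.index.name = "node_id"
    frame.to_csv(path, sep="\t")
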