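"""Family network alignment: remapping PENs onto an MSSA and commonality.

Members of a structural family are related through a multiple structure-based
sequence alignment (MSSA, e.g. MUSTANG output).  Aligned columns define
"equivalent residues" across members; each member's thresholded network is
remapped from residue space into column space, with alignment gaps becoming
*virtual nodes* that can never carry an edge (the stored sentinel energy for a
virtual pair is +100 kJ/mol, far above any meaningful cutoff, but zero degree
is also enforced structurally).  The commonality coefficient of a column pair,
cc_ij = X_ij / M, is the fraction of the M members whose remapped network has
that edge; thresholding cc yields the family network f-PEN_e(cc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO

from .network import ClusterSet, ThresholdedNetwork, _component_clusters

#: Sentinel energy (kJ/mol) stored for any pair touching a virtual node.
VIRTUAL_NODE_ENERGY = 100.0

GAP_CHARS = frozenset("-.")


class MSSAFormatError(ValueError):
    """Raised for malformed alignments (ragged lengths, duplicate ids, all-gap rows)."""


@dataclass
class MSSA:
    """Multiple structure-based sequence alignment of M members over L columns.

    ``mapping[member]`` is a length-L integer array giving, per column, the
    1-based residue index of that member, or 0 at gap columns.
    """

    member_ids: list[str]
    sequences: dict  # member_id -> aligned string of length L
    mapping: dict = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise MSSAFormatError("duplicate member ids in alignment")
        lengths = {len(self.sequences[m]) for m in self.member_ids}
        if len(lengths) != 1:
            raise MSSAFormatError(f"aligned lengths disagree: {sorted(lengths)}")
        self.mapping = {}
        for m in self.member_ids:
            idx = np.zeros(self.L, dtype=int)
            pos = 0
            for c, ch in enumerate(self.sequences[m]):
                if ch not in GAP_CHARS:
                    pos += 1
                    idx[c] = pos
            if pos == 0:
                raise MSSAFormatError(f"member {m!r} maps no columns (all gaps)")
            self.mapping[m] = idx

    @property
    def L(self) -> int:
        return len(self.sequences[self.member_ids[0]])

    @property
    def M(self) -> int:
        return len(self.member_ids)

    def n_residues(self, member: str) -> int:
        return int(self.mapping[member].max())

    def gap_columns(self, member: str) -> frozenset:
        """0-based columns that are gaps for ``member``."""
        return frozenset(int(c) for c in np.nonzero(self.mapping[member] == 0)[0])

    def column_of_residue(self, member: str, residue_index: int) -> int:
        """0-based column holding the member's 1-based ``residue_index``."""
        cols = np.nonzero(self.mapping[member] == residue_index)[0]
        if cols.size == 0:
            raise KeyError(f"member {member!r} has no residue {residue_index}")
        return int(cols[0])


def read_mssa(path: str | Path) -> MSSA:
    """Read an aligned FASTA (gap character '-') into an MSSA."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise MSSAFormatError(f"cannot parse {path} as an alignment: {exc}") from exc
    ids = [rec.id for rec in aln]
    seqs = {rec.id: str(rec.seq).upper() for rec in aln}
    if len(seqs) != len(ids):
        raise MSSAFormatError("duplicate member ids in alignment")
    return MSSA(member_ids=ids, sequences=seqs)


@dataclass
class RemappedPEN:
    """A member's PEN_e re-indexed onto MSSA columns (0-based).

    ``edges`` hold ordered column pairs; ``virtual_nodes`` are this member's
    gap columns and are guaranteed edge-free.  ``energies``, if carried, is an
    L x L matrix with the +100 kJ/mol sentinel on virtual pairs and NaN where
    the source matrix had no entry.
    """

    member_id: str
    L: int
    edges: frozenset
    virtual_nodes: frozenset
    cutoff_e: float
    energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a in self.virtual_nodes or b in self.virtual_nodes:
                raise ValueError(
                    f"member {self.member_id!r}: edge ({a},{b}) touches a virtual node"
                )
            if not (0 <= a < b < self.L):
                raise ValueError(f"edge ({a},{b}) outside columns 0..{self.L - 1}")

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.L, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg


@dataclass
class FamilyNetwork:
    """Commonality coefficients over aligned columns at one energy cutoff.

    ``cc_matrix[i, j] = X[i, j] / M`` where X counts members possessing edge
    (i, j) in their remapped networks; members gapped at i or j cannot possess
    it and contribute 0 while M stays the family size.
    """

    cutoff_e: float
    member_ids: list[str]
    cc_matrix: np.ndarray
    x_matrix: np.ndarray
    virtual_counts: np.ndarray  # per column, number of members gapped there

    @property
    def M(self) -> int:
        return len(self.member_ids)

    @property
    def L(self) -> int:
        return self.cc_matrix.shape[0]


def remap_pen(
    net: ThresholdedNetwork,
    mssa: MSSA,
    member_id: str,
    energies: "np.ndarray | None" = None,
) -> RemappedPEN:
    """Re-index a member's network from residue space onto MSSA columns.

    The member's i-th residue (alignment order) must be the i-th node of
    ``net``; a node count differing from the member's non-gap column count is
    a consistency error.  ``energies`` may pass the member's residue-space
    energy matrix (same node order) to carry energies into column space.
    """
    if member_id not in mssa.mapping:
        raise KeyError(f"member {member_id!r} not in alignment")
    n_res = mssa.n_residues(member_id)
    if len(net.nodes) != n_res:
        raise ValueError(
            f"member {member_id!r}: network has {len(net.nodes)} nodes but the "
            f"alignment maps {n_res} residues"
        )
    node_index = {node: k for k, node in enumerate(net.nodes)}
    # column holding residue k (0-based residue order -> 0-based column)
    res_to_col = np.zeros(n_res, dtype=int)
    for col, ridx in enumerate(mssa.mapping[member_id]):
        if ridx > 0:
            res_to_col[ridx - 1] = col
    edges = set()
    for u, v in net.edges:
        a = res_to_col[node_index[u]]
        b = res_to_col[node_index[v]]
        edges.add((min(a, b), max(a, b)))
    virtual = mssa.gap_columns(member_id)

    col_energies = None
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        if energies.shape != (n_res, n_res):
            raise ValueError("energies must be square over the member's residues")
        col_energies = np.full((mssa.L, mssa.L), np.nan)
        real = np.asarray(sorted(set(range(mssa.L)) - virtual), dtype=int)
        col_energies[np.ix_(real, real)] = energies
        for c in virtual:
            col_energies[c, :] = VIRTUAL_NODE_ENERGY
            col_energies[:, c] = VIRTUAL_NODE_ENERGY
    return RemappedPEN(
        member_id=member_id,
        L=mssa.L,
        edges=frozenset(edges),
        virtual_nodes=virtual,
        cutoff_e=net.cutoff_e,
        energies=col_energies,
    )


def commonality(remapped: Sequence[RemappedPEN]) -> FamilyNetwork:
    """Per-edge commonality coefficients cc_ij = X_ij / M over a family."""
    if len(remapped) < 2:
        raise ValueError("a family needs at least two members")
    L = remapped[0].L
    e = remapped[0].cutoff_e
    for r in remapped[1:]:
        if r.L != L:
            raise ValueError("remapped networks have differing alignment lengths")
        if r.cutoff_e != e:
            raise ValueError("remapped networks were thresholded at different cutoffs")
    M = len(remapped)
    x = np.zeros((L, L), dtype=int)
    virtual_counts = np.zeros(L, dtype=int)
    for r in remapped:
        for a, b in r.edges:
            x[a, b] += 1
            x[b, a] += 1
        for c in r.virtual_nodes:
            virtual_counts[c] += 1
    return FamilyNetwork(
        cutoff_e=e,
        member_ids=[r.member_id for r in remapped],
        cc_matrix=x / M,
        x_matrix=x,
        virtual_counts=virtual_counts,
    )


def fpen_edges(fam: FamilyNetwork, cc_threshold: float) -> set:
    """Column pairs of f-PEN_e(cc): cc_ij >= cc_threshold (0 < cc <= 1)."""
    if not (0 < cc_threshold <= 1):
        raise ValueError("cc_threshold must lie in (0, 1]")
    iu, ju = np.nonzero(np.triu(fam.cc_matrix, k=1) >= cc_threshold)
    return {(int(a), int(b)) for a, b in zip(iu, ju)}


def family_clusters(
    fam: FamilyNetwork, cc_threshold: float, min_size: int = 3
) -> ClusterSet:
    """Connected sub-graphs of f-PEN_e(cc) with at least ``min_size`` columns."""
    edges = fpen_edges(fam, cc_threshold)
    nodes = sorted({c for e in edges for c in e})
    return _component_clusters(nodes, edges, min_size)


def family_hubs(
    remapped: Sequence[RemappedPEN],
    degree_min: int = 3,
    member_fraction: float = 0.7,
) -> set:
    """Columns that are hubs (degree >= degree_min) in >= member_fraction of members.

    Virtual nodes have zero degree and therefore count against the fraction.
    """
    if not (0 < member_fraction <= 1):
        raise ValueError("member_fraction must lie in (0, 1]")
    if degree_min < 1:
        raise ValueError("degree_min must be >= 1")
    if not remapped:
        return set()
    M = len(remapped)
    L = remapped[0].L
    tally = np.zeros(L, dtype=int)
    for r in remapped:
        tally += (r.degrees() >= degree_min).astype(int)
    return {int(c) for c in np.nonzero(tally / M >= member_fraction)[0]}
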