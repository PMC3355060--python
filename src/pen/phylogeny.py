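"""Interaction-conservation phylogeny.

Two remote homologues that share few sequence identities can still share most
of their stabilizing interactions.  This module scores that sharing: for each
pair of members remapped onto common alignment columns, the conservation
matrix S marks column pairs whose edge is present in both networks, the
similarity score SS is the conserved fraction of edges (Jaccard index of the
two edge sets by default), and the distance D = 1 − SS feeds agglomerative
clustering (UPGMA by default) whose dendrogram is emitted as Newick.

Because edges never touch virtual (gap) columns, S is automatically zero
wherever either member is gapped.  An optional energy mode additionally
requires the two interaction energies to agree within a tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .family import RemappedPEN

DENOMINATORS = ("union", "min", "mean")
LINKAGES = ("average", "single", "complete")
DISTANCE_TRANSFORMS = ("one_minus", "neglog")

#: Cap applied to -ln(SS) when SS = 0, so the transform stays finite.
_NEGLOG_CAP = 50.0


@dataclass
class PairSimilarity:
    """Conserved-edge similarity between two remapped member networks."""

    member_a: str
    member_b: str
    s_matrix: np.ndarray  # L x L 0/1, symmetric: edge present in both members
    n_conserved: int
    denominator: int | float
    ss: float


@dataclass
class DistanceSet:
    """Pairwise interaction-conservation distances over a family."""

    member_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.member_ids)
        if self.d.shape != (m, m):
            raise ValueError("distance matrix shape must match member count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def _conserved_edges(
    rem_a: RemappedPEN, rem_b: RemappedPEN, tol: float | None
) -> set:
    shared = rem_a.edges & rem_b.edges
    if tol is None:
        return set(shared)
    if rem_a.energies is None or rem_b.energies is None:
        raise ValueError("energy-tolerance mode needs remapped networks with energies")
    out = set()
    for a, b in shared:
        ea = rem_a.energies[a, b]
        eb = rem_b.energies[a, b]
        if np.isfinite(ea) and np.isfinite(eb) and abs(ea - eb) <= tol:
            out.add((a, b))
    return out


def pair_similarity(
    rem_a: RemappedPEN,
    rem_b: RemappedPEN,
    tol: float | None = None,
    denominator: str = "union",
) -> PairSimilarity:
    """Similarity score SS between two members' remapped networks.

    Default mode: an edge is conserved when present in both networks at the
    shared cutoff, and SS = |conserved| / |union of edge sets| (Jaccard).
    ``denominator`` may instead use the smaller (``min``) or the mean
    (``mean``) of the two edge counts.  With ``tol`` set, conservation also
    requires |E_a − E_b| <= tol kJ/mol for the pair's stored energies.
    Two empty networks are identically empty: SS = 1 with a warning.
    """
    if rem_a.L != rem_b.L:
        raise ValueError("remapped networks have differing alignment lengths")
    if rem_a.cutoff_e != rem_b.cutoff_e:
        raise ValueError("remapped networks were thresholded at different cutoffs")
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    conserved = _conserved_edges(rem_a, rem_b, tol)
    na, nb = len(rem_a.edges), len(rem_b.edges)
    if denominator == "union":
        denom = len(rem_a.edges | rem_b.edges)
    elif denominator == "min":
        denom = min(na, nb)
    else:
        denom = 0.5 * (na + nb)
    if denom == 0:
        warnings.warn(
            f"members {rem_a.member_id!r}/{rem_b.member_id!r} have no edges; "
            "SS defined as 1 (identical emptiness)",
            stacklevel=2,
        )
        ss = 1.0
    else:
        ss = len(conserved) / denom
    s = np.zeros((rem_a.L, rem_a.L), dtype=np.uint8)
    for a, b in conserved:
        s[a, b] = s[b, a] = 1
    return PairSimilarity(
        member_a=rem_a.member_id,
        member_b=rem_b.member_id,
        s_matrix=s,
        n_conserved=len(conserved),
        denominator=denom,
        ss=float(ss),
    )


def similarity_matrix(
    remapped: Sequence[RemappedPEN],
    tol: float | None = None,
    denominator: str = "union",
) -> tuple[list[str], np.ndarray]:
    """All-pairs SS matrix with unit diagonal, member order preserved."""
    m = len(remapped)
    if m < 2:
        raise ValueError("need at least two members")
    ss = np.eye(m)
    for i, j in combinations(range(m), 2):
        p = pair_similarity(remapped[i], remapped[j], tol=tol, denominator=denominator)
        ss[i, j] = ss[j, i] = p.ss
    return [r.member_id for r in remapped], ss


def distance_matrix(
    pairs: Sequence[PairSimilarity],
    member_ids: Sequence[str],
    transform: str = "one_minus",
) -> DistanceSet:
    """Distances from pairwise similarity scores.

    Default D = 1 − SS; ``neglog`` uses −ln(SS), capped for SS = 0.  Every
    unordered member pair must be covered.
    """
    if transform not in DISTANCE_TRANSFORMS:
        raise ValueError(f"transform must be one of {DISTANCE_TRANSFORMS}")
    ids = list(member_ids)
    index = {m: k for k, m in enumerate(ids)}
    m = len(ids)
    ss = np.full((m, m), np.nan)
    np.fill_diagonal(ss, 1.0)
    for p in pairs:
        if p.member_a not in index or p.member_b not in index:
            raise ValueError(f"pair {p.member_a}/{p.member_b} names an unknown member")
        i, j = index[p.member_a], index[p.member_b]
        ss[i, j] = ss[j, i] = p.ss
    if np.any(np.isnan(ss)):
        i, j = map(int, np.argwhere(np.isnan(ss))[0])
        raise ValueError(f"missing similarity for pair {ids[i]}/{ids[j]}")
    if transform == "one_minus":
        d = 1.0 - ss
    else:
        with np.errstate(divide="ignore"):
            d = np.minimum(-np.log(np.clip(ss, 0.0, 1.0)), _NEGLOG_CAP)
    np.fill_diagonal(d, 0.0)
    return DistanceSet(member_ids=ids, d=d)


def _newick(node, labels, parent_height: float) -> str:
    height = 0.0 if node.is_leaf() else node.dist / 2.0
    length = parent_height - height
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.10g}"
    left = _newick(node.left, labels, height)
    right = _newick(node.right, labels, height)
    return f"({left},{right}):{length:.10g}"


def build_tree(dist: DistanceSet, linkage: str = "average") -> str:
    """Agglomerative dendrogram over the distance set, serialized as Newick.

    Node heights are half the merge distance (the UPGMA/ultrametric
    convention), so two leaves at distance d sit under a root of height d/2.
    Members are processed in lexicographic id order, making ties — and
    therefore the output string — deterministic under input permutation.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(dist.member_ids) < 2:
        raise ValueError("need at least two members to build a tree")
    order = np.argsort(np.asarray(dist.member_ids, dtype=object))
    labels = [dist.member_ids[k] for k in order]
    d = dist.d[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    root = hierarchy.to_tree(z)
    body = _newick(root, labels, root.dist / 2.0)
    # the root itself has no branch; strip its zero-length suffix
    body = body.rsplit(":", 1)[0]
    return body + ";"


def cut_into_clades(dist: DistanceSet, k: int, linkage: str = "average") -> list[set]:
    """Partition members into k clades by cutting the dendrogram."""
    order = np.argsort(np.asarray(dist.member_ids, dtype=object))
    labels = [dist.member_ids[i] for i in order]
    d = dist.d[np.ix_(order, order)]
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    assign = hierarchy.fcluster(z, t=k, criterion="maxclust")
    clades: dict[int, set] = {}
    for lab, c in zip(labels, assign):
        clades.setdefault(int(c), set()).add(lab)
    return sorted(clades.values(), key=lambda s: sorted(s))
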