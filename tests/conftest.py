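"""Shared fixtures: random matrices/graphs, brute-force oracles, a worked two-member family."""

from __future__ import annotations

import numpy as np
import pytest

from pen.energy import EnergyMatrix
from pen.family import MSSA
from pen.network import ThresholdedNetwork, threshold_network


def random_energy_matrix(rng: np.random.Generator, n: int) -> EnergyMatrix:
    """Random symmetric matrix with energies in [-30, 0] and ~20% absent entries."""
    values = np.full((n, n), np.nan)
    iu, ju = np.triu_indices(n, k=1)
    e = rng.uniform(-30.0, 0.0, size=iu.size)
    absent = rng.random(iu.size) < 0.2
    e[absent] = np.nan
    values[iu, ju] = e
    values[ju, iu] = e
    ids = [f"R{k + 1}" for k in range(n)]
    return EnergyMatrix(residue_ids=ids, values=values, mode="full")


def random_network(rng: np.random.Generator, n: int, p: float = 0.15) -> ThresholdedNetwork:
    nodes = tuple(f"R{k + 1}" for k in range(n))
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((nodes[i], nodes[j]))
    return ThresholdedNetwork(nodes=nodes, edges=frozenset(edges), cutoff_e=-10.0)


def bfs_components(nodes, edges) -> list[set]:
    """Independent breadth-first component oracle."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        seen.add(start)
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def fig2_family():
    """A two-member beta-loop-beta worked example.

    Member s1 has a short loop (gaps at columns 4-5 of the 10-column MSSA),
    member s2 is ungapped.  Both members carry an interaction between the
    residues mapped to columns 0 and 9 (the aligned strand tips); s2 also has
    a private edge.  Returns (mssa, nets, matrices).
    """
    mssa = MSSA(
        member_ids=["s1", "s2"],
        sequences={"s1": "VLKY--AGIC", "s2": "VLKYPQAGIC"},
    )
    cutoff = -10.0

    def member_matrix(member: str, strong_pairs: list[tuple[int, int]]) -> EnergyMatrix:
        n = mssa.n_residues(member)
        values = np.full((n, n), np.nan)
        iu, ju = np.triu_indices(n, k=1)
        values[iu, ju] = values[ju, iu] = -2.0  # background, above cutoff
        for i, j in strong_pairs:
            values[i, j] = values[j, i] = -15.0
        ids = [f"{member}:R{k + 1}" for k in range(n)]
        return EnergyMatrix(residue_ids=ids, values=values, mode="full")

    # s1 residues 1..8 map to columns 0..3, 6..9 -> edge cols (0,9) = residues (0,7)
    m1 = member_matrix("s1", [(0, 7)])
    # s2 residues 1..10 map to columns identically -> edge cols (0,9) = residues (0,9)
    m2 = member_matrix("s2", [(0, 9), (2, 6)])
    nets = {
        "s1": threshold_network(m1, cutoff),
        "s2": threshold_network(m2, cutoff),
    }
    return mssa, nets, {"s1": m1, "s2": m2}
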