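"""Residue–residue non-bonded interaction energies.

A Protein Energy Network (PEN) weights every residue pair by the sum of its
atomic Coulomb and Lennard-Jones interaction energies, averaged over a
conformational ensemble.  This module computes that weighted substrate: the
:class:`EnergyMatrix`.  Conventions follow molecular-mechanics force fields —
charges in elementary-charge units, distances in nm, sigma in nm, epsilon and
energies in kJ/mol.  Atomic coordinates are carried in Å (the PDB convention)
and converted to nm internally.

Self-pairs and sequential neighbours (|i − j| ≤ 1 within one chain) are
excluded from the matrix: their through-bond coupling would otherwise swamp
the non-covalent signal the network is built to expose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

#: Molecular-mechanics Coulomb prefactor, kJ·mol^-1·nm·e^-2.
COULOMB_CONSTANT = 138.935485

ANGSTROM_PER_NM = 10.0

MODE_FULL = "full"
MODE_LJ_ONLY = "lj_only"

COMBINING_RULES = ("lorentz_berthelot", "geometric")


class EnergyDomainError(ValueError):
    """Raised when an energy term is evaluated outside its domain (e.g. r <= 0)."""


class ParameterizationError(ValueError):
    """Raised when a required force-field parameter is missing for an atom."""


def coulomb_energy(q_i: float, q_j: float, r: float, dielectric: float = 1.0) -> float:
    """Electrostatic pair energy f*q_i*q_j/(eps_r*r) in kJ/mol.

    Parameters
    ----------
    q_i, q_j:
        Partial charges in elementary-charge units.
    r:
        Separation in nm; must be positive.
    dielectric:
        Relative dielectric constant eps_r (> 0); 1 corresponds to the raw
        vacuum molecular-mechanics potential.
    """
    if not all(math.isfinite(v) for v in (q_i, q_j, r, dielectric)):
        raise EnergyDomainError("coulomb_energy requires finite inputs")
    if r <= 0:
        raise EnergyDomainError(f"interatomic distance must be positive, got r={r}")
    if dielectric <= 0:
        raise EnergyDomainError(f"dielectric must be positive, got {dielectric}")
    return COULOMB_CONSTANT * q_i * q_j / (dielectric * r)


def lj_energy(sigma_ij: float, epsilon_ij: float, r: float) -> float:
    """Lennard-Jones 12-6 pair energy 4*eps*[(sigma/r)^12 - (sigma/r)^6] in kJ/mol.

    Zero at r = sigma and −epsilon at the minimum r = 2^(1/6)*sigma.
    """
    if not all(math.isfinite(v) for v in (sigma_ij, epsilon_ij, r)):
        raise EnergyDomainError("lj_energy requires finite inputs")
    if r <= 0:
        raise EnergyDomainError(f"interatomic distance must be positive, got r={r}")
    if sigma_ij <= 0:
        raise EnergyDomainError(f"sigma must be positive, got {sigma_ij}")
    if epsilon_ij < 0:
        raise EnergyDomainError(f"epsilon must be non-negative, got {epsilon_ij}")
    sr6 = (sigma_ij / r) ** 6
    return 4.0 * epsilon_ij * (sr6 * sr6 - sr6)


def combine_lj(
    sigma_i: float,
    epsilon_i: float,
    sigma_j: float,
    epsilon_j: float,
    rule: str = "lorentz_berthelot",
) -> tuple[float, float]:
    """Cross-interaction (sigma_ij, epsilon_ij) under the given combining rule.

    ``lorentz_berthelot``: arithmetic-mean sigma, geometric-mean epsilon.
    ``geometric``: geometric mean for both.
    """
    if rule == "lorentz_berthelot":
        return 0.5 * (sigma_i + sigma_j), math.sqrt(epsilon_i * epsilon_j)
    if rule == "geometric":
        return math.sqrt(sigma_i * sigma_j), math.sqrt(epsilon_i * epsilon_j)
    raise ValueError(f"unknown combining rule {rule!r}; expected one of {COMBINING_RULES}")


@dataclass
class AtomRecord:
    """One parameterized atom.

    ``coordinates`` are in Å; ``lj_sigma`` in nm; ``lj_epsilon`` in kJ/mol;
    ``partial_charge`` in elementary-charge units. ``residue_index`` is the
    1-based position of the parent residue in its chain.
    """

    atom_name: str
    residue_index: int
    coordinates: np.ndarray
    partial_charge: float
    lj_sigma: float
    lj_epsilon: float

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,):
            raise ValueError("coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.lj_sigma <= 0:
            raise ValueError(f"lj_sigma must be positive for atom {self.atom_name}")
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be non-negative for atom {self.atom_name}")
        if not math.isfinite(self.partial_charge):
            raise ValueError(f"non-finite charge for atom {self.atom_name}")


@dataclass
class StructureEnsemble:
    """A fixed atom roster with one or more coordinate frames.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å over an identical atom
    ordering; per-atom force-field parameters are carried alongside.  Residues
    are identified by ``residue_ids`` and located by (``chain_ids``,
    ``seq_positions``) for the sequential-neighbour exclusion.
    """

    residue_ids: list[str]
    chain_ids: list[str]
    seq_positions: list[int]
    atom_residue: np.ndarray  # (n_atoms,) index into residue_ids
    atom_names: list[str]
    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    frames: np.ndarray  # (n_frames, n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        n = len(self.residue_ids)
        if not (len(self.chain_ids) == len(self.seq_positions) == n):
            raise ValueError("residue metadata lengths disagree")
        a = self.atom_residue.shape[0]
        if self.frames.ndim != 3 or self.frames.shape[1] != a or self.frames.shape[2] != 3:
            raise ValueError(
                "frames must have shape (n_frames, n_atoms, 3) with a constant atom roster"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        for arr, name in ((self.charges, "charges"), (self.sigmas, "sigmas"), (self.epsilons, "epsilons")):
            if arr.shape[0] != a:
                raise ValueError(f"{name} length does not match atom count")
        if np.any(self.atom_residue < 0) or np.any(self.atom_residue >= n):
            raise ValueError("atom_residue index out of range")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def n_atoms(self) -> int:
        return self.atom_residue.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def atoms_of(self, residue: int, frame: int = 0) -> list[AtomRecord]:
        """Materialize the AtomRecords of one residue in one frame."""
        idx = np.nonzero(self.atom_residue == residue)[0]
        return [
            AtomRecord(
                atom_name=self.atom_names[k],
                residue_index=self.seq_positions[residue],
                coordinates=self.frames[frame, k],
                partial_charge=self.charges[k],
                lj_sigma=self.sigmas[k],
                lj_epsilon=self.epsilons[k],
            )
            for k in idx
        ]


@dataclass
class EnergyMatrix:
    """Symmetric averaged residue-pair interaction energies in kJ/mol.

    Absent entries (self-pairs, sequential neighbours) are NaN.  ``mode``
    records whether electrostatics were included (``full``) or only the
    Lennard-Jones term (``lj_only``).
    """

    residue_ids: list[str]
    values: np.ndarray
    mode: str = MODE_FULL
    n_frames: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over residue_ids")
        if not np.array_equal(np.isnan(self.values), np.isnan(self.values.T)) or not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("energy matrix must be symmetric")
        if self.mode not in (MODE_FULL, MODE_LJ_ONLY):
            raise ValueError(f"mode must be '{MODE_FULL}' or '{MODE_LJ_ONLY}'")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def pairs(self) -> Iterator[tuple[int, int, float]]:
        """Yield (i, j, energy) for every present entry with i < j."""
        n = self.n_residues
        for i in range(n):
            for j in range(i + 1, n):
                v = self.values[i, j]
                if not np.isnan(v):
                    yield i, j, float(v)

    def get(self, res_i: str, res_j: str) -> float:
        i = self.residue_ids.index(res_i)
        j = self.residue_ids.index(res_j)
        return float(self.values[i, j])


def residue_pair_energy(
    atoms_i: Sequence[AtomRecord],
    atoms_j: Sequence[AtomRecord],
    mode: str = MODE_FULL,
    dielectric: float = 1.0,
    combining_rule: str = "lorentz_berthelot",
) -> float:
    """Total inter-residue energy: sum of LJ (+ Coulomb in ``full`` mode) over all atom pairs."""
    if not atoms_i or not atoms_j:
        raise ValueError("both atom lists must be non-empty")
    total = 0.0
    for a in atoms_i:
        for b in atoms_j:
            r_nm = float(np.linalg.norm(a.coordinates - b.coordinates)) / ANGSTROM_PER_NM
            if r_nm <= 0:
                raise EnergyDomainError(
                    f"overlapping atoms {a.atom_name!r} and {b.atom_name!r} (r = 0)"
                )
            sig, eps = combine_lj(a.lj_sigma, a.lj_epsilon, b.lj_sigma, b.lj_epsilon, combining_rule)
            total += lj_energy(sig, eps, r_nm)
            if mode == MODE_FULL:
                total += coulomb_energy(a.partial_charge, b.partial_charge, r_nm, dielectric)
    return total


def _sequential_neighbour_mask(ensemble: StructureEnsemble) -> np.ndarray:
    """Boolean (n, n) mask of excluded residue pairs: diagonal and |i−j| <= 1 in-chain."""
    chains = np.asarray(ensemble.chain_ids, dtype=object)
    seq = np.asarray(ensemble.seq_positions, dtype=int)
    same_chain = chains[:, None] == chains[None, :]
    close = np.abs(seq[:, None] - seq[None, :]) <= 1
    mask = same_chain & close
    np.fill_diagonal(mask, True)
    return mask


def build_energy_matrix(
    ensemble: StructureEnsemble,
    mode: str = MODE_FULL,
    dielectric: float = 1.0,
    combining_rule: str = "lorentz_berthelot",
    distance_cutoff: float | None = None,
) -> EnergyMatrix:
    """Averaged residue-pair energy matrix over all frames of an ensemble.

    Every non-sequential residue pair gets the atom-pair-summed LJ (+ Coulomb
    in ``full`` mode) energy, arithmetically averaged over frames with equal
    weights.  ``distance_cutoff`` (nm), if given, zeroes atom-pair terms beyond
    that separation — a speed knob, off by default.
    """
    if mode not in (MODE_FULL, MODE_LJ_ONLY):
        raise ValueError(f"mode must be '{MODE_FULL}' or '{MODE_LJ_ONLY}'")
    if combining_rule not in COMBINING_RULES:
        raise ValueError(f"unknown combining rule {combining_rule!r}")
    n = ensemble.n_residues
    a = ensemble.n_atoms

    if combining_rule == "lorentz_berthelot":
        sig_ij = 0.5 * (ensemble.sigmas[:, None] + ensemble.sigmas[None, :])
    else:
        sig_ij = np.sqrt(ensemble.sigmas[:, None] * ensemble.sigmas[None, :])
    eps_ij = np.sqrt(ensemble.epsilons[:, None] * ensemble.epsilons[None, :])
    q_ij = ensemble.charges[:, None] * ensemble.charges[None, :]

    iu, ju = np.triu_indices(a, k=1)
    res_i = ensemble.atom_residue[iu]
    res_j = ensemble.atom_residue[ju]
    inter = res_i != res_j

    acc = np.zeros((n, n), dtype=float)
    for f in range(ensemble.n_frames):
        coords_nm = ensemble.frames[f] / ANGSTROM_PER_NM
        diff = coords_nm[iu] - coords_nm[ju]
        r = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        bad = inter & (r <= 0)
        if np.any(bad):
            k = int(np.nonzero(bad)[0][0])
            raise EnergyDomainError(
                f"overlapping atoms {ensemble.atom_names[iu[k]]!r} and "
                f"{ensemble.atom_names[ju[k]]!r} in frame {f} (r = 0)"
            )
        sel = inter.copy()
        if distance_cutoff is not None:
            sel &= r <= distance_cutoff
        rs = r[sel]
        sr6 = (sig_ij[iu[sel], ju[sel]] / rs) ** 6
        e = 4.0 * eps_ij[iu[sel], ju[sel]] * (sr6 * sr6 - sr6)
        if mode == MODE_FULL:
            e = e + COULOMB_CONSTANT * q_ij[iu[sel], ju[sel]] / (dielectric * rs)
        np.add.at(acc, (res_i[sel], res_j[sel]), e)
    acc /= ensemble.n_frames
    acc = acc + acc.T

    excluded = _sequential_neighbour_mask(ensemble)
    acc[excluded] = np.nan
    return EnergyMatrix(
        residue_ids=list(ensemble.residue_ids),
        values=acc,
        mode=mode,
        n_frames=ensemble.n_frames,
    )
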