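"""Energy model: analytic anchors, combining rules, ensemble averaging, oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pen.energy import (
    COULOMB_CONSTANT,
    AtomRecord,
    EnergyDomainError,
    StructureEnsemble,
    build_energy_matrix,
    combine_lj,
    coulomb_energy,
    lj_energy,
    residue_pair_energy,
)
from pen.synthetic import make_toy_structure


@pytest.mark.parametrize(
    ("q_i", "q_j", "r", "dielectric", "expected"),
    [
        (0.0, 1.0, 0.5, 1.0, 0.0),
        (1.0, 1.0, 1.0, 1.0, 138.935485),
        (1.0, -1.0, 0.5, 1.0, -277.87097),
        (1.0, 1.0, 1.0, 2.0, 138.935485 / 2),
    ],
)
def test_coulomb_hand_values(q_i, q_j, r, dielectric, expected):
    assert coulomb_energy(q_i, q_j, r, dielectric) == pytest.approx(expected, abs=1e-5)


@given(
    q=st.floats(-2, 2, allow_nan=False),
    r=st.floats(0.05, 5, allow_nan=False),
)
@settings(derandomize=True, max_examples=50)
def test_coulomb_halving_r_doubles(q, r):
    full = coulomb_energy(q, 1.0, r)
    half = coulomb_energy(q, 1.0, r / 2)
    assert half == pytest.approx(2 * full, rel=1e-12, abs=1e-12)


@pytest.mark.parametrize("bad_r", [0.0, -1.0, float("nan"), float("inf")])
def test_coulomb_domain_errors(bad_r):
    with pytest.raises(EnergyDomainError):
        coulomb_energy(1.0, 1.0, bad_r)


def test_lj_analytic_anchors():
    # zero crossing at r = sigma, minimum of exactly -epsilon at 2^(1/6) sigma
    assert lj_energy(0.3, 0.5, 0.3) == pytest.approx(0.0, abs=1e-12)
    assert lj_energy(0.3, 0.5, 0.3 * 2 ** (1 / 6)) == pytest.approx(-0.5, rel=1e-12)
    assert lj_energy(0.3, 0.0, 0.2) == 0.0


def test_lj_domain_errors():
    with pytest.raises(EnergyDomainError):
        lj_energy(0.3, 0.5, 0.0)
    with pytest.raises(EnergyDomainError):
        lj_energy(-0.3, 0.5, 0.1)


def test_combining_rules():
    sig, eps = combine_lj(0.2, 0.4, 0.4, 0.9, "lorentz_berthelot")
    assert sig == pytest.approx(0.3)
    assert eps == pytest.approx(0.6)
    sig_g, eps_g = combine_lj(0.2, 0.4, 0.4, 0.9, "geometric")
    assert sig_g == pytest.approx(math.sqrt(0.08))
    assert eps_g == pytest.approx(0.6)
    with pytest.raises(ValueError):
        combine_lj(0.2, 0.4, 0.4, 0.9, "bogus")


def _atom(name, res, xyz_angstrom, q, sigma, eps):
    return AtomRecord(name, res, np.asarray(xyz_angstrom, dtype=float), q, sigma, eps)


class TestResiduePairEnergy:
    def test_reduces_to_single_atom_pair(self):
        a = _atom("A1", 1, [0, 0, 0], 0.5, 0.3, 0.4)
        b = _atom("B1", 3, [4.0, 0, 0], -0.2, 0.35, 0.6)
        r = 0.4  # nm
        sig, eps = combine_lj(0.3, 0.4, 0.35, 0.6)
        expected = lj_energy(sig, eps, r) + coulomb_energy(0.5, -0.2, r)
        assert residue_pair_energy([a], [b]) == pytest.approx(expected, rel=1e-12)

    def test_zero_parameters_give_zero(self):
        a = _atom("A1", 1, [0, 0, 0], 0.0, 0.3, 0.0)
        b = _atom("B1", 3, [5.0, 0, 0], 0.0, 0.3, 0.0)
        assert residue_pair_energy([a], [b]) == 0.0

    def test_two_vs_one_atom_brute_force(self):
        a1 = _atom("A1", 1, [0, 0, 0], 0.3, 0.3, 0.5)
        a2 = _atom("A2", 1, [1.0, 1.0, 0], -0.1, 0.25, 0.2)
        b1 = _atom("B1", 3, [4.0, 0, 0], 0.2, 0.35, 0.4)
        expected = 0.0
        for a in (a1, a2):
            r = float(np.linalg.norm(a.coordinates - b1.coordinates)) / 10.0
            sig, eps = combine_lj(a.lj_sigma, a.lj_epsilon, b1.lj_sigma, b1.lj_epsilon)
            expected += lj_energy(sig, eps, r) + coulomb_energy(
                a.partial_charge, b1.partial_charge, r
            )
        assert residue_pair_energy([a1, a2], [b1]) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_in_arguments(self):
        a = [_atom("A1", 1, [0, 0, 0], 0.3, 0.3, 0.5)]
        b = [_atom("B1", 3, [3.0, 2.0, 1.0], -0.4, 0.28, 0.7)]
        assert residue_pair_energy(a, b) == pytest.approx(residue_pair_energy(b, a))

    def test_overlapping_atoms_error_names_pair(self):
        a = [_atom("CA", 1, [0, 0, 0], 0.3, 0.3, 0.5)]
        b = [_atom("CB", 3, [0, 0, 0], -0.4, 0.28, 0.7)]
        with pytest.raises(EnergyDomainError, match="CA"):
            residue_pair_energy(a, b)

    def test_lj_only_drops_electrostatics(self):
        a = [_atom("A1", 1, [0, 0, 0], 0.5, 0.3, 0.4)]
        b = [_atom("B1", 3, [4.0, 0, 0], -0.2, 0.35, 0.6)]
        sig, eps = combine_lj(0.3, 0.4, 0.35, 0.6)
        assert residue_pair_energy(a, b, mode="lj_only") == pytest.approx(
            lj_energy(sig, eps, 0.4), rel=1e-12
        )


def _random_ensemble(rng, n_res=4, max_atoms=5, n_frames=2, n_chains=2):
    """Random parameterized ensemble, residues spaced widely to avoid overlaps."""
    chain_ids, seq_positions, residue_ids = [], [], []
    atom_residue, atom_names = [], []
    charges, sigmas, epsilons = [], [], []
    for r in range(n_res):
        chain = chr(ord("A") + r % n_chains)
        chain_ids.append(chain)
        seq_positions.append(r // n_chains + 1)
        residue_ids.append(f"{chain}:X{r + 1}")
        for a in range(int(rng.integers(1, max_atoms + 1))):
            atom_residue.append(r)
            atom_names.append(f"A{r}_{a}")
            charges.append(float(rng.uniform(-0.5, 0.5)))
            sigmas.append(float(rng.uniform(0.25, 0.4)))
            epsilons.append(float(rng.uniform(0.1, 1.0)))
    n_atoms = len(atom_names)
    frames = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        base = rng.uniform(0, 3, size=(n_res, 3)) + np.arange(n_res)[:, None] * 6.0
        frames[f] = base[np.array(atom_residue)] + rng.uniform(-0.8, 0.8, size=(n_atoms, 3))
    return StructureEnsemble(
        residue_ids=residue_ids,
        chain_ids=chain_ids,
        seq_positions=seq_positions,
        atom_residue=np.array(atom_residue),
        atom_names=atom_names,
        charges=np.array(charges),
        sigmas=np.array(sigmas),
        epsilons=np.array(epsilons),
        frames=frames,
    )


def _naive_matrix(ens, mode="full", dielectric=1.0):
    """Brute-force double loop over frames, residue pairs and atom pairs."""
    n = ens.n_residues
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            if ens.chain_ids[i] == ens.chain_ids[j] and abs(
                ens.seq_positions[i] - ens.seq_positions[j]
            ) <= 1:
                continue
            total = 0.0
            for f in range(ens.n_frames):
                ai = [k for k in range(ens.n_atoms) if ens.atom_residue[k] == i]
                aj = [k for k in range(ens.n_atoms) if ens.atom_residue[k] == j]
                for a in ai:
                    for b in aj:
                        r = np.linalg.norm(ens.frames[f, a] - ens.frames[f, b]) / 10.0
                        sr6 = ((0.5 * (ens.sigmas[a] + ens.sigmas[b])) / r) ** 6
                        e = 4 * math.sqrt(ens.epsilons[a] * ens.epsilons[b]) * (sr6**2 - sr6)
                        if mode == "full":
                            e += COULOMB_CONSTANT * ens.charges[a] * ens.charges[b] / (dielectric * r)
                        total += e
            out[i, j] = out[j, i] = total / ens.n_frames
    return out


class TestBuildEnergyMatrix:
    def test_matches_naive_double_loop(self, rng):
        for _ in range(5):
            ens = _random_ensemble(rng, n_res=5, n_frames=2)
            got = build_energy_matrix(ens)
            want = _naive_matrix(ens)
            assert np.allclose(np.nan_to_num(got.values), np.nan_to_num(want), atol=1e-9)
            assert np.array_equal(np.isnan(got.values), np.isnan(want))

    def test_symmetry_exact(self, rng):
        ens = _random_ensemble(rng, n_res=6)
        m = build_energy_matrix(ens)
        assert np.array_equal(
            np.nan_to_num(m.values), np.nan_to_num(m.values.T)
        )

    def test_identical_frames_equal_single_frame(self, rng):
        ens1 = _random_ensemble(rng, n_frames=1)
        ens3 = StructureEnsemble(
            residue_ids=ens1.residue_ids,
            chain_ids=ens1.chain_ids,
            seq_positions=ens1.seq_positions,
            atom_residue=ens1.atom_residue,
            atom_names=ens1.atom_names,
            charges=ens1.charges,
            sigmas=ens1.sigmas,
            epsilons=ens1.epsilons,
            frames=np.repeat(ens1.frames, 3, axis=0),
        )
        m1 = build_energy_matrix(ens1)
        m3 = build_energy_matrix(ens3)
        assert np.allclose(np.nan_to_num(m1.values), np.nan_to_num(m3.values), atol=1e-12)

    def test_two_frames_average_arithmetically(self, rng):
        ens = _random_ensemble(rng, n_frames=2)
        both = build_energy_matrix(ens).values
        only_a = build_energy_matrix(
            StructureEnsemble(
                residue_ids=ens.residue_ids, chain_ids=ens.chain_ids,
                seq_positions=ens.seq_positions, atom_residue=ens.atom_residue,
                atom_names=ens.atom_names, charges=ens.charges, sigmas=ens.sigmas,
                epsilons=ens.epsilons, frames=ens.frames[:1],
            )
        ).values
        only_b = build_energy_matrix(
            StructureEnsemble(
                residue_ids=ens.residue_ids, chain_ids=ens.chain_ids,
                seq_positions=ens.seq_positions, atom_residue=ens.atom_residue,
                atom_names=ens.atom_names, charges=ens.charges, sigmas=ens.sigmas,
                epsilons=ens.epsilons, frames=ens.frames[1:],
            )
        ).values
        assert np.allclose(
            np.nan_to_num(both), np.nan_to_num((only_a + only_b) / 2), atol=1e-12
        )

    def test_sequential_neighbours_excluded_in_chain(self):
        m = build_energy_matrix(make_toy_structure("mini_chain", n_residues=4))
        present = {(i, j) for i, j, _ in m.pairs()}
        assert present == {(0, 2), (0, 3), (1, 3)}

    def test_interchain_pairs_never_excluded(self):
        # two chains with seq positions 1 and 1: |delta| = 0 but different chains
        m = build_energy_matrix(make_toy_structure("two_particles"))
        assert not np.isnan(m.values[0, 1])

    def test_lj_only_equals_full_with_zero_charges(self, rng):
        ens = _random_ensemble(rng)
        zeroed = StructureEnsemble(
            residue_ids=ens.residue_ids, chain_ids=ens.chain_ids,
            seq_positions=ens.seq_positions, atom_residue=ens.atom_residue,
            atom_names=ens.atom_names, charges=np.zeros_like(ens.charges),
            sigmas=ens.sigmas, epsilons=ens.epsilons, frames=ens.frames,
        )
        lj = build_energy_matrix(ens, mode="lj_only").values
        full0 = build_energy_matrix(zeroed, mode="full").values
        assert np.allclose(np.nan_to_num(lj), np.nan_to_num(full0), atol=1e-12)

    def test_distance_cutoff_drops_far_pairs(self):
        ens = make_toy_structure("mini_chain", n_residues=4, spacing_nm=0.4)
        m = build_energy_matrix(ens, distance_cutoff=0.9)
        # pair (0,3) is 1.2 nm apart -> all its atom terms beyond the cutoff
        assert m.values[0, 3] == 0.0
        assert m.values[0, 2] != 0.0
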