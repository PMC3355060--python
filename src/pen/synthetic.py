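"""Synthetic fixtures: toy structures with analytic energies and planted families.

Two generators back the test surface of the whole pipeline without any
external data:

* :func:`make_toy_structure` builds desk-scale parameterized structures
  (``two_particles``, ``mini_chain``) whose pairwise energies follow from the
  Coulomb and Lennard-Jones formulas by hand.

* :func:`make_family` builds a family of energy matrices plus a matching MSSA
  with a *planted* conserved edge set (present in every member), optional
  clade-specific edge pools, per-member private noise edges and gap columns —
  together with a machine-readable truth table.  Identical spec + seed
  regenerate byte-identical files.

Energy regimes mimic the conventions of real interaction networks: planted
conserved edges draw from a strongly favourable band (default −30..−15
kJ/mol, the electrostatics-dominated regime), noise edges from a weaker band
(−14..−8, the vdW-dominated regime) and non-edges from −5..0.  The bands are
disjoint so a single threshold separates the classes exactly.  No attempt is
made to imitate realistic protein geometry or a real force field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .energy import EnergyMatrix, StructureEnsemble
from .family import MSSA
from .io import write_energy_tsv

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

TOY_KINDS = ("two_particles", "mini_chain")


def make_toy_structure(
    kind: str,
    r_nm: float = 0.5,
    charges: tuple[float, float] = (0.0, 0.0),
    sigma_nm: float = 0.3,
    epsilon_kjmol: float = 0.5,
    n_residues: int = 4,
    spacing_nm: float = 0.4,
    n_frames: int = 1,
) -> StructureEnsemble:
    """Build a toy parameterized structure with hand-computable energies.

    ``two_particles``: two single-atom residues on separate chains (so the
    sequential-neighbour exclusion never applies) at separation ``r_nm``.
    ``mini_chain``: >= 4 single-atom residues equally spaced on a line in one
    chain, exercising the |i−j| <= 1 exclusion.  All frames are identical
    copies, so ensemble averaging is a no-op by construction.
    """
    if kind == "two_particles":
        if r_nm <= 0:
            raise ValueError("two particles must not coincide (r_nm > 0)")
        coords = np.array([[0.0, 0.0, 0.0], [r_nm * 10.0, 0.0, 0.0]])
        ens = StructureEnsemble(
            residue_ids=["A:T01 1", "B:T02 1"],
            chain_ids=["A", "B"],
            seq_positions=[1, 1],
            atom_residue=np.array([0, 1]),
            atom_names=["X1", "X2"],
            charges=np.array(charges, dtype=float),
            sigmas=np.full(2, sigma_nm),
            epsilons=np.full(2, epsilon_kjmol),
            frames=np.repeat(coords[None, :, :], n_frames, axis=0),
        )
        return ens
    if kind == "mini_chain":
        if n_residues < 4:
            raise ValueError("mini_chain needs at least 4 residues")
        if spacing_nm <= 0:
            raise ValueError("coincident atoms: spacing_nm must be positive")
        xs = np.arange(n_residues) * spacing_nm * 10.0
        coords = np.column_stack([xs, np.zeros(n_residues), np.zeros(n_residues)])
        q = np.array([(-1.0) ** k * 0.1 for k in range(n_residues)])
        return StructureEnsemble(
            residue_ids=[f"A:T{k + 1:02d} {k + 1}" for k in range(n_residues)],
            chain_ids=["A"] * n_residues,
            seq_positions=list(range(1, n_residues + 1)),
            atom_residue=np.arange(n_residues),
            atom_names=[f"X{k + 1}" for k in range(n_residues)],
            charges=q,
            sigmas=np.full(n_residues, sigma_nm),
            epsilons=np.full(n_residues, epsilon_kjmol),
            frames=np.repeat(coords[None, :, :], n_frames, axis=0),
        )
    raise ValueError(f"unknown toy kind {kind!r}; expected one of {TOY_KINDS}")


def write_toy_pdb(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write a toy ensemble as a minimal multi-MODEL PDB file."""
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 1
        for a in range(ensemble.n_atoms):
            res = ensemble.atom_residue[a]
            res_label = ensemble.residue_ids[res]
            # residue ids are "<chain>:<resname> <resseq>"
            resname = res_label.split(":")[1].split()[0]
            x, y, z = ensemble.frames[f, a]
            # strict PDB fixed columns: name 13-16, resname 18-20, chain 22,
            # resseq 23-26, coords 31-54, element 77-78
            lines.append(
                f"ATOM  {serial:5d} {ensemble.atom_names[a]:<4s} {resname:>3s} "
                f"{ensemble.chain_ids[res]:1s}{ensemble.seq_positions[res]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}{'C':>12s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_toy_params(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Parameter TSV matching :func:`write_toy_pdb` output."""
    rows = ["res_name\tatom_name\tcharge_e\tsigma_nm\tepsilon_kjmol"]
    for a in range(ensemble.n_atoms):
        res = ensemble.atom_residue[a]
        resname = ensemble.residue_ids[res].split(":")[1].split()[0]
        rows.append(
            f"{resname}\t{ensemble.atom_names[a]}\t{ensemble.charges[a]:.6g}"
            f"\t{ensemble.sigmas[a]:.6g}\t{ensemble.epsilons[a]:.6g}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


@dataclass
class SyntheticFamilySpec:
    """Recipe for a planted-conservation family of energy matrices.

    ``planted_edges`` may be an explicit list of column pairs or an integer
    count to sample.  ``private_edge_rate`` is the expected number of noise
    edges per member (sampled disjointly across members so per-edge truth is
    exact); ``gap_rate`` gaps non-protected columns per member.  With
    ``n_clades`` > 1 the members are split evenly and each clade receives its
    own pool of ``clade_edge_count`` shared edges, giving high within-clade
    and low between-clade edge overlap.
    """

    M: int = 5
    L: int = 60
    planted_edges: "int | list[tuple[int, int]]" = 8
    private_edge_rate: float = 0.0
    gap_rate: float = 0.0
    conserved_range: tuple[float, float] = (-30.0, -15.0)
    noise_range: tuple[float, float] = (-14.0, -8.0)
    background_range: tuple[float, float] = (-5.0, 0.0)
    n_clades: int = 1
    clade_edge_count: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2 or self.L < 4:
            raise ValueError("need M >= 2 members and L >= 4 columns")
        ranges = [self.conserved_range, self.noise_range, self.background_range]
        for lo, hi in ranges:
            if lo >= hi:
                raise ValueError("energy ranges must be (low, high) with low < high")
        # class bands must not overlap, so one threshold separates them exactly
        if not (self.conserved_range[1] <= self.noise_range[0] <= self.noise_range[1] <= self.background_range[0]):
            raise ValueError("energy ranges must be disjoint and ordered conserved < noise < background")
        n_pairs = self.L * (self.L - 1) // 2
        n_planted = (
            self.planted_edges if isinstance(self.planted_edges, int) else len(self.planted_edges)
        )
        if n_planted > n_pairs:
            raise ValueError("more planted edges than column pairs available")


@dataclass
class FamilyTruth:
    """Ground truth accompanying a generated family."""

    member_ids: list[str]
    planted_edges: list  # column pairs present in every member
    clade_of: dict  # member -> clade index
    clade_edges: dict  # clade index -> list of column pairs
    private_edges: dict  # member -> list of column pairs
    gap_columns: dict  # member -> sorted gap column list
    matrices: dict  # member -> EnergyMatrix (residue space)
    mssa: MSSA


def _sample_pairs(rng, L, count, forbidden, protected_only=None):
    """Sample ``count`` distinct column pairs outside ``forbidden``."""
    pairs = []
    attempts = 0
    while len(pairs) < count:
        attempts += 1
        if attempts > 200 * max(count, 1) + 1000:
            raise ValueError("infeasible spec: cannot place requested edges")
        a, b = sorted(rng.integers(0, L, size=2).tolist())
        if a == b:
            continue
        p = (a, b)
        if p in forbidden or p in pairs:
            continue
        if protected_only is not None and (a not in protected_only or b not in protected_only):
            continue
        pairs.append(p)
    return pairs


def make_family(
    spec: SyntheticFamilySpec, out_dir: str | Path | None = None
) -> FamilyTruth:
    """Generate a synthetic family per ``spec``; optionally write it to disk.

    On disk: one energy TSV per member, ``family.afa`` (aligned FASTA),
    ``manifest.tsv`` and ``truth.json``.  Planted (and clade) edge columns are
    never gapped in any member, so planted edges survive remapping verbatim.
    """
    rng = np.random.default_rng(spec.seed)
    member_ids = [f"m{k + 1:02d}" for k in range(spec.M)]
    L = spec.L

    if isinstance(spec.planted_edges, int):
        planted = _sample_pairs(rng, L, spec.planted_edges, set())
    else:
        planted = [tuple(sorted(p)) for p in spec.planted_edges]
        if len(set(planted)) != len(planted):
            raise ValueError("duplicate planted edges")
        for a, b in planted:
            if not (0 <= a < b < L):
                raise ValueError(f"planted edge ({a},{b}) outside columns")

    clade_of = {m: k % spec.n_clades for k, m in enumerate(member_ids)}
    used = set(planted)
    clade_edges: dict[int, list] = {}
    if spec.n_clades > 1:
        for c in range(spec.n_clades):
            clade_edges[c] = _sample_pairs(rng, L, spec.clade_edge_count, used)
            used.update(clade_edges[c])
    protected_cols = {c for p in used for c in p}

    gap_columns: dict[str, list[int]] = {}
    for m in member_ids:
        gaps = [
            c
            for c in range(L)
            if c not in protected_cols and rng.random() < spec.gap_rate
        ]
        # keep at least one mapped column even under extreme gap rates
        if len(gaps) >= L:
            gaps = gaps[:-1]
        gap_columns[m] = gaps

    private_edges: dict[str, list] = {}
    taken = set(used)
    for m in member_ids:
        n_priv = int(rng.poisson(spec.private_edge_rate)) if spec.private_edge_rate > 0 else 0
        ok_cols = set(range(L)) - set(gap_columns[m])
        private_edges[m] = _sample_pairs(rng, L, n_priv, taken, protected_only=ok_cols)
        taken.update(private_edges[m])

    sequences: dict[str, str] = {}
    matrices: dict[str, EnergyMatrix] = {}
    for m in member_ids:
        gaps = set(gap_columns[m])
        seq = [
            "-" if c in gaps else AMINO_ACIDS[rng.integers(0, 20)] for c in range(L)
        ]
        sequences[m] = "".join(seq)
        cols = [c for c in range(L) if c not in gaps]  # residue order = column order
        col_to_res = {c: k for k, c in enumerate(cols)}
        n = len(cols)
        values = np.full((n, n), np.nan)
        lo, hi = spec.background_range
        iu, ju = np.triu_indices(n, k=1)
        values[iu, ju] = rng.uniform(lo, hi, size=iu.size)
        member_edges = list(planted) + clade_edges.get(clade_of[m], []) + private_edges[m]
        for a, b in member_edges:
            if a in gaps or b in gaps:
                continue  # cannot happen for planted/clade edges by construction
            lo_e, hi_e = (
                spec.noise_range if (a, b) in private_edges[m] and (a, b) not in used
                else spec.conserved_range
            )
            i, j = col_to_res[a], col_to_res[b]
            values[min(i, j), max(i, j)] = rng.uniform(lo_e, hi_e)
        full = np.full((n, n), np.nan)
        full[iu, ju] = values[iu, ju]
        full[ju, iu] = values[iu, ju]
        ids = [f"{m}:R{k + 1}" for k in range(n)]
        matrices[m] = EnergyMatrix(residue_ids=ids, values=full, mode="full", n_frames=1)

    mssa = MSSA(member_ids=list(member_ids), sequences=sequences)
    truth = FamilyTruth(
        member_ids=member_ids,
        planted_edges=sorted(planted),
        clade_of=clade_of,
        clade_edges={c: sorted(v) for c, v in clade_edges.items()},
        private_edges={m: sorted(v) for m, v in private_edges.items()},
        gap_columns={m: sorted(v) for m, v in gap_columns.items()},
        matrices=matrices,
        mssa=mssa,
    )
    if out_dir is not None:
        _write_family(truth, spec, Path(out_dir))
    return truth


def _write_family(truth: FamilyTruth, spec: SyntheticFamilySpec, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = []
    manifest = ["member_id\tpath"]
    for m in truth.member_ids:
        fasta.append(f">{m}\n{truth.mssa.sequences[m]}")
        mat_path = out_dir / f"{m}_energies.tsv"
        write_energy_tsv(truth.matrices[m], mat_path)
        manifest.append(f"{m}\t{mat_path.name}")
    (out_dir / "family.afa").write_text("\n".join(fasta) + "\n")
    (out_dir / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    payload = {
        "spec": {
            k: (list(map(list, v)) if isinstance(v, list) else v)
            for k, v in asdict(spec).items()
        },
        "planted_edges": [list(p) for p in truth.planted_edges],
        "clade_of": truth.clade_of,
        "clade_edges": {str(c): [list(p) for p in v] for c, v in truth.clade_edges.items()},
        "private_edges": {m: [list(p) for p in v] for m, v in truth.private_edges.items()},
        "gap_columns": truth.gap_columns,
    }
    (out_dir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
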