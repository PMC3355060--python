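"""Readers and writers for the formats the pipeline exchanges.

PDB structures (multi-MODEL files are conformer ensembles) are parsed with
Bio.PDB; force-field parameters, energy matrices, secondary-structure labels
and family manifests travel as TSV.  Energy TSVs carry commented header lines
(`# residues:`, `# mode:`, `# n_frames:`) so the residue roster and ordering
survive a round trip even for residues with no surviving entry.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .energy import (
    EnergyMatrix,
    ParameterizationError,
    StructureEnsemble,
)
from .network import LCProfile, SSEAnnotation, ThresholdedNetwork

PARAM_COLUMNS = ["res_name", "atom_name", "charge_e", "sigma_nm", "epsilon_kjmol"]


def read_params_tsv(path: str | Path) -> dict:
    """Force-field table keyed by (res_name, atom_name)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table {path} lacks columns {missing}")
    table = {}
    for row in df.itertuples(index=False):
        table[(str(row.res_name), str(row.atom_name))] = (
            float(row.charge_e),
            float(row.sigma_nm),
            float(row.epsilon_kjmol),
        )
    return table


def _is_hydrogen(atom) -> bool:
    elem = (atom.element or "").strip().upper()
    if elem:
        return elem == "H"
    return atom.get_name().lstrip("0123456789").startswith("H")


def read_pdb_ensemble(
    pdb_path: str | Path, params: dict | str | Path
) -> StructureEnsemble:
    """Parse a (possibly multi-MODEL) PDB file into a parameterized ensemble.

    Each MODEL becomes one frame; the atom roster is taken from the first
    model and must be consistent across models.  For altloc'd atoms the first
    altloc is kept.  Atoms without a parameter-table entry abort with a
    :class:`ParameterizationError`, except hydrogens, which are skipped with
    a warning so heavy-atom-only inputs still work.
    """
    from Bio.PDB import PDBParser

    if not isinstance(params, dict):
        params = read_params_tsv(params)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {pdb_path}")

    residue_ids: list[str] = []
    chain_ids: list[str] = []
    seq_positions: list[int] = []
    atom_keys: list[tuple] = []  # (chain, resseq, atom_name) for cross-model lookup
    atom_residue: list[int] = []
    atom_names: list[str] = []
    charges: list[float] = []
    sigmas: list[float] = []
    epsilons: list[float] = []

    first = models[0]
    for chain in first:
        for residue in chain:
            het, resseq, icode = residue.id
            if het.strip():
                continue  # skip waters/heteroatoms; parameters target polymer residues
            res_label = f"{chain.id}:{residue.get_resname()} {resseq}"
            res_idx = len(residue_ids)
            residue_ids.append(res_label)
            chain_ids.append(chain.id)
            seq_positions.append(int(resseq))
            seen = set()
            for atom in residue:
                name = atom.get_name()
                if name in seen:
                    continue  # first altloc wins
                seen.add(name)
                key = (residue.get_resname(), name)
                if key not in params:
                    if _is_hydrogen(atom):
                        warnings.warn(
                            f"hydrogen {name} of {res_label} lacks parameters; skipped",
                            stacklevel=2,
                        )
                        continue
                    raise ParameterizationError(
                        f"no force-field parameters for atom {name!r} of residue "
                        f"{residue.get_resname()!r} ({res_label})"
                    )
                q, sig, eps = params[key]
                atom_keys.append((chain.id, resseq, name))
                atom_residue.append(res_idx)
                atom_names.append(name)
                charges.append(q)
                sigmas.append(sig)
                epsilons.append(eps)

    if not atom_keys:
        raise ValueError(f"no parameterized atoms found in {pdb_path}")

    frames = np.empty((len(models), len(atom_keys), 3), dtype=float)
    for f, model in enumerate(models):
        lookup = {}
        for chain in model:
            for residue in chain:
                het, resseq, _ = residue.id
                if het.strip():
                    continue
                for atom in residue:
                    k = (chain.id, resseq, atom.get_name())
                    if k not in lookup:
                        lookup[k] = atom.get_coord()
        for a, key in enumerate(atom_keys):
            if key not in lookup:
                raise ValueError(
                    f"model {f} of {pdb_path} is missing atom {key}; frames must "
                    "share one atom roster"
                )
            frames[f, a] = lookup[key]

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


def write_energy_tsv(matrix: EnergyMatrix, path: str | Path) -> None:
    """Long-format energy TSV: res_i, res_j, energy_kjmol, mode (+ roster header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# residues:\t{','.join(matrix.residue_ids)}\n")
        fh.write(f"# mode:\t{matrix.mode}\n")
        fh.write(f"# n_frames:\t{matrix.n_frames}\n")
        fh.write("res_i\tres_j\tenergy_kjmol\tmode\n")
        ids = matrix.residue_ids
        for i, j, v in matrix.pairs():
            fh.write(f"{ids[i]}\t{ids[j]}\t{v:.10g}\t{matrix.mode}\n")


def read_energy_tsv(path: str | Path) -> EnergyMatrix:
    """Read a long-format energy TSV back into an EnergyMatrix."""
    path = Path(path)
    roster: list[str] | None = None
    mode = None
    n_frames = 1
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("\t")
            key = key.rstrip(":")
            if key == "residues":
                roster = val.split(",")
            elif key == "mode":
                mode = val
            elif key == "n_frames":
                n_frames = int(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"res_i", "res_j", "energy_kjmol"}
    if not required <= set(df.columns):
        raise ValueError(f"energy TSV {path} lacks columns {sorted(required - set(df.columns))}")
    if roster is None:
        seen: list[str] = []
        for col in ("res_i", "res_j"):
            for r in df[col].astype(str):
                if r not in seen:
                    seen.append(r)
        roster = seen
    if mode is None:
        modes = set(df["mode"].astype(str)) if "mode" in df.columns else set()
        mode = modes.pop() if len(modes) == 1 else "full"
    index = {r: k for k, r in enumerate(roster)}
    n = len(roster)
    values = np.full((n, n), np.nan)
    for row in df.itertuples(index=False):
        i, j = index[str(row.res_i)], index[str(row.res_j)]
        values[i, j] = values[j, i] = float(row.energy_kjmol)
    return EnergyMatrix(residue_ids=roster, values=values, mode=mode, n_frames=n_frames)


def write_energy_dense(matrix: EnergyMatrix, path: str | Path) -> None:
    """Dense matrix TSV with residue ids as header row/column; absent entries blank."""
    df = pd.DataFrame(matrix.values, index=matrix.residue_ids, columns=matrix.residue_ids)
    df.to_csv(path, sep="\t", na_rep="", float_format="%.10g", index_label="residue")


def read_sse_tsv(path: str | Path) -> SSEAnnotation:
    """Secondary-structure TSV: res_id, label (H/E/C), strand_index (blank unless E)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"res_id": str})
    for col in ("res_id", "label"):
        if col not in df.columns:
            raise ValueError(f"SSE table {path} lacks column {col!r}")
    labels = {}
    strand_index = {}
    for row in df.itertuples(index=False):
        labels[str(row.res_id)] = str(row.label)
        si = getattr(row, "strand_index", None)
        if si is not None and not pd.isna(si):
            strand_index[str(row.res_id)] = int(si)
    return SSEAnnotation(labels=labels, strand_index=strand_index)


def read_manifest(path: str | Path) -> dict:
    """Family manifest TSV (member_id, path); relative paths resolve beside the manifest."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"member_id", "path"} <= set(df.columns):
        raise ValueError(f"manifest {path} needs columns member_id and path")
    out = {}
    for row in df.itertuples(index=False):
        p = Path(str(row.path))
        if not p.is_absolute():
            p = path.parent / p
        out[str(row.member_id)] = p
    return out


def write_edge_list(
    net: ThresholdedNetwork,
    matrix: EnergyMatrix,
    path: str | Path,
    classes: dict | None = None,
) -> None:
    """Edge TSV (res_i, res_j, energy_kjmol[, interface_class])."""
    class_of = {}
    if classes:
        for cls, edges in classes.items():
            for e in edges:
                class_of[tuple(sorted(e))] = cls
    with Path(path).open("w") as fh:
        cols = "res_i\tres_j\tenergy_kjmol"
        if classes:
            cols += "\tinterface_class"
        fh.write(cols + "\n")
        for u, v in sorted(net.edges):
            line = f"{u}\t{v}\t{matrix.get(u, v):.10g}"
            if classes:
                line += f"\t{class_of.get(tuple(sorted((u, v))), '')}"
            fh.write(line + "\n")


def write_graphml(net: ThresholdedNetwork, path: str | Path) -> None:
    g = net.to_networkx()
    g.graph["cutoff_e"] = net.cutoff_e
    g.graph["mode"] = net.mode
    nx.write_graphml(g, str(path))


def write_lc_profile(profile: LCProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"e_kjmol": profile.e_grid, "normalized_lc": profile.normalized_lc}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_distance_phylip(member_ids, d: np.ndarray, path: str | Path) -> None:
    """PHYLIP square distance-matrix format."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(member_ids)}\n")
        for i, m in enumerate(member_ids):
            row = " ".join(f"{x:.6f}" for x in d[i])
            fh.write(f"{m:<10s} {row}\n")
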