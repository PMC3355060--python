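# Methods

## Energy model

The interaction energy between two residues is the sum over their
inter-residue atom pairs of a Coulomb term f·q_i·q_j/(ε_r·r) and a 12-6
Lennard-Jones term 4ε[(σ/r)¹² − (σ/r)⁶], with f = 138.935485
kJ·mol⁻¹·nm·e⁻², charges in elementary-charge units and distances in nm
(coordinates are read in Å and converted). Energies are averaged over the
frames of a conformational ensemble with equal weights; a single structure
is the one-frame special case. The model is deliberately force-field
agnostic: per-atom parameters (charge, σ, ε) come from a user-supplied TSV
table, because absolute energies depend on the parameter set and the method
only relies on relative and thresholded behaviour.

Choices, each configurable:

* **Combining rule** for cross σ/ε: Lorentz–Berthelot (arithmetic σ,
  geometric ε) by default; all-geometric available.
* **Dielectric** ε_r = 1 by default (raw vacuum molecular-mechanics
  potential).
* **Distance cutoff**: none by default — all atom pairs are summed; an
  optional nm cutoff zeroes far terms for speed.
* **Exclusions**: self-pairs and sequential neighbours, read as |i−j| ≤ 1
  within one chain; inter-chain pairs are never excluded. The through-bond
  coupling of adjacent residues would otherwise dominate the non-covalent
  signal.
* **Hydrogens** are included when present and parameterized; unparameterized
  hydrogens are skipped with a warning so heavy-atom inputs work, while a
  missing heavy-atom parameter is an error (silent omission would bias
  energies).
* **Altlocs**: the first altloc per atom is kept. Missing atoms are not
  rebuilt; inputs are expected to be complete at the level the user cares
  about.

## Thresholded networks

PEN_e keeps edges with E_ij ≤ e; "at or below" is the inclusive reading of a
maximum-energy cutoff, so edge sets are nested as e relaxes toward 0 and the
largest-cluster (LC) profile is monotone. The LC profile reports the largest
connected component over the *full* graph (no minimum size) normalized by
residue count; its 0.5-crossing, linearly interpolated between grid points,
is reported descriptively (on real TIM-barrel data this transition sits near
−15 kJ/mol for full PENs and −7 kJ/mol for LJ-only networks). Clusters, by
contrast, are components of size ≥ 3 — isolated interacting pairs are not
clusters — ordered by descending size, ties broken by smallest member.
Hub thresholds: single-network hubs take a caller-chosen minimum degree
(CLI default 4); family hubs are fixed at degree ≥ 3 in a fraction of
members (default 0.7).

Interface classification of edges uses per-residue H/E/C labels with strand
ordinals (consumed from a DSSP-like TSV, never computed here). Precedence:
any endpoint labelled C → loop; mixed H/E → α/β; both H → α/α; both E →
β/β, split into contiguous (strand ordinals differing by ≤ 1, or the
first/last strand pair when the barrel-wraparound flag is set, since closed
β-barrels make those adjacent) versus long-range. Only non-neighbouring
strands count as long-range so that backbone hydrogen-bonded contacts
between adjacent strands do not masquerade as tertiary conservation.

## Family alignment and commonality

The MSSA (aligned FASTA) defines equivalent residues. A member's network is
remapped into column space by its column→residue mapping; its gap columns
become virtual nodes. The +100 kJ/mol virtual-pair sentinel is stored for
fidelity when energies are carried along, but zero degree is enforced
structurally — no threshold comparison against the sentinel is ever relied
on. All alignment columns are kept regardless of gap fraction.

cc_ij = X_ij / M, where X counts members possessing edge (i,j) and M is the
family size. A member gapped at i or j cannot possess the edge and
contributes 0 to X while M stays fixed — the denominator is the family, not
the subset of members defined at that column. Thresholding is inclusive
(cc_ij ≥ cc), so cc = 1.0 selects edges present in every member.

## Conservation index

Raw column conservation is Σ_a p_a ln p_a over the frequencies of non-gap
symbols — 0 for a fully conserved column, −ln 20 at maximal diversity. Gaps
are excluded from the counts; all-gap columns are undefined and excluded
from normalization. EC is the z-score of the raw values across defined
columns using the population (ddof = 0) standard deviation (sample SD
selectable); if every column has identical raw conservation the spread is
zero and all EC values are set to 0 with a warning. Sequences are counted
unweighted — families are assumed pre-culled of redundant members (< 30 %
identity), so redundancy weighting would add complexity without signal.

## Interaction-conservation phylogeny

For members a, b remapped onto shared columns, S_ij = 1 when edge (i,j) is
present in both networks at the common cutoff (an optional energy mode
additionally requires |E^a_ij − E^b_ij| ≤ tol). SS is the conserved fraction
of edges; since "fraction of edges" admits several denominators, the default
is the union of the two edge sets (making SS the Jaccard index: symmetric,
in [0,1], equal to 1 iff the edge sets coincide), with min and mean
selectable. Two empty edge sets are scored SS = 1 (identical emptiness) with
a warning. D = 1 − SS by default (−ln SS available, capped at SS = 0).
Pairwise comparisons reuse the family MSSA projected to each pair rather
than recomputing pairwise structural alignments; this keeps all pair scores
on one coordinate system at the cost of inheriting the family alignment's
gap placement.

Trees come from agglomerative clustering (average/UPGMA default; single and
complete available) on D. Node heights are half the merge distance — the
ultrametric convention, so two leaves at distance d join at height d/2 —
and members are pre-sorted lexicographically, which makes tie-breaking and
hence the Newick string deterministic under input permutation.

## Synthetic data

The family generator emulates the inputs of the real pipeline — per-member
energy matrices plus an MSSA — with planted structure: a conserved edge set
present in every member, optional per-clade edge pools, per-member private
noise edges, and per-member gap columns. Energy bands are disjoint by
construction (conserved U(−30, −15) kJ/mol, mirroring the
electrostatics-dominated regime of real interaction networks; noise
U(−14, −8), the vdW-dominated regime; background U(−5, 0)), so a single
threshold separates the classes exactly and truth tables are exact rather
than statistical. Two further exactness guarantees: planted and clade-pool
edges never touch a gapped column of any member, and private noise edges are
sampled disjointly across members so a noise edge's commonality is exactly
1/M. Generated matrices may contain sequential-neighbour pairs (they stand
for matrices whose exclusion happened upstream at energy-computation time).
Default sizes used in the test suite — M = 5 members, L = 60 columns, 8
planted edges, and for clade experiments M = 8 in two clades of 4 with
30-edge clade pools — give within-clade edge overlap around 0.9 and
between-clade overlap below 0.1.

What the generator does *not* emulate: realistic protein geometry, real
force-field parameters, correlated gap blocks, alignment errors, or
energy variation of a conserved edge across members. Passing recovery tests
therefore shows the remapping/commonality/phylogeny machinery is correct,
not that any particular cutoff is optimal for real structures. The toy
structure generator (`two_particles`, `mini_chain`) covers the opposite end:
energies hand-computable from the closed forms, including the
sequential-neighbour exclusion pattern.

## Numerical notes and limitations

* Energy matrices store absent entries as NaN; symmetry is validated on
  construction.
* Threshold comparisons are plain `<=` on floats; cutoffs are user units
  (kJ/mol) and no tolerance is applied.
* Overlapping atoms (r = 0) raise an error naming the atom pair rather than
  returning an infinity.
* The LC midpoint uses first-crossing linear interpolation; plateaus return
  the right edge of the crossing segment.
* Problem sizes in the test suite (networks ≤ 50 nodes, families ≤ 8 × 60
  columns, 100 clade replicates) are chosen to keep the whole suite in a few
  seconds while still exercising every code path; the algorithms themselves
  are O(atoms²) per frame for energies and near-linear in edges elsewhere,
  and handle real domain sizes (hundreds of residues) comfortably.
* No MD, minimization, structural superposition, DSSP, bonded terms or
  solvent models: structures, alignments and secondary-structure labels are
  consumed, not produced.
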