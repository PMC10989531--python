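# Methods

## Model

For each of the eight scalar coupling types (¹J_NH, ¹J_CH, ²J_HH, ²J_NH,
²J_CH, ³J_HH, ³J_CH, ³J_NH) an independent LightGBM regression model maps a
fixed, named descriptor vector of one (hydrogen, partner) atom pair to the
coupling constant in Hz. The approach assumes that the local geometry of
the pair — above all interatomic distances, and the positions of
electronegative O/N atoms near the coupling path — carries most of the
signal, and that tree ensembles can exploit monotone transforms of these
distances without explicit angle or dihedral features.

Boosting hyperparameters (defaults of `BoostingParams`): num_leaves 128,
min_child_samples 79, bagging_seed 11, learning_rate 0.2, reg_lambda 0.3,
boosting_type gbdt, subsample_freq 1, subsample 0.9, objective regression,
metric mae, verbosity −1, reg_alpha 0.1, max_depth 13, colsample_bytree 1.0.
The boosting round count is fixed at 1000 with no early stopping so runs
are deterministic; it is configurable (`n_rounds`). Training defaults to a
single thread with LightGBM's `deterministic` flag, trading speed for
bit-wise reproducibility; multi-threaded training is possible but may not
reproduce bit-for-bit.

## Descriptor composition

The per-type vector lengths are 296 (CH types), 295 (NH), 289 (HH) and 211
(traditional baseline). The exact composition is frozen as name lists in
`jcoupling.descriptors` so feature matrices are stable across releases:

**Molecular block (210).** `mol_num_atoms` and `mol_num_bonds`; the first
172 entries of RDKit's molecule-level descriptor battery excluding the
eight `BCUT2D_*` descriptors (they raise on molecules that fail charge
perception); and 18 per-atom properties for each target atom (degree,
H-neighbor count, ring flag, aromatic flag, hybridization one-hot over
SP/SP2/SP3/other, element one-hot over H/C/N/O/F, formal charge, ring-size
flags 3–6). The RDKit molecule is built from the element list plus the
covalently perceived bond graph; bond orders are then inferred from the
geometry (`rdDetermineBonds`), falling back to single bonds with partial
sanitization (ring + hybridization perception only) for open-shell
fragments. A battery descriptor that raises or returns a non-finite value
is recorded as 0.0. All battery descriptors are 2D (coordinate-free), which
is what makes the whole block exactly invariant under rigid motions.

**Pair distance (1).** The Euclidean distance between the target atoms, Å.

**Same-type statistics (49).** Let D be the multiset of pair distances of
all couplings of the record's type in the molecule and d the record's own
distance. For each of three groupings — all of D, the subset sharing the
record's hydrogen, the subset sharing its partner — the block holds count,
mean, min, max, population std, sum, range, d−mean, d−min, d−max, d−std,
d÷mean, d÷min, d÷max and the 1-based rank of d (15 × 3 = 45), plus the two
cross-group mean differences and two group-size fractions (4). Distances
are strictly positive, so quotient denominators are never zero; the std is
never used as a denominator. A singleton group is legal and yields
mean = min = max = d, std = 0, rank = 1.

**Midpoint distances (12).** From the arithmetic midpoint of the pair to
the six nearest O atoms and the six nearest N atoms, ascending. Slots
beyond the available atom count hold the sentinel 1000 (Å) — far outside
any physical intramolecular distance, so trees separate "absent" cleanly.

**Target-atom distances (24).** The same 6+6 scheme per target atom, the
atom itself excluded from its own candidate list (all other atoms,
including the other target, are candidates). For the three NH types the
nitrogen target's first N-distance slot (`atom1_N_1`) is removed as
near-degenerate, giving 295.

**HH replacement (17).** For ²J_HH/³J_HH both targets are hydrogens with
mirror-image environments, so the 24 target-atom slots are replaced by the
elementwise average of the two hydrogens' 12 heteroatom distances, the
averaged distance to each hydrogen's nearest C-or-N atom, and the averaged
per-hydrogen same-type distance mean/min/max/std — 289 in total.

**Traditional mode (211).** Molecular block plus the pair distance only;
this emulates descriptor sets built for chemical-shift prediction and
serves as the comparison baseline.

## Pipeline

Molecules are split 70/30 at the molecule level
(|train| = ⌊0.7·n⌋, seeded, shared by every coupling type in one fit) so
no structure leaks between partitions. Near-constant toolkit descriptors
are removed per type with a most-frequent-value filter: a molecular-block
column is dropped iff its modal value accounts for ≥ 95 % of the *training*
rows; the keep mask is stored in the model bundle and re-applied at
prediction time. Evaluation reports r² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE, and
RRMSE = RMSE divided by the population (÷ n) standard deviation of the true
values; with the population convention r² = 1 − RRMSE² holds as an exact
identity (the implementation derives r² from RRMSE so the identity is exact
in floating point as well; r² still agrees with the textbook formula to
≈ 1 ulp). Variable importance is LightGBM split gain, ties broken by name.

## Bond perception and pair taxonomy

Bonds are perceived with single-bond covalent radii (H 0.31, C 0.76,
N 0.71, O 0.66, F 0.57 Å) and a 0.40 Å tolerance: i–j bonded iff
dist ≤ r_i + r_j + tol. The coupling order n is the shortest bond-path
length (breadth-first search); pairs with n ∈ {1,2,3} and partner in
{H, C, N} are classifiable (a 1-bond H–H pair, i.e. molecular hydrogen, is
outside the eight-type taxonomy), O/F partners and longer paths are not.
When supplied records disagree with the perceived classification, the
supplied type wins and a warning is logged — the pipeline trusts dataset
labels. Enumeration lists each unordered pair once (for HH pairs the lower
index first), ordered by atom indices.

## Synthetic data

The simulator emulates the two input tables with five hard-coded
small-molecule templates — ethane, propane, ethanol, ethylamine,
fluoroethane — stored as internal coordinates and assigned round-robin.
Each conformer jitters bond lengths by N(0, 0.02 Å) and bond angles by
N(0, 3°), and rotates every rotatable-bond dihedral by a uniform angle on
[0°, 360°); these magnitudes keep the perceived topology identical to the
template's while varying all distances the descriptors see. Constants
follow closed-form laws of the actual geometry: 1J = 125 − 50·(r − 1.09) Hz
(CH-like magnitude), 2J = −12 + 5·cos φ Hz at the intervening atom's angle
φ, 3J from a Karplus curve with (A, B, C) = (7, −1, 5) Hz over the path
dihedral (shortest path, ties broken toward the lowest intermediate
indices), each plus N(0, σ²) noise with σ = 0.1 Hz by default. All
magnitudes are in the range of typical printed couplings; tests compare
against the simulator's own ground truth, so their exact values are not
load-bearing.

What the generator does *not* emulate: rings and aromatic systems beyond
test fixtures, conformational ensembles, through-space effects, the sign
conventions and substituent dependence of real couplings, and the sheer
structural diversity of a real 85k-molecule dataset. Passing the recovery
tests therefore demonstrates that the pipeline can learn smooth geometric
laws from its descriptors — not that it attains any particular accuracy on
experimental or DFT-derived constants.

## Problem sizes and numerical choices

The recovery checks run the full pipeline on 2000-molecule fixtures
(roughly 18 000 ³J_HH and 14 000 ¹J_CH records) and a 600-molecule fixture
for the noise-monotonicity sweep — sizes at which held-out r² estimates are
stable to a few thousandths while a full run stays in the minutes range on
one CPU. Degenerate inputs are handled explicitly: an empty coupling table
yields an empty report; a type with zero records is skipped with a warning;
training sets smaller than `min_child_samples` warn that the model may
collapse to a constant; zero-variance targets make r²/RRMSE undefined and
raise. Coordinates are Å everywhere; coupling constants and RMSE are Hz;
file round-trips preserve coordinates and constants to 1 × 10⁻⁶.

## Open design points

Where the descriptor scheme was genuinely open the package freezes one
documented convention: k = 6 nearest neighbors per heteroatom element
(12 midpoint and 24 target-atom slots), the 49-statistic composition above,
and the 172-name battery subset. Whether the near-constant filter should
act per type or globally is equally open; it acts per type here, matching
the per-type model structure. The split seed (default 42) and round count
are exposed so users can probe sensitivity to both.
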