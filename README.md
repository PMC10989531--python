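# jcoupling

Prediction of NMR indirect spin–spin coupling constants (scalar *J*
couplings, in Hz) directly from 3D molecular structures, using atom-pair
geometric descriptors and one gradient-boosted regression model per
coupling type.

## The problem

A scalar coupling constant ⁿJ_XH quantifies the through-bond interaction
between a hydrogen nucleus and a partner nucleus X ∈ {H, C, N} separated by
n ∈ {1, 2, 3} bonds. These constants carry rich stereochemical information
(the vicinal ³J_HH coupling follows the Karplus relation
J(θ) = A·cos²θ + B·cosθ + C in the dihedral angle θ), but computing them
quantum-chemically is expensive. This package learns the regression
y = f(X) from data: X is a fixed, named descriptor vector for one
(H, partner) atom pair, y is the coupling constant in Hz, and f is a
LightGBM gradient-boosted tree ensemble fitted separately for each of the
eight coupling types (¹J_NH, ¹J_CH, ²J_HH, ²J_NH, ²J_CH, ³J_HH, ³J_CH,
³J_NH).

The descriptor vector combines five blocks (296 values for CH types):

| block | count |
|---|---|
| toolkit molecular descriptors (RDKit battery subset + per-target-atom properties) | 210 |
| Euclidean distance between the target atoms | 1 |
| statistics of same-type coupling distances in the molecule | 49 |
| distances from the pair midpoint to the 6 nearest O and 6 nearest N atoms | 12 |
| distances from each target atom to its 6 nearest O and 6 nearest N atoms | 24 |

When a molecule has no O (or N), those distance slots hold the sentinel
value 1000. HH types replace the last block with 17 averages over the two
hydrogens (289 total); NH types drop the nitrogen target's nearest-N slot
(295 total). A "traditional" baseline mode uses only the molecular block
plus the pair distance (211), mirroring descriptor sets built for chemical
shift prediction. See `docs/methods.md` for every composition detail.

Data are read in the CHAMPS/Kaggle scalar-coupling CSV dialect (a per-atom
`structures.csv` and a coupling table) or plain XYZ files; covalent bonds
are perceived from coordinates with covalent-radius cutoffs; models are
evaluated with r², RMSE and RRMSE (RMSE divided by the standard deviation
of the true values) on a molecule-level 70/30 split, so no molecule
contributes pairs to both partitions.

## Worked example

The built-in simulator generates jittered conformers of five small-molecule
templates and assigns coupling constants from closed-form geometric laws
(1J linear in bond length, 2J in the cosine of the intervening angle,
3J from a Karplus curve) plus Gaussian noise — so the learning task has a
known ground truth:

```python
from jcoupling import (ScalarCouplingModel, SimulatorParams,
                       generate_structures, simulate_couplings)

structures = generate_structures(300, seed=1)
couplings = simulate_couplings(structures, SimulatorParams(seed=1, noise_sd=0.1))
model = ScalarCouplingModel(structures, couplings, mode="proposed",
                            coupling_types=["1JCH", "3JHH"])
results = model.fit(train_fraction=0.7, seed=42)
print(results.summary())
```

prints

```
Scalar coupling regression (LightGBM, molecule-level split)
mode: proposed   train molecules: 210   test molecules: 90

type    n_test       r2   RMSE/Hz   RRMSE
1JCH       522    0.980     0.141   0.142
3JHH       808    0.917     0.733   0.288

top descriptors by split gain:
  1JCH #1: pair_distance (2819.7)
  1JCH #2: st_mol_d_minus_std (30.5)
  1JCH #3: st_partner_min (18.0)
  3JHH #1: st_mol_d_over_mean (7415.3)
  3JHH #2: st_mol_d_minus_mean (7247.7)
  3JHH #3: st_mol_d_minus_std (7141.4)
```

The one-bond coupling is essentially a function of the C–H distance, and
the booster finds `pair_distance` to be by far its most important input;
the vicinal ³J_HH signal is carried by the same-type distance statistics,
which are monotone transforms of the H···H distance and hence of the
dihedral angle. Held-out r² of 0.92 at noise σ = 0.1 Hz means the model has
recovered most of the Karplus law from distances alone.

The same workflow is available from the shell:

```bash
jcoupling simulate --n 300 --seed 1 --out data/
jcoupling train-eval --structures data/structures.csv \
    --couplings data/couplings.csv --out runs/ --types 1JCH,3JHH
jcoupling predict --models runs/models.pkl \
    --structures data/structures.csv --out predictions.csv
```

`train-eval` writes `metrics.csv` (type, mode, r², RMSE, RRMSE, n_test) and
`importance.csv` (type, rank, descriptor, importance).

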