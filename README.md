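# dynalysis

Comparative analysis of molecular-dynamics trajectories: given two
simulated systems — say a drug-sensitive protein–inhibitor complex and a
resistant double mutant — quantify *how* the dynamics differ. The package
covers the standard post-MD toolchain used in resistance-mechanism and
allostery studies:

- **Conformational metrics** — Kabsch superposition (iterative mean
  reference), RMSD, per-residue RMSF and RMSF differences, distance
  collective variables, coordinate PCA, and 2-D free-energy landscapes by
  Boltzmann inversion.
- **Markov state models** — k-means microstates, reversible
  (symmetrized-count) transition matrices, implied timescales
  t = −τ/ln|λ|, spectral macrostate lumping, block-bootstrap
  Chapman–Kolmogorov validation, and medoid representative structures.
- **Correlated motions and networks** — the dynamic cross-correlation
  matrix (DCCM), a mutual-information generalized correlation
  GC = sqrt(1 − exp(−2·MI/3)) with a Kraskov k-NN MI estimator, residue
  interaction networks with −ln|C| edge weights and a 4.5 Å / 75%-occupancy
  contact rule, Girvan–Newman communities at maximum modularity, and
  optimal (Dijkstra) signalling paths with physical path lengths.
- **Interactions** — geometric hydrogen bonds (3.5 Å / 135°), water
  bridges with per-water persistence, Shrake–Rupley SASA, solvent-shell
  water counts, and pairwise Coulomb + Lennard-Jones residue–ligand
  interaction energies.
- **Synthetic generators** — Gaussian ensembles with planted correlations,
  metastable Markov chains, and rigid complex fixtures with planted
  hydrogen bonds/bridges/shell waters, all with exact ground truth; the
  entire package is validated against these closed forms.

File I/O (PDB topologies, DCD/XTC trajectories, MDAnalysis selection
grammar) is wrapped in `dynalysis.io`; everything downstream works on plain
numpy containers. See `docs/methods.md` for precise definitions and
conventions.

## Worked example

Correlated motions on a synthetic ensemble with a planted correlation of
r = 0.8 between atoms 1 and 4 (for jointly Gaussian motion, DCCM = r and
GC = |r| exactly, so both estimators can be checked by eye):

```python
import numpy as np
from dynalysis.io import Selection
from dynalysis.metrics import rmsf
from dynalysis.network import dccm, generalized_correlation
from dynalysis.synthetic import GaussianEnsembleSpec, gen_gaussian_ensemble

spec = GaussianEnsembleSpec(n_atoms=5, n_frames=20_000, sigma=0.5,
                            correlations=[(0, 3, 0.8)], seed=42)
ens = gen_gaussian_ensemble(spec)
sel = Selection(tuple(range(5)))

C = dccm(ens, sel)
G = generalized_correlation(ens, sel)
print(f"DCCM[ALA1, ALA4]  = {C.values[0, 3]:+.3f}")
print(f"DCCM[ALA1, ALA3]  = {C.values[0, 2]:+.3f}")
print(f"GC[ALA1, ALA4]    = {G.values[0, 3]:.3f}")
print(f"GC[ALA1, ALA3]    = {G.values[0, 2]:.3f}")
print(rmsf(ens, sel).round(3).to_string(index=False))
```

Output:

```
DCCM[ALA1, ALA4]  = +0.800
DCCM[ALA1, ALA3]  = +0.004
GC[ALA1, ALA4]    = 0.795
GC[ALA1, ALA3]    = 0.053
 resid resname  rmsf
     1     ALA 0.868
     2     ALA 0.865
     3     ALA 0.867
     4     ALA 0.869
     5     ALA 0.864
```

The RMSF of isotropic noise with per-component σ = 0.5 Å is
σ√3 ≈ 0.866 Å, recovered above to within sampling error.

An MSM on a planted 3-state chain (true implied timescales 8.16 and 4.90
frames from the eigenvalues of the planted transition matrix):

```python
from dynalysis.msm import (ck_test, coarse_grain, estimate_transitions,
                           implied_timescales)
from dynalysis.synthetic import MarkovEnsembleSpec, gen_markov_ensemble

T = np.array([[0.90, 0.07, 0.03],
              [0.07, 0.88, 0.05],
              [0.03, 0.05, 0.92]])
centers = np.array([[0.0, 0.0], [3.0, 0.0], [1.5, 2.6]])
spec = MarkovEnsembleSpec(T, centers, noise_sigma=0.15,
                          n_steps=100_000, seed=7)
ens, labels = gen_markov_ensemble(spec)

print(implied_timescales(labels, lags=[1, 2, 5, 10],
                         n_timescales=2).round(2).to_string(index=False))
model = estimate_transitions(labels, 1)
part = coarse_grain(model, 2)
table = ck_test(labels, part, 1, factors=(2, 3, 4, 5),
                n_bootstrap=50, seed=0)
print(f"CK points within CI: {100 * table['within_ci'].mean():.0f}%")
```

Output:

```
 lag_frames  lag_time  connected  t_2  t_3
          1       1.0       True 8.23 4.89
          2       2.0       True 8.21 4.88
          5       5.0       True 8.18 4.86
         10      10.0       True 8.29 4.90
CK points within CI: 100%
```

Timescales are flat across lags and match the planted values within 1–2%,
and the Chapman–Kolmogorov test confirms Markovianity.

## Command line

```bash
dynalysis compare --config run.yaml      # full two-system pipeline
dynalysis rmsd   --topology t.pdb --trajectory t.dcd --selection "name CA"
dynalysis rmsf   --topology t.pdb --trajectory t.dcd --out rmsf.csv
dynalysis dccm   --topology t.pdb --trajectory t.dcd --out dccm.csv
dynalysis sasa   --topology t.pdb --trajectory t.dcd --selection "resname LIG"
dynalysis synth  --spec fixture.yaml --out fixtures/ --seed 1
```

A `compare` configuration names two systems (topology + trajectories, or a
synthetic spec), a fit selection, and per-stage parameters; the pipeline
runs superposition, RMSD/RMSF/ΔRMSF, CVs, PCA, landscapes, the MSM, DCCM,
the network with communities and an optimal path, and interaction analyses,
writing CSV/GraphML/PDB outputs plus a `manifest.json`. A failing stage is
logged without aborting the rest, and all randomness derives from the
configured seed.

## Reproduction

All headline behaviors are checked end-to-end by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which runs the main computations on synthetic ground-truth data (the DCCM
brute-force oracle, the Gaussian GC limit, MSM timescale recovery and CK
coverage, the planted community partition, the optimal-path oracle,
rigid-fit RMSD and isotropic RMSF, the SASA and Coulomb/Lennard-Jones
closed forms, planted interaction-fixture occupancies, landscape curvature
recovery, and a null/planted two-system comparison) and writes each value
with the size of the data behind it. The run takes about half a minute;
`python -m pytest -q tests/` covers the same ground plus unit and property
tests in about two minutes.
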