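# vdyn

Analysis toolkit for comparing the conformational dynamics of protein
variants from molecular-dynamics ensembles, built around the CYP3A5
missense-variant problem: single amino-acid substitutions that leave the
fold intact but reshape the enzyme's plasticity, catalytic-pocket geometry,
and drug binding.

Given an ensemble of snapshots (and per-frame energy decompositions from an
MM-GBSA pipeline), `vdyn` computes:

- **Structural deviation** — least-squares (Kabsch) superposition, per-frame
  RMSD against a crystal reference, per-residue RMSF and variant-vs-wild-type
  RMSF differences, with flexible-loop exclusion (e.g. residues 260–270 and
  280–288 of CYP3A5) in sequence numbering.
- **Essential dynamics** — Cartesian PCA of the Cα covariance
  (`CartesianPCA`, a scikit-learn-style estimator), explained-variance
  accounting, subspace overlap between two ensembles
  RMSIP = √( (1/n) Σᵢ Σⱼ (μᵢ·νⱼ)² ) over the first *n* = 20 eigenvectors,
  porcupine mode vectors, and cross-projection of variant conformations onto
  the wild-type eigenbasis.
- **Correlation networks** — the dynamic cross-correlation matrix
  DCC(i,j) = ⟨Δrᵢ·Δrⱼ⟩ / √(⟨Δrᵢ²⟩⟨Δrⱼ²⟩) and the |DCC| ≥ 0.5 residue link
  network.
- **Free-energy landscapes** — ΔG = −k_B T ln P(PC1, PC2) by Boltzmann
  inversion of the projection histogram, global-minimum bookkeeping, and
  representative-conformation extraction.
- **Binding energetics** — the interaction-entropy estimator
  −TΔS = k_B T ln⟨e^{βΔE_int}⟩ (log-sum-exp stabilized), assembly of
  ΔG_binding = ⟨E_int⟩ − TΔS + ΔG_solv from per-frame series, docking-pose
  selection metrics (fraction of native contacts, ligand-COM–Fe distance,
  ligand RMSD), pocket shrinkage percentages, and the quadratic
  pocket-volume↔affinity regression y = a·x² + b·x + c with its R².
- **Synthetic data** — seeded generators (Gaussian ensembles with planted
  low-rank covariance, two-state hopping, Gaussian energy series, noisy
  quadratic datasets) that plant known ground truth for every stage, so the
  whole pipeline is verifiable without a simulation engine.

## Worked example

```python
import numpy as np
from vdyn import (make_toy_chain, random_orthonormal_modes, sample_gaussian_trajectory,
                  select_atoms, fit_pca, make_energy_series, binding_energy,
                  quadratic_fit, binding_energy_table, pocket_volumes, shrinkage)

# recover a planted essential-dynamics spectrum (9, 4, 1 A^2)
chain = make_toy_chain(100)
modes = random_orthonormal_modes(300, 3, seed=1)
traj = sample_gaussian_trajectory(chain, modes, np.array([9.0, 4.0, 1.0]), 5000, seed=2)
pca = fit_pca(traj, select_atoms(chain, "ca"))
print("leading eigenvalues (A^2):", np.round(pca.eigenvalues_[:3], 2))

# interaction-entropy binding free energy from a per-frame energy series
series = make_energy_series(mean=-58.5, sigma=1.0, n=100_000, seed=3)
series.g_solv = np.full(series.n_frames, 38.7)
result = binding_energy(series)
print(f"<E_int> = {result.e_int_mean:.2f}, -TdS = {result.minus_tds:.3f}, "
      f"dG_binding = {result.g_binding:.2f} kcal/mol")

# pocket-volume vs affinity regression over the published per-variant values
table = binding_energy_table()
rit = table[table.drug == "ritonavir"].set_index("variant")
fit = quadratic_fit(pocket_volumes().loc[rit.index], rit.g_binding)
print(f"ritonavir fit: a={fit.a:.3e}, b={fit.b:.3f}, c={fit.c:.0f}, R^2={fit.r_squared:.2f}")
print(f"V238A pocket shrinkage: {shrinkage(1438.22, 1970.70):.1f}%")
```

prints

```
leading eigenvalues (A^2): [9.14 3.96 1.  ]
<E_int> = -58.50, -TdS = 0.836, dG_binding = -18.96 kcal/mol
ritonavir fit: a=1.331e-04, b=-0.468, c=399, R^2=0.95
V238A pocket shrinkage: 27.0%
```

The PCA recovers the planted eigenvalues within sampling error; the −TΔS of
a Gaussian energy series with σ = 1 kcal/mol at 300 K converges to
σ²/(2k_BT) = 0.839 kcal/mol; the seven-variant ritonavir regression gives
R² ≈ 0.95 with a convex (a > 0) volume–affinity relationship; and the V238A
catalytic pocket is 27% smaller than wild type.

A `vdyn` command-line tool mirrors the library
(`vdyn simulate|select|rmsd|rmsf|rmsf-diff|pca|rmsip|porcupine|dccm|dccm-links|fel|ie-energy|volfit|pose-metrics`),
reading PDB/DCD/XTC inputs and writing tidy CSV/JSON.

## Scope

Trajectory generation (MD engines), docking, PB/GB solvation solvers,
pocket-volume/tunnel computation, and force-field energy evaluation are out
of scope: their numeric outputs (per-frame energy decompositions, pocket
volumes) are consumed as inputs.
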