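# Methods

This note records the models implemented in `vdyn`, their assumptions, the
defaults that matter, and the design choices made where more than one
convention exists.

## Coordinate conventions and selections

Coordinates are Angstrom throughout; energies kcal/mol; temperatures K;
times ns (with a 10 ps default snapshot interval). Residue numbering is the
PDB sequence numbering and is never rewritten; selections carry the actual
sequence positions of their atoms, plus an optional `offset` field relating
a 0-based array index to a sequence position (CYP3A5 constructs use an
offset of 25). Exclusion ranges — by default the flexible loops 260–270 and
280–288 that are unresolved in the substrate-free crystal structure — are
inclusive on both ends and always expressed in sequence numbering. An
expression that selects no atoms raises rather than silently returning an
empty set. Alternate locations keep the highest-occupancy conformer (first
in file order on ties). Hydrogens are retained when present but excluded
from `heavy` selections, matching the heavy-atom convention of the pose
metrics. No mass weighting is used anywhere: the observables are defined on
plain Cα/backbone coordinates.

## Superposition, RMSD, RMSF

`superpose` computes the closed-form least-squares rotation (Kabsch with
reflection correction, via `scipy.spatial.transform.Rotation.align_vectors`)
over a fit selection and applies the transform to all atoms. The rotation is
always proper (det = +1); fewer than three fit atoms or a collinear set is a
degenerate-fit error. Superposition is idempotent to well below 1e−8 A.

RMSD_t = √((1/N) Σᵢ |rᵢ(t) − rᵢ^ref|²) after per-frame fitting (fitting can
be disabled). RMSD carries an explicit unit field (`angstrom` or `nm`) —
both appear in practice, and an implicit unit is a classic source of
factor-10 confusion. RMSF_i = √(⟨|rᵢ(t) − ⟨rᵢ⟩|²⟩) over the equilibrated
frames, computed about the ensemble mean by default (with one internal
fitting pass against the mean); a `reference`-based variant is available
because both conventions exist in the literature and the choice is rarely
stated. Deviation series use the full trajectory, while fluctuation and
mode analyses use the equilibrated frames; equilibration is a fixed
`discard_before` time chosen by inspection (no automatic detection), with
200 ns the working default for production runs of the CYP3A5 systems.

## Essential dynamics

`CartesianPCA` diagonalizes the covariance of the centered 3N coordinate
matrix through an SVD of the frame matrix (numerically stabler than forming
the 3N×3N covariance; identical spectrum). Eigenvalues are sample variances
(ddof = 1) in A²; explained-variance fractions are eigenvalue shares of the
total. Each eigenvector is sign-flipped so its largest-magnitude component
is positive, making outputs deterministic across linear-algebra backends.
The ensemble must be superposed to a common reference first, since PCA on
unfitted coordinates mixes internal motion with rigid-body drift.

RMSIP between two decompositions is √((1/n) Σᵢ Σⱼ (μᵢ·νⱼ)²) over the first
n = 20 eigenvectors: the double-sum square-rooted form is the only one that
is symmetric, bounded by [0, 1], and reaches 1 for identical subspaces; an
un-rooted variant is provided for comparison with sources that print the
formula without the root. For random k-dimensional subspaces in dimension D
the expected RMSIP is √(k/D) (≈ 0.129 for k = 20, D = 1200), the reference
null for judging observed overlaps.

Porcupine vectors for mode k are `scale · v_k` reshaped per atom, anchored
at the mean structure, exported in NMD-style text. Cross-projection scores a
conformation against a *reference* decomposition's mean and eigenvectors
(e.g. variant global-minimum structures on the wild-type PC1/PC2 plane); the
caller is responsible for superposing the frame to the reference fitting
frame first.

## Correlation networks

DCC(i,j) = ⟨Δrᵢ·Δrⱼ⟩ / √(⟨Δrᵢ²⟩⟨Δrⱼ²⟩) over equilibrated frames, the
standard normalization that guarantees values in [−1, 1] with unit
diagonal. Atoms with (numerically) zero fluctuation would make the
normalization undefined; their off-diagonal correlations are set to 0 with
a warning, and the diagonal stays 1 by convention. Link extraction keeps
pairs with |DCC| ≥ threshold (0.5 default; the comparison is declared
inclusive rather than left ambiguous), labels them with sequence positions,
and flags sequential neighbors (|i−j| ≤ 2 in chain order) whose correlation
is trivial. All retained frames are used by default, with an optional
stride.

## Free-energy landscapes

ΔG(bin) = −k_B T ln P(bin) over a 2D histogram of the (PC1, PC2) scores,
with k_B = 1.987204259×10⁻³ kcal mol⁻¹ K⁻¹ and T = 300 K by default. The
histogram covers the data range padded by 1% (a fixed 0.5 A pad on a
degenerate axis), 50×50 bins by default — fine enough to resolve landscape
topology while keeping bins populated at typical frame counts. Empty bins
are masked, not set to +∞, and export as missing values. Energies are
shifted so the global minimum is 0; `shift=False` keeps the absolute
−k_B T ln P values, since both conventions appear in published landscapes.
The global minimum is the occupied bin of minimal ΔG, ties broken by higher
count then lowest (row, col) index; the representative conformation is the
frame inside that bin closest to the bin center (earliest frame on ties).

Two checks tie the construction to closed forms: two bins with an 0.8/0.2
occupancy split differ by k_B T ln 4 = 0.8265 kcal/mol at 300 K exactly, and
for a Gaussian reaction coordinate of variance λ the fitted curvature of
ΔG(PC1) equals k_B T/λ. For the two-state generator the well-minimum ΔΔG
estimate carries a binning error bounded by k_B T ln 2 (the worst case is a
well peak split half/half across a bin edge); summing occupancy over each
well's bins instead is binomial-accurate.

## Binding energetics

The interaction-entropy estimator is −TΔS = k_B T ln⟨e^{βΔE}⟩ with
ΔE = E_int − ⟨E_int⟩, evaluated via log-sum-exp so only the spread of the
series limits the numerics; it depends only on fluctuations (invariant to
constant offsets), is non-negative by Jensen's inequality, and is exactly
zero for a constant series (short-circuited to avoid a ~1e−15 floating
residue from the mean subtraction). For a Gaussian series of standard
deviation σ the estimator converges to σ²/(2k_B T) — 0.8387 kcal/mol for
σ = 1 kcal/mol at 300 K. The binding free energy is assembled as
ΔG_binding = ⟨E_int⟩ + (−TΔS) + ⟨ΔG_solv⟩ from per-frame series read from
delimited text (MMPBSA-style column aliases are recognized); replicas are
pooled with equal weight after any upstream per-replica equilibration
filter, and a series without a solvation column yields a gas-phase-only
result flagged incomplete. Solvation and force-field energies themselves
are inputs, not computed here.

The published per-variant table of binding terms and the mdpocket pocket
volumes ship in `vdyn.reference_data` as inputs to the term-combination,
shrinkage, and regression stages. The volume–affinity model is the
quadratic y = a·x² + b·x + c fitted by ordinary least squares on the design
(x², x, 1); the source that motivated it prints the model as a product of
root terms "(x−a)(x−b)(x−c)", but only the quadratic reading with those
printed values as the coefficients a, b, c reproduces the reported energies
and R² (the literal product form yields values of order 10⁹), so the
quadratic interpretation is implemented and noted here. Shrinkage is
100·(v_ref − v_variant)/v_ref, signed, so a pocket larger than the
reference reports negative shrinkage.

Pose metrics follow the CAPRI-style convention: native contacts are
reference-pose ligand-heavy/receptor-heavy atom pairs within 4.5 A, fnat is
the fraction preserved by the candidate, the COM distance is from the
ligand heavy-atom centroid to the heme iron, and the ligand RMSD is
computed without refitting after receptor superposition (refitting would
hide exactly the displacement being measured). A reference pose with no
contacts leaves fnat undefined rather than zero.

## Synthetic generators

Each generator is a pure function of its arguments with a private seeded
`numpy.random.Generator` — mirroring the fixed-engine-seed discipline of
production MD protocols — and its planted truth can be serialized to a
sidecar JSON. The toy chain is an idealized helix-like Cα trace (rise
1.5 A, radius 2.3 A, 100°/residue), giving selections and superpositions a
non-degenerate, non-collinear geometry. Gaussian ensembles have population
covariance exactly Σ λ_k v_k v_kᵀ over orthonormal planted modes
(orthonormality enforced to 1e−8); two-state ensembles hop independently
between reference and displaced wells with isotropic jitter σ = 0.1 A so
histogram bins are realistically occupied (zero-width states collapse the
histogram); energy series are i.i.d. Gaussian; quadratic datasets sample x
uniformly over a stated range with Gaussian noise.

What passing tests on these fixtures show — and what they do not: the
generators reproduce the *statistical* structure the analyses assume
(harmonic fluctuations with a low-rank covariance, bimodal occupancy,
converged energy fluctuations), so recovery tests validate the estimators'
correctness and calibration. They carry no kinetics, no frame-to-frame
correlation, no anharmonicity, and no solvent; nothing here validates
whether a particular real trajectory is converged or equilibrated.

## Verification problem sizes

The standing verification suite uses desk-scale problems chosen so each
statistical check is decisive: 5,000 frames × 100 residues for the planted
3-mode spectrum (sampling error well inside the 10% recovery band), 20,000
frames for the DCCM independence null (per-pair standard error ≈ 0.004,
max |DCC| over 870 pairs ≪ the 0.05 bound) and for two-state landscape
recovery, 10⁶ samples for the interaction-entropy closed form (±5%), and
100 draws for the random-subspace RMSIP baseline. The published
table/volume computations are exact arithmetic; the only tolerance there is
the 0.02 kcal/mol rounding slack of the printed terms.

## Known limitations

- Multi-model PDB is the only text trajectory format; binary formats go
  through mdtraj and inherit its precision (DCD stores float32).
- The RMSF internal fit iterates the mean once rather than to convergence;
  for well-superposed inputs the difference is far below sampling error.
- The landscape is histogram-based; no kernel density estimate, no
  minimum-energy paths.
- `fnat` uses a single distance cutoff with no bond-topology awareness.
- Equilibration is a user-supplied cutoff; no automated convergence
  diagnostics are provided.
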