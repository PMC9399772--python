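# Methods

This note defines every quantity the package computes and states the
conventions and estimators used, so results can be interpreted without
reading the source.

## Input model

A system is a *topology* (atom names, elements, residue ids, chains; read
from PDB via MDAnalysis) plus an *ensemble* of frames (Å coordinates with
strictly increasing frame times in ns; DCD/XTC read and concatenated in the
order given). Atom selections use the MDAnalysis selection grammar; dash
ranges (`resid 3-6`) are accepted and normalized. All distance cutoffs in
the package are closed (≤, with a 1e-9 Å numerical guard), so an atom
exactly at a cutoff counts.

## Superposition, RMSD, RMSF

Rigid-body fits use the Kabsch SVD solution (proper rotations only). The
default reference is an iteratively refined mean structure: every frame is
fitted to the current mean of the fit selection, the mean is recomputed,
and the cycle repeats to convergence. This makes superposition idempotent.
The transform is computed on the selection and applied to all atoms.

RMSD of a selection to a reference frame is
`sqrt(mean_i |r_i − r_i^ref|²)`; no fitting is performed inside
`rmsd_series` itself. Per-atom RMSF is `sqrt(<|r_i − <r_i>|²>)` about the
ensemble mean; isotropic noise of per-component σ gives RMSF = σ√3. System
comparisons report `delta = rmsf_a − rmsf_b` per residue.

## PCA and free-energy landscapes

PCA diagonalizes the 3k×3k covariance of the superposed selection
(population normalization, 1/n). Eigenvalues are clipped at zero and sorted
descending; projections are centered, so they reconstruct the centered
coordinates exactly.

A 2-D free-energy landscape over two collective variables is the Boltzmann
inversion of their histogram, `F = −kT ln(P / P_max)`, reported in kT (and
convertible to kcal/mol with k_B = 0.0019872041 kcal/(mol·K)). The occupied
minimum is exactly 0; empty bins carry NaN rather than an arbitrary cap.
For Gaussian CVs with standard deviation σ this yields a paraboloid with
curvature 1/(2σ²) per axis, which is used as a recovery oracle.

## Markov state models

Frames are clustered into microstates by k-means (k-means++ seeding, fixed
random state) in CV space. Transition counts at lag τ respect trajectory
boundaries (no counts across replica joins). The estimator symmetrizes
counts, (C + Cᵀ)/2, restricts to the largest connected component, and
row-normalizes; the stationary distribution π comes from the symmetrized
row sums. The spectrum is computed from the similar symmetric matrix
D^{1/2} T D^{−1/2} (D = diag π), so eigenvalues are exactly real and
detailed balance holds to machine precision.

Implied timescales are `t_i = −τ / ln|λ_i(τ)|`; lag-independence of t_i
indicates Markovianity at that lag. Macrostates come from a crisp spectral
lumping: k-means on the leading right eigenvectors ψ_i = v_i/√π, with
macrostate ids ordered by population. The Chapman–Kolmogorov test compares
the macrostate transition matrix predicted as T(τ)^k with the one
re-estimated at lag kτ; confidence intervals come from a block bootstrap
over contiguous trajectory blocks, and the reported score is the fraction
of matrix elements whose prediction lies inside the estimated CI.
Representative structures are medoids: the member frame minimizing the
total pairwise fitted RMSD to the other members of its macrostate.

## Correlated motions and networks

The dynamic cross-correlation matrix (DCCM) is the normalized covariance of
displacement vectors, `C_ij = <Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)`, in
[−1, 1]. Zero-variance atoms yield NaN rows with a warning. DCCM scores
orthogonal correlated motions as 0.

The generalized correlation fixes that blind spot:
`GC_ij = sqrt(1 − exp(−2·MI_ij / 3))` with MI the mutual information
between the two atoms' 3-D displacement vectors, estimated by the
Kraskov–Stögbauer–Grassberger k-nearest-neighbor estimator (algorithm 1,
Chebyshev metric, k = 6, duplicate points jittered). For jointly Gaussian
motion GC = |r| exactly, which the tests exploit.

The residue network has one node per selected residue (typically its Cα).
An edge joins two residues whose minimum heavy-atom distance stays within
4.5 Å in at least 75% of frames (both parameters configurable; boundary
inclusive; sequence neighbors excluded by default). Edge weights are
`−ln|C_ij|`, so strong correlation means short network distance; |C| = 0
edges are dropped with a warning. Communities come from Girvan–Newman
divisive clustering — repeatedly removing the edge of highest weighted
betweenness — with the partition chosen at maximum weighted modularity
along the dendrogram. Signalling routes are minimum-total-weight Dijkstra
paths with deterministic tie-breaking (fewer hops, then lexicographic);
the physical path length is the sum of mean inter-node distances along the
route.

## Interactions

A hydrogen bond D–H…A exists in a frame when the donor–acceptor distance is
≤ 3.5 Å and the D–H–A angle (at the hydrogen) is ≥ 135°; both cutoffs are
configurable. Donor hydrogens are resolved from frame-0 geometry (≤ 1.25 Å
from the donor heavy atom). A water bridge exists when one water is
simultaneously hydrogen-bonded (either role) to a protein atom and a ligand
atom; per protein-residue/ligand-residue pair the package reports both the
pair occupancy (any water) and the maximum persistence of any single water,
which distinguishes a conserved structural water from an exchanging site.

SASA is Shrake–Rupley: quasi-uniform points (golden-spiral construction,
960 by default) on each atom's solvent-expanded sphere (van der Waals
radius + 1.4 Å probe); the accessible fraction times the sphere area,
summed over the selection, with all atoms occluding. Solvent-shell counts
are waters whose O lies within a configurable radius (default 5.0 Å) of any
ligand atom.

The residue–ligand interaction energy is the plain pairwise nonbonded sum,
`E_elec = Σ 332.0636 q_i q_j / r_ij` (kcal/mol) and
`E_vdw = Σ 4 ε_ij [(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶]` with Lorentz–Berthelot
combining, no cutoff and unit dielectric, reported as mean ± SD over
frames; frames with sub-0.5 Å contacts are flagged as clashes.

## Synthetic validation data

Because μs-scale MD ensembles are not reproducible at desk scale, every
stage is validated against generators with exact ground truth: Gaussian
ensembles with planted per-component correlations (closed-form DCCM, MI and
GC), metastable Markov chains emitted into a CV plane (closed-form
timescales), and rigid protein/ligand/water fixtures with planted hydrogen
bonds, bridges and shell waters whose occupancies are exact by
construction.
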