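# Methods

This note records the models, conventions, numerical choices and known
limitations behind `dynevo`, in the order the pipeline applies them.

## Ensembles, alignment, superposition

The analysis operates on C-alpha traces. Ensembles enter as multi-model
PDB (parsed with biotite) or as a plain `frame site x y z` table; the
table writer uses full `repr` precision so table round-trips are
bit-exact, while PDB round-trips carry the format's 10⁻³ Å precision.
Residues lacking a CA atom are skipped with a warning; a file with no CA
atoms is an error. Multi-chain files use the first chain unless a chain ID
is configured — the intended inputs are single-domain monomers.

Superposition is closed-form weighted Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`, with the residual
recomputed directly from coordinates (the library's reported residual
loses precision to cancellation on near-exact fits). Reflections are never
returned. Collinear or coincident site sets are rejected because the
optimal rotation is not unique there. Trajectory alignment iterates
align-to-mean / recompute-mean to a fixed point (mean shift < 10⁻¹² Å RMS,
≤ 100 passes), seeded with the coordinate mean so an already-aligned
ensemble is a fixed point; when rigid-body contamination has collapsed the
raw mean toward a degenerate shape, the first frame seeds instead. Frames
within one call are superposed by a batched Kabsch (batched 3×3 SVDs),
which is what makes windowed PCA over thousands of frames cheap.

## Windowed PCA and convergence

The covariance of each window uses the population (1/T) normalization, as
befits a time average. Eigendecomposition keeps at most 30 modes (faster
modes carry no information about large-scale functional motion), clips
roundoff-negative eigenvalues to zero, and fixes each eigenvector's sign
by making its largest-magnitude component positive — signs are physically
meaningless, and fixing them makes every downstream comparison
reproducible. The fluctuation profile of mode *k* is λₖ·|v₍ₖ,ᵢ₎|² per site
(Å²), i.e. the eigenvalue-scaled squared amplitude; this convention makes
the profile sum to the mode variance and puts the divergence cutoffs in
Å².

Windows are laid out by (length, stride) in frames; time is deliberately
abstracted to frames because the package consumes generic ensembles, not
timed MD. Each window is aligned independently. Convergence compares the
slowest-mode profiles of successive windows by Pearson correlation; the
run is converged when the last `min_windows_converged` comparisons all
exceed 0.8. The default `min_windows_converged = 4` makes the converged
span equal three window-lengths when stride = length/2 (five
half-overlapping windows). Comparing the top *m* mode profiles instead is
available (`n_modes_compare`); the pair statistic is then the minimum
correlation over modes, the strictest choice. A constant (zero-variance)
profile makes the correlation undefined and is reported as an error naming
the window rather than silently passed. Non-convergence is a gate: the
pipeline refuses to run comparative stages on unconverged ensembles unless
forced, on the view that the remedy is more sampling, not a warning.

## Dynamics space

G has 3N′ rows (N′ = alignment columns ungapped in every protein; at least
4 required) and P·K columns — one per (protein, mode), K = 10 by default,
so three proteins give 30 columns. Each column is the mode's eigenvector
restricted to the aligned sites, weighted by its eigenvalue λ (not √λ:
the weighting follows the construction's plain statement; √λ is available
via a flag). Restricted vectors are not re-normalized; the retained norm
is recorded per column as a coverage diagnostic, so heavy gapping is
visible rather than silently rescaled. Column signs are canonicalized on
the restricted vector, which is what makes protein placement invariant to
arbitrary eigenvector signs.

A protein's coordinates are the projections of its weighted slowest-mode
column onto the top-d left singular vectors (d = 2 by default); the
alternative placement at the centroid of all K of its column projections
is available via `placement="centroid"`. The projection basis ("left") and
placement are recorded in the output sidecar so either convention can be
reproduced. Pairwise protein distances are Euclidean in the retained d
dimensions. Significance testing of cluster separation is out of scope.

## Divergence screens

All per-site statistics are indexed by alignment column; a site deleted in
one protein yields a gap column (NaN delta) and annotations on its two
flanking columns, so deletions are reported through their neighbours. The
two-way classification uses the pair of parallel lines at ±cutoff around
the diagonal Δfluct(A→B) = Δfluct(B→C): above the band (`upper_left`) the
B→C branch dominates in the signed plane, below it (`lower_right`) the
A→B branch does. Note the labels name plot regions, not magnitudes: a
site strongly *rigidified* on the B→C branch has a large negative
Δfluct(B→C) and lands below the band.

The criticality screen is dd = ‖|Δfluct(A→B)| − |Δfluct(B→C)|‖ > cutoff.
The default cutoff is 0.002 Å². Because dd scales with the ensemble's
overall fluctuation magnitude, the cutoff is defined relative to a
reference magnitude: the default value corresponds to ensembles whose mean
per-site slowest-mode fluctuation is 0.002 Å²/site, and
`scale_dd_cutoff` rescales it proportionally to the observed pooled mean.
With defaults this reads: *a site is critical when its net fluctuation
change exceeds the average site's entire slow-mode fluctuation*. The
rationale is statistical: any localized stiffness change renormalizes the
global mode and spreads collateral change of a fraction of the mean onto
the remaining flexible sites, and finite sampling (T = 2000 frames puts
~3% relative noise on the top eigenvalue) adds jitter of the same order;
a cutoff at the mean sits above both while genuine site-localized
perturbations move their sites by multiples of it.

Cross-correlation maps default to the mode-reconstructed covariance over
the retained modes, Cᵢⱼ = Σₖ λₖ vₖᵢvₖⱼᵀ traced over x, y, z (matching the
reduced mode set used everywhere else); full-trajectory computation is the
alternative route and agrees exactly when all 3N modes are retained.
Values are clipped to [−1, 1] against roundoff and the diagonal is set to
exactly 1; a zero-variance site is an error naming the site. Block
summaries average a rows × columns submatrix excluding diagonal entries.

The static screen superposes one structure onto the other over all
ungapped columns and flags per-column squared displacements above 6 Å² —
a coarse detector of residues repacking into distinct static
conformations; it deliberately ignores dynamics.

## Fold-candidate scoring

Hydrophobic radius of gyration uses the configurable hydrophobic set
{ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, CYS}. Contact counts use strict
inequality (< 7.0 Å); with secondary-structure labels supplied, loop
residues are excluded and same-element pairs are not counted (both rules
individually switchable — inputs without labels count all hydrophobic
pairs). The combined score is a rank sum (rg ascending + contacts
descending, minimum rank for ties, final ties broken by rg then input
order): scale-free and robust, with the raw criteria always emitted so
alternative combinations can be applied downstream. Clustering is a
deterministic one-pass leader scheme at 1.0 Å RMSD radius — a
radius-based criterion is incompatible with k-means (which needs k), and
input-order determinism makes the clustering testable; the post-hoc
medoid (member minimizing total intra-cluster RMSD) may differ from the
founding leader, so assignment-time RMSDs are recorded per member.
Consensus contact maps translate each homolog's pairs into the target
numbering via per-homolog label maps, drop pairs touching unaligned
sites, and intersect.

## Synthetic ground truth

The generator is an anisotropic elastic network (ANM) over an idealized
C-alpha chain: springs connect site pairs within 10 Å (default stiffness
1, arbitrary units), and the analytic covariance is the pseudo-inverse of
the Hessian scaled by `temperature_scale`, with eigenvalues below 10⁻⁸ ×
the largest treated as rigid modes and removed. An ENM was chosen over MD
because the analysis consumes only second-moment structure, so parameter
recovery is exact in the large-sample limit and desk-fast. Ensembles are
exact draws from the stationary Gaussian via the symmetric
eigenfactorization, optionally composed with random per-frame rigid
motions (rotation + translations up to 5 Å) that a correct alignment must
remove; every output is a pure function of (spec, seed), with per-protein
seeds expanded from the scenario seed by a documented affine scheme.

Toy chains come in three geometries (extended, helix, helix-loop-helix)
with 3.8 Å consecutive spacing and right-handed helices (2.3 Å radius,
1.5 Å rise, 100°/residue). Small distance-spring networks can possess
internal zero-stiffness mechanisms — an extended chain is maximally
floppy, and the default 20-site helix-loop-helix carries one soft
mechanism; the helix geometry is full-rank (exactly six zero modes) and
is used where rank matters.

Mutations are planted by multiplying the stiffness of all springs
incident to chosen sites by a factor (> 1 rigidifies). The default
scenario — 20-site helix-loop-helix, 2000 frames per ensemble, proteins A
and B from the base network and C with sites (0, 9, 10, 12, 19) stiffened
×4 — places the perturbation at the chain's five most flexible sites
(termini, loop, helix-2 start), emulating the rigidification of a
flexible, functionally important region during the evolution of binding
specificity. This placement matters: the slowest mode is collective, so
stiffening sites the mode barely moves produces changes smaller than the
mode-renormalization it induces elsewhere, and no per-site screen could
attribute them. Inter-region couplings are planted as a rank-1
shared-motion term added to the covariance across two site groups, which
raises the cross-correlation block mean while preserving positive
semi-definiteness. The non-convergence scenario switches the generator
mid-run to a strongly reshaped network (one helix stiffened ×8, the other
loosened ×8), reversing the slow-mode profile shape across the switch.

What the generator does *not* emulate: anharmonicity and multi-basin
kinetics, sequence-dependent interactions, side-chain packing, solvent,
and real mutational physics beyond local stiffness change. Passing the
planted-recovery checks therefore demonstrates that the statistics
recover second-moment ground truth at realistic sampling noise — not that
any particular biological mutation would be detected.

## Problem sizes and tolerances

Benchmark sweeps use 10 seeds of the default scenario (3 × 2000 frames,
20 sites), 5000-frame draws for the sampling-consistency check, and
20 random 5–15-site cases for the superposition oracle; these sizes put
every sweep at seconds-to-a-minute on one core while leaving the
statistical margins wide. Exact-contract tolerances: covariance vs
double-loop oracle 10⁻¹² (absolute, Å²), eigenvalues vs oracle 10⁻⁸,
trace conservation 10⁻¹⁰ relative, rigid-motion eigenvalue invariance
10⁻⁸ Å², SVD reconstruction 10⁻¹⁰ relative Frobenius, sign/permutation
invariance 10⁻¹⁰, Kabsch vs grid search 10⁻³ Å. The grid-search
superposition oracle searches rotation-vector (axis-angle) space — Euler
parameterizations are gimbal-degenerate near the identity and trap
hierarchical zooming in curved valleys.

## Known limitations

* Alignment-based PCA assumes fluctuations small enough that rigid-body
  removal and internal motion separate cleanly; ensembles with very soft
  mechanisms (huge-amplitude modes) violate this and their analytic
  covariance is not exactly recovered.
* The Pearson convergence rule compares successive windows only; slow
  drifts with period longer than the run can pass it.
* Dynamics-space distances have no attached significance model.
* The dd screen attributes changes per site; strongly delocalized
  perturbations are fundamentally ambiguous under any per-site statistic.
* Deletion handling reports flanking columns but does not model the
  backbone rearrangement a deletion causes.
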