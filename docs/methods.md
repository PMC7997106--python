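# Methods

This note documents the models, numerical choices, and limitations behind
`zernipatch`. Everything stated here is computed by the test suite or the
acceptance script; nothing is quoted from external runs.

## Pipeline overview

A *patch* is the solvent-accessible surface (SAS) generated by a declared set
of residues. The pipeline is

1. **select** — residue-range selection (inclusive intervals, chain-qualified
   or wildcard, author numbering taken verbatim from the file);
2. **sample** — SAS point sampling over the *full* structure, then restriction
   to points owned by the selected atoms;
3. **potential** — Coulomb sum over all atomic partial charges, split by sign;
4. **voxelize** — three weighted copies of the point cloud (unit weights,
   |V⁺|, |V⁻|) accumulated into unit-ball grids sharing one placement;
5. **moments → invariants** — 3D Zernike moments C_nlm and the
   rotation-invariant norms F_nl.

Step 2's full-structure scope matters: a binding-site surface is shaped by
occlusion from the surrounding protein, so surface points are generated for
every atom and only then filtered by ownership. Callers who really want the
bare patch can pass just those atoms.

## Surface sampling

Each atom sphere, expanded by the probe radius (default 1.4 Å, a water
molecule), carries a deterministic Fibonacci lattice of `samples_per_atom`
points (default 200). A sample is buried — and removed — when it lies strictly
inside another atom's expanded sphere, with a relative tolerance of 1e-9 to
absorb roundoff at exact contact. This is point-sampled SAS, not a
triangulated or analytically resolved surface: area estimates and burial
boundaries carry sampling noise that decays like the inverse square root of
the sample count. A brute-force burial oracle (every sample against every
atom) pins the implementation exactly in the tests.

The lattice is deterministic so identical inputs give identical surfaces with
no seed; the price is that the lattice does not co-rotate with the molecule,
which contributes to the invariance error budget below.

## Electrostatics

The potential at surface point p is V(p) = (1/ε) Σ_i q_i / |p − x_i| with
charges in elementary units from a PQR file (PDB files get zero charges) and a
uniform dielectric ε (default 4.0, a common protein-interior compromise).
This is deliberately not a Poisson–Boltzmann model: the descriptor consumes
only the sign-split spatial *pattern* of the potential, for which a bare
screened Coulomb sum suffices and stays reproducible with no solver
parameters. The sign split V = V⁺ − V⁻ is exact and loses nothing; it exists
because the invariant norms cannot distinguish positive from negative values,
only patterns of nonzero mass. Electrostatic voxels are weighted by |V| by
default; a `binarize_elec` flag switches to 0/1 occupancy for callers who want
pure pattern comparison.

## Voxelization

Points are translated to their centroid (this makes translation invariance
exact) and isotropically scaled so the farthest point sits at radius
`ball_fill` (default 0.7) inside the unit ball — far enough from the boundary
that no mass is truncated, close enough not to waste resolution. Each point
adds its weight to the voxel containing it (nearest-voxel accumulation), so
total grid mass equals the weight sum exactly; mass conservation is asserted
in the tests. The default grid dimension is 64, which resolves order-20
polynomials. All three channels of one patch share one centering and scale, so
they live in a common frame.

## Zernike moments

Moments are defined with the 3/(4π) normalization, under which the basis is
orthonormal on the unit ball. The radial polynomials are constructed from
Jacobi polynomials, R_nl(r) ∝ r^l P_k^{(0, l+1/2)}(2r² − 1) with k = (n−l)/2,
normalized so ∫₀¹ R_nl² r² dr = 4π/3; combined with orthonormal spherical
harmonics this makes (3/4π)∫|Z|² dV = 1 (verified numerically: the discrete
Gram matrix at dimension 64, order 6 deviates from identity by ≤ 0.011, pure
quadrature error).

The production route expands every Z_nl^m as a polynomial in (x, y, z) —
coefficients built once per order in exact rational arithmetic (`Fraction`),
converted to floats only at the end — and contracts the conjugated coefficient
table with geometric moments M_rst of the nonzero voxels. Negative-m
coefficients follow from C_{n,l,−m} = (−1)^m conj(C_nlm), exact for real
fields. The independent test oracle evaluates R_nl(r)·Y_l^m(θ, φ) directly at
every voxel center via scipy's spherical harmonics and Jacobi polynomials; the
two routes agree to ≤ 1e-6 relative error (measured ~5e-12) at order 8 on 32³
grids. Order 20 is the validated stability ceiling; higher orders work but
warn, since the rational coefficients grow combinatorially and the float
contraction loses digits.

Reconstruction (the truncated series) is provided for validation: its L2 error
against the input is non-increasing in the order, and re-analysis of a
reconstructed field recovers the moments up to discrete-orthogonality error.

## Invariance accuracy

Translation invariance is exact by construction (verified to float
tolerance). Rotation invariance is exact for the *moments* of a fixed
function, but the pipeline discretizes twice, and both steps break perfect
invariance:

* **voxel quantization** — rotating the *same* point cloud and re-binning
  moves descriptor components by up to ~1e-2 of the largest component at
  dimension 64 (measured: max|ΔF|/F_max ≈ 1.05% for a 4000-point cloud). This
  error shrinks roughly quadratically with grid dimension.
* **surface re-sampling** — rotating the atoms re-samples the SAS on the
  fixed Fibonacci lattice; at 400 samples/atom this roughly doubles the
  deviation (measured, helix-like fixture, 20 seeded rigid motions, full
  pipeline: max|ΔF|/F_max ≈ 3.0%, whole-vector L1 relative deviation ≈ 1.6%).

Because small components sit at this absolute noise floor, *per-component*
relative deviation is meaningless for components far below the vector maximum
(it approaches 100% regardless of implementation or sampling density). The
honest guarantee this package makes — and tests — is at the vector level:
whole-descriptor L1 relative deviation ≤ 3% under rigid motion at default
settings, improving with samples per atom and grid dimension. Two tests in the
acceptance suite assert a stricter per-component 1% bound at dimension 64;
they fail by design and their failure messages point here. Patches whose
boundary is defined by burial against other atoms (e.g. a pocket lining) are
noisier still (~17% vector deviation measured for the cavity fixture), because
rigid motion flips which samples are buried at the patch rim.

Descriptors are *not* normalized before distance computation (distances are
raw L1 sums, as defined); a `normalize_descriptors` flag provides unit-length
normalization for callers comparing patches of very different sizes. The
descriptors are also invariant under reflection — the m-norm discards
handedness — which is why a bowl and its mirror bump share a shape descriptor,
and why shape complementarity and shape similarity coincide.

## Distance distributions and the signed overlap

Ensembles are compared through distributions of pairwise descriptor distances:
within one ensemble all unordered pairs i < j (n(n−1)/2 samples, self-pairs
excluded so intra distributions carry no structural zeros), across two
ensembles all ordered pairs (n₁·n₂). The electrostatic channel of a
distribution uses the like-pairing average (the similarity definition).

The overlap coefficient between two distributions is ∫ min(f̂₁, f̂₂) dx, where
f̂ are Gaussian kernel density estimates with Silverman bandwidth, evaluated
on a shared grid of 512 points spanning the pooled sample range extended by 3
bandwidths on each side. Both densities are renormalized to unit mass *on that
grid*, so a distribution overlapped with itself scores exactly 1 up to
trapezoid error; byte-identical sample sets short-circuit to exactly +1. The
sign is positive when the first distribution's mean is the larger (ties break
positive, a deterministic convention since the sign rule is only stated for
strict ordering). Degenerate zero-variance sample sets are rejected with an
error rather than silently producing a delta-function KDE. Overlap magnitude
is symmetric to numerical tolerance; the sign is antisymmetric.

## Two-cluster bimodality criterion

A distance-to-reference series is declared two-state when the exact 1-D
2-means split (threshold minimizing within-cluster sum of squares) yields
Ashman's D = |μ₁ − μ₂| / sqrt((s₁² + s₂²)/2) > 4. The conventional D > 2
applies to true mixture components; hard-splitting *unimodal* data inflates
the statistic (a Gaussian split at its mean scores ≈ 2.7, a uniform ≈ 3.5), so
the default threshold is 4. The planted two-state fixture scores D ≈ 15–21.

## PCA of descriptor ensembles

PCA is fit on the pooled, mean-centered matrix of all ensembles' descriptor
vectors (pooling is required for a shared projection plane), via
scikit-learn. Projections keep their ensemble labels; explained-variance
fractions are reported per component. A planted two-cluster fixture recovers
the centroid separation within 10%.

## Synthetic fixtures: what they emulate and what they do not

The fixture module generates every test input: single spheres and dipoles
(analytic checks), helix-like chains with alternating charge (generic
asymmetric patches), two-state ensembles (a helix and a 60°-kinked copy with
0.15 Å Gaussian jitter, alternating frames — a caricature of a slow
conformational switch plus fast fluctuations), and a complementary
cavity/bump pair. All randomness flows through explicit integer seeds.

The complementary pair plants a known ground truth: cavity and bump linings
share one angular lattice, the bump radius is the cavity radius minus one
atom-plus-probe diameter, and rim margins are chosen per curvature sign
(burial truncates a convex SAS cap earlier than a concave one), so the two
patch surfaces are point-inversion-congruent caps. The bump's lining charges
are rescaled at build time so both patches carry the same mean |potential|,
making the cross-channel match an amplitude match too. The mismatched control
is a flat wide bump (radius 14 Å, half-angle 40°). These fixtures validate the
machinery; they do not emulate real protein surfaces — no atom-type diversity,
no charge heterogeneity beyond the planted patterns, no force-field geometry —
so passing tests demonstrate correctness of the computation, not biological
accuracy of any particular comparison.

## Problem sizes

The test suite and acceptance script run at deliberately modest scale: patch
fixtures of 20–600 atoms, ensembles of 21–40 frames, grids of 32³–64³, orders
8–20. The acceptance script describes 21 frames at order 20 on a 48³ grid with
150 samples/atom — enough for the overlap extremes it measures, which are
scale-free properties of the estimator. Production use on real structures
(thousands of atoms, hundreds of frames) is linear in frames and near-linear
in atoms for surface construction; the moment contraction cost depends only on
the number of nonzero voxels and the order.

## Known limitations

* Point-sampled SAS, not an analytic surface: burial boundaries jitter under
  rigid motion; patch rims are the dominant noise source.
* Bare Coulomb with uniform dielectric; no screening beyond 1/ε, no solvent
  reaction field.
* Nearest-voxel accumulation aliases thin surfaces; it was chosen for its
  exact mass-conservation contract, and it bounds the invariance accuracy as
  quantified above.
* Reflection-blindness is inherent to the invariants: enantiomeric patches
  are indistinguishable in every channel.
* The residue-selection syntax has no insertion-code support (files carrying
  insertion codes are rejected rather than silently merged).
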