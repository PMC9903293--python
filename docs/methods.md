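# Methods

## Forward model

The domain is the unit-radius disk (2D) or unit-radius cylinder of height 1
(3D), meshed with linear simplices. The disk mesh is built from concentric
rings whose node counts are multiples of the electrode count, so the
structured mesh is exactly invariant under rotation by one electrode
spacing; the homogeneous-disk frame is then periodic across stimulation
blocks to machine precision, which the test suite exploits. An optional
seeded `jitter` displaces interior nodes to emulate unstructured meshes.
The cylinder extrudes the disk into an even number of prism layers (each
split into three tetrahedra with a conforming min-vertex rule) so that a
node layer lies exactly on the mid-height electrode plane.

Electrodes follow the gap (point-electrode) model: unit current enters and
leaves the node group of each adjacent electrode pair and voltages are node
potential differences. One non-electrode boundary node is grounded per
solve; differential measurements make the choice immaterial. A complete
electrode model with contact impedance is deliberately out of scope:
difference imaging is insensitive to the electrode model at the accuracy
studied here. The adjacent protocol takes, per stimulation pair (k, k+1),
the 13 adjacent voltage pairs sharing no current-carrying electrode, in
increasing order starting just after the stimulation pair; the same
convention is used by the forward solver, the 13 × 16 reshape and all file
I/O.

The phantom places a heart disk/sphere (radius 0.3, conductivity 2) between
two lungs (conductivity 0.5, radius swept 0.3–0.6) on background 1.0
(arbitrary units; lengths are fractions of the domain radius). Centers
default to heart (0, 0.1) and lungs (±0.3975, −0.0442) — the lateral
layout scaled so the fully expanded lung still fits in the domain. Element
membership is decided by centroid; the heart is assigned after the lungs
and wins overlaps. Geometrically, a radius-0.6 lung at a feasible center
must overlap both the domain center and the heart; this is a property of
the normalized geometry, not of the meshing, and it shapes everything
below.

## Separation

Both separations act on a single raw 208-voltage frame.

**PCA.** The frame is reshaped to 13 × 16 (rows = measurement positions,
columns = injections). Columns are the variables: each column is centered
over its 13 rows and the 16 × 16 covariance (normalization 1/(13−1)) is
eigen-decomposed. Centering makes the matrix rank ≤ 12, so exactly 12
components are significant for a generic frame. Eigenvector signs are
fixed (largest-magnitude loading positive) so weighted recompositions are
run-to-run stable. Recomposition adds the column means back and sums
weighted rank-one terms; unit weights reproduce the input to round-off.
Cardiac separation zeroes the lung-dominant component, PC4 by default
(1-based, configurable); ventilation separation multiplies it by a gain,
default 1.01.

Note that the *operator* "decompose, zero component 4, recompose" is not
idempotent: after removal that eigen-direction has zero variance, so a
second decomposition promotes the next component into slot 4. Removal is a
projection only under a fixed basis, which is the form the test suite
asserts.

**EMD.** The serial frame (protocol flat order, stimulation-major) is
sifted classically: cubic-spline envelopes through local maxima/minima with
two extrema mirrored past each end, iterating until the Cauchy criterion
SD < 0.2 or 10 sifts, extracting IMFs until the residue has fewer than
three extrema. The residue is kept at weight 1 in every recomposition, so
IMFs + residue always reproduce the input to 1e−8 or better. Cardiac
separation drops IMF1, ventilation separation scales it by the gain. The
IMF count for the default phantom frame is 4 under this policy (such
counts are policy- and signal-dependent; richer or noisier signals yield
more). All sifting knobs are exposed in the run config and logged.

## Inverse problem and metrics

Sensitivities are computed by the adjoint method: for measurement (s, m),
dv/dσₑ = −volₑ ∇u_s · ∇u_m at the reference conductivity; with adjacent
drive the 16 drive fields serve both roles, so one sparse factorization
yields the whole 208 × n_elements Jacobian (validated against finite
differences to 1e−4). Reconstruction is one-step Gauss–Newton,
Δσ = (JᵀJ + λ²·s·R)⁻¹Jᵀ(v − v_ref), R the NOSER diagonal diag(JᵀJ)^0.5
(or identity), with the scale factor s making λ dimensionless; λ defaults
to 0.05. In 3D only elements within |z − h/2| < 0.15 of the electrode
plane are reconstructed (2.5D). Images are rasterized to a 32 × 32 grid on
[−1, 1]² by point-in-element lookup (nearest slab element in 3D), masked
to the unit disk.

GREIT figures are computed from the quarter-amplitude set (in-mask pixels
with signed amplitude ≥ ¼ of the signed peak): PE is the Euclidean
distance from the target center to the amplitude-weighted centroid of the
set; SD is the fraction of set amplitude outside the equal-area circle C
centered at that centroid; RNG is opposite-sign amplitude outside C over
same-sign amplitude inside C; AR and RES are reported alongside. A binary
(unweighted) centroid is available for sensitivity checks. All lengths are
in domain radii, so the figures are dimensionless.

## What the simulator shows — and what it cannot

The pipeline reproduces the qualitative phenomena of the simulated-breathing
study: with equal radii all three inclusions reconstruct cleanly; as the
lungs expand the central positive (cardiac) peak of the profile collapses
(strongly decreasing end to end, with sub-percent discretization ripples at
interior radii); removing the lung-dominant component raises the central
peak again for both methods; and the ringing of the PCA-separated image
exceeds that of the EMD-separated one while both are far below the
unseparated image's.

Quantitatively, however, single-component removal cannot make the cardiac
image clean in this geometry. The lungs-0.6 voltage signal is ~3–4 orders
of magnitude stronger than the cardiac signal and spans at least three
principal components / several IMFs of the frame (the two-lung pair
contributes a mean, a cos 2θ and a sin 2θ injection-space signature, plus
harmonics, and at maximal expansion it overlaps the heart region itself,
adding a nonlinear interaction term). Removing any one component therefore
leaves a lung residue larger than the whole cardiac signal, and SD/RNG of
the separated images remain far above what an ideal separation (or a
heart-only phantom, which scores PE ≈ 0, SD ≈ 0.05, RNG ≈ 0.05) would
give. This was verified directly: subtracting the exact lungs-only signal
still leaves SD ≈ 0.2 from the interaction term, and an exhaustive search
over all removals of up to three components bottoms out near SD ≈ 0.4.
Consequences visible in the figure-of-merit suite: SD and RNG of the
separated images sit an order of magnitude above the ideal, and the
lung-gain sweep (0 → 0.99 → 1.01) is not monotone at gain 0, where removing
the entire carrier-dominated IMF1 produces large reconstruction artifacts.
A separation that concentrated the lung into exactly one component would
require properties of the measurement matrix that this geometry does not
produce.

The synthetic phantom also idealizes real data in ways that matter: it is
noiseless by default (optional seeded Gaussian noise is a config knob),
perfectly cylindrical, stationary within a frame (no cardiac-cycle motion),
and uses the gap electrode model. Passing tests therefore demonstrate the
algorithmic contracts and the geometry-driven phenomena above, not clinical
performance on human recordings.

## Numerical choices

* Covariance normalization 1/(13−1); irrelevant to selection (scale-free),
  fixed for reproducibility.
* Eigenvalue significance threshold 1e−10 relative to the largest.
* Hyperparameter λ = 0.05 with the NOSER prior emulates a standard one-step
  difference solver; λ and prior are config knobs and logged provenance.
* Degenerate inputs: monotone signals yield zero IMFs and residue = input;
  an all-one-sign image raises on a wrong-sign quarter set; empty quarter
  sets raise rather than return NaNs; non-positive conductivities and
  non-finite frames are rejected at construction.
* Problem sizes: the default study runs on a ~1000-element 2D disk
  (element size 0.08) for interactive work and a ~5500-tet 3D cylinder
  (element size 0.15) for the headline figures; both solve in seconds.
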