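# Methods

## The constrained projection model

A tilt series images the same field of particles T times under a known
acquisition geometry. `spcet` never treats the resulting particle projections
as independently alignable images: the five 2D alignment parameters of
projection *i* of a particle are a deterministic function of (a) the tilt
geometry of the image it came from — tilt-axis angle α, stage tilt β, image
shifts — and (b) the particle's single rigid transformation (three Euler
angles, one 3D position). Refinement therefore optimizes 6 parameters per
particle instead of 5T, which is what makes alignment tractable at
tomographic SNR.

Conventions (fixed and used identically by the simulator, the scorers and
the reconstructor, so every round trip is exactly testable):

* Euler angles are intrinsic ZYZ in degrees, `R = Rz(θ)·Ry(φ)·Rz(ψ)`,
  mapping reference-frame coordinates to the particle's placement.
  Canonical storage ranges are θ, ψ ∈ [−180, 180), φ ∈ [0, 180]; at gimbal
  lock ψ is set to 0 and folded into θ.
* The tilt operator rotates the coordinate frame by −α so the tilt axis is
  vertical, tilts about it by β, and rotates back: `M = Rz(α)·Ry(β)·Rz(−α)`;
  the beam projects along z after applying M.
* Tomogram coordinates are 0-based voxels with rotation origin
  `(nx//2, ny//2, nz//2)`; per-tilt shifts are applied last, in the
  projection plane, in unbinned pixels. (Whether shifts precede or follow
  the tilt rotation is a genuine convention choice; shift-last is fixed
  here and used consistently everywhere.)

The projection orientation is `Q = M·R`, the projection shift is the tilted
3D position projected to the image plane plus the per-tilt (and per-region)
image shifts. All of this is exact rotation-matrix algebra — no small-angle
approximation anywhere.

## Forward model and score

All projections — simulated data, reprojections for scoring, and the
adjoint used in reconstruction — go through one Fourier central-slice
operator (trilinear interpolation in the volume transform, phase ramps for
sub-pixel shifts). Because data generation and scoring share the operator,
the self-match score of a noiseless projection is 1 to numerical precision,
which anchors all recovery benchmarks.

The projection-matching score `d` is the normalized cross-correlation
between an observed crop and the CTF-multiplied reprojection, computed over
a resolution band in Fourier space (DC excluded, so `d` is invariant to
image scaling and offset, and bounded in [−1, 1]). The refinement objective
`D` is the sum of `d` over the projections involved. This plain normalized
correlation (rather than an SNR-weighted variant) is a deliberate
simplification: the score enters only through arg-max and monotone
comparisons, so parameter-recovery behavior is unaffected.

Crops are cut once around each particle's predicted projection position; all
subsequent motion is expressed through Fourier phase ramps relative to the
crop center. Binning is Fourier cropping (anti-aliased), applied to the
reference and the crops together.

## Refiners

**Global search** scans an orientation grid (ZYZ product grid, degenerate
in-plane rows collapsed); for each candidate orientation the per-tilt
reprojections follow from the constraint, and an integer 3D displacement
grid around the initial position is scored through per-tilt phase ramps.
Ties break toward the first grid point. A surface-normal prior (from
spherical-surface picking) collapses the search to the single in-plane
angle, which is where the order-of-magnitude evaluation saving comes from.

**Fully constrained refinement** maximizes the particle's summed score over
its six rigid parameters. The rotation is parametrized as a rotation-vector
perturbation about the current orientation, not as Euler deltas: Euler
coordinate descent fails to converge even on noiseless data (θ and ψ are
coupled and degenerate near φ = 0/180, leaving narrow curved valleys a
per-coordinate search cannot follow), while the rotation-vector chart is
isotropic at the current pose. The maximizer is bounded derivative-free
Powell (direction-set) search, tolerance 0.01°/0.01 px; a final guard keeps
the input pose if the optimizer somehow ends lower, so the aggregate score
is non-decreasing by construction. The z-translation bound defaults to the
in-plane shift bound.

Per-projection CTFs are held at the particle's entry position during a local
pose search: the depth-defocus gradient across a few voxels (∼ tens of Å at
2 Å/px) is far below CTF sensitivity at these box sizes.

**Region-based geometry refinement** partitions the tomogram into a uniform
half-open grid (boundary coordinates fall in the upper cell; flat index
`ix + nx·iy + nx·ny·iz`) and, per region and tilt, maximizes the summed
score of the region's particles over corrections (dα, dβ, dshift) to the
shared geometry, holding particle poses fixed — a piecewise-constant model
of beam-induced deformation. Per-coordinate bounded search suffices here
(the four parameters are not strongly coupled). Regions with fewer particles
than a configurable minimum keep zero corrections and are reported. A
single-region grid is exactly global per-tilt geometry refinement. The
per-region β correction is refined per tilt (per-series β refinement can be
emulated by tying the window, but per-tilt is the default).

**Region-based CTF refinement** maximizes the same objective over a region's
mean defocus pair and astigmatism angle within a user tolerance (zero
tolerance returns the input). The search runs on (mean, difference, angle)
coordinates — the mean defocus is the well-determined direction, while the
df1/df2 split is degenerate for round beams — and starts with a 100 Å grid
scan along the mean-defocus axis before the bounded Powell polish, because
the objective oscillates with Thon-ring side lobes and a purely local search
can lock onto the wrong ring. Pose-dependent factors (slices, phase ramps)
are precomputed; only the CTF factor is re-evaluated per step. The summed
score never decreases (input returned otherwise).

## CTF model and estimation

`CTF(k, t) = −(√(1−A²)·sin γ + A·cos γ)` with
`γ = πλ·df(t)·k² − (π/2)·Cs·λ³·k⁴ + phase_shift` and
`df(t) = (df1+df2)/2 + (df1−df2)/2·cos 2(t − astig_angle)`; λ from the
relativistic electron wavelength. Defocus is in Å, underfocus positive,
`df1 ≥ df2` by convention (violations are normalized by swapping and
rotating the angle 90°). A particle's projection defocus is the tilt value
offset by its depth along the beam after the tilt rotation (larger z in the
untilted frame decreases defocus; the sign is arbitrary but consistent with
the simulator).

Per-tilt estimation: radially averaged power spectrum, background = linear
interpolation through its smoothed local minima, defocus by grid-search
correlation against |CTF|², then astigmatism from per-sector defocus via a
cos 2θ least-squares model. The reported fit quality is the sector-resolved
correlation against the final model; estimates below 0.3 are flagged (not
raised). A plain correlation or a 1D peak-prominence statistic cannot
separate astigmatic Thon rings from the best-of-many-defoci chance
correlation of white noise; the sector-resolved statistic separates them by
a factor of ∼5 empirically. This estimator is a documented simplification
(band-limited sectors; no resolution-dependent fit ranges or equiphase
averaging).

## Reconstruction

Direct Fourier inversion: each crop's transform, de-shifted to center the
particle and multiplied by its CTF, is gridded as a central slice (trilinear
spreading) into a complex numerator; CTF² (times any weights) accumulates
into the denominator; the map is `num / (den + w)` with the Wiener constant
`w` = 1% of the mean nonzero denominator (a small-denominator regularizer,
not a sharpening filter). Partial reconstructions are plain sums, so
bundle-wise processing is exact: any grouping yields the same map. Because
float addition is not associative, `merge_bundles` first sorts partials into
a canonical (content-hash) order, making merges bit-identical under input
permutation. Half-sets split particles by id parity. FSC is per-shell
correlation; resolution is the first 0.143 crossing with linear
interpolation between shells.

Exposure weights follow the Gaussian-falloff family
`w_u(k) ∝ exp(−k²/(4·b_u))` with `b_u = b_ref·exp(z_u)` monotone in the
unit's standardized mean score; weights are renormalized to sum to one over
units at every frequency, and all-equal scores give exactly uniform weights.
`b_ref = 0.03 Å⁻²` makes an average unit's falloff equivalent to a ∼33 Å²
B-factor envelope. The functional form is this package's choice; only its
printed properties (normalization, monotonicity, uniform limit) are treated
as contracts. A mean curve over the whole dataset can stand in when a tilt
series has too few particles for stable per-unit scores.

## Video frames

Per (particle, tilt), frames (optionally running-averaged; a centered window
that slides inward at the edges so every output averages exactly `window`
frames) are aligned against the reference reprojection on a bounded integer
shift grid with quadratic sub-pixel interpolation. The noisy trajectories
are then smoothed in closed form by minimizing
`Σ‖raw − s‖² + λ_t Σ‖Δ²s‖² + λ_s Σ_pairs ‖s_p − s_q‖²` (sparse linear
solve per tilt; neighbors are particles within a projection-distance
cutoff — radius-based rather than k-nearest, exposed in the call).
`λ_t → ∞` collapses each trajectory to its best straight line (the second
difference annihilates linear motion). Trajectories are reported relative
to frame 0. Low per-frame SNR triggers automatic window doubling until the
mean raw score clears a floor. Per-frame mean scores over all particles
feed the exposure weighting; frame-aligned, weighted crops drop straight
into the reconstructor.

## Classification

K-class expectation-maximization over class volumes, with the tilt
constraint imposed twice: initialization randomizes whole particles (never
projections) over the seeds, and per-particle occupancies are the
Gaussian-tilt-weighted average (s.d. 6°, centered on the zero-tilt image,
renormalized over the particle's available tilts) of the per-projection
occupancies, so all projections of a particle share one class distribution.
Per-projection occupancies are a softmax of standardized scores using
*global* statistics. Because a softmax is invariant to per-projection score
offsets, the relevant global scale is the spread of the cross-class score
residuals; the raw score spread is dominated by tilt-angle and dose effects
common to all classes and would wash out the class contrast entirely (the
EM then collapses to uniform occupancies — observed, not hypothesized).
Score-based weights are deliberately not used in the occupancy averaging
(they overfit at tomographic SNR), and the full tilt range participates.
Class maps are rebuilt each iteration with occupancy-weighted insertion;
empty classes are reseeded from a random half of the largest class (logged);
everything is deterministic given the seed. Focused classification confines
class-map differences to a soft spherical mask before scoring. The
unconstrained baseline runs the same EM with independent per-projection
memberships; in comparisons its classification unit is the projection
(that is what it classifies), versus the particle for constrained mode.

## Picking

Density convention is dense = dark (an `invert` flag flips it).
Contamination: high-pass, binarize at mean + 3 s.d. of the flipped contrast,
remove components below a voxel floor, fill holes, dilate. Size-based
picking: truncate extreme densities at median ± 5 robust sigmas first
(smoothed gold/ice tails otherwise swamp the local maxima of nearby
particles), Gaussian low-pass with σ = radius/2, local maxima of the
flipped density above median + 2 robust sigmas, outside the mask, greedy
Euclidean minimum separation of one diameter, ordered by strength then
position. Sphere detection is matched filtering with zero-mean unit-norm
spherical-shell kernels over a radius sweep on the standardized volume —
the accumulator equivalent of spherical Hough voting; under pure noise the
response is ∼N(0, 1), so the threshold is in sigma units, with a 10%
relative floor to drop shell-intersection side lobes and non-maximum
suppression at half the minimum radius. Surface sampling is a Fibonacci
lattice at the requested arc spacing with outward radial normals. Particle
cleaning averages per-projection scores, applies an explicit or automatic
(Otsu) threshold — the automatic mode only when the histogram is bimodal by
inter-class variance ratio > 0.75, since a unimodal Gaussian already
scores ∼0.64 on that ratio — then removes the lower-scoring member of any
pair closer than the minimum distance (idempotent by construction).

## Synthetic data

The generator emulates exactly the statistics the pipeline assumes: a smooth
asymmetric multi-sphere phantom (soft tanh edges ∼1 voxel keep it
band-limited; an appended lobe makes the second structural variant), uniform
random orientations, CTF with per-tilt defocus jitter, additive white
Gaussian noise calibrated so signal-variance/noise-variance inside the
particle boxes equals the requested SNR, a dose model
`exp(−k²·B(e)/4)` with B linear in accumulated exposure under a
dose-symmetric acquisition order plus a cos β thickness factor, per-region
shift/angle perturbations ramping with exposure, and per-tilt frame stacks
whose shared drift is a linear term plus a random walk (optional stage
settle). By default each frame is an undamaged shifted copy of signal/F, so
frame sums match tilt-image statistics exactly; optional intra-frame motion
blur (sinc along the drift step) and intra-frame B-factor damage reproduce
the bell-shaped per-frame score curve of real videos when enabled.
Everything is deterministic for a fixed seed, and ground-truth tables round
trip through the text formats.

Particles are placed with a minimum 3D separation and a projected-separation
constraint checked over the central tilt range (|β| ≤ 40°), because crops of
overlapping neighbors corrupt every scoring benchmark; overlap at extreme
tilts is left in, as it is unavoidable in real data under the cos β
footprint compression. In the picking generator, contamination blobs are
placed first and particles are kept clear of them — contamination physically
displaces particles.

What the synthetic data does not emulate: structured (pink/ice) background
noise, fiducial-marker residuals, alignment errors of the tilt series
itself, non-rigid particle flexibility, or atomically realistic density.
Passing benchmarks therefore demonstrate the estimators' correctness and
statistical efficiency under the stated model, not end-to-end performance
on any particular real specimen.

## Problem sizes and defaults

The standard refinement benchmark uses a 64-voxel particle box at 2 Å/px,
41 tilts (−60°…+60°, 3° steps, dose-symmetric order), 50 particles at
SNR 0.5, refinement at 2× binning over a 100–9 Å band; classification uses
the 32-voxel phantom, 21 tilts, 200 particles at SNR 0.2; frame benchmarks
use 12 particles, 13 tilts, 8 frames. These sizes keep each benchmark in
the minutes range on a single CPU while leaving the measured recovery well
clear of its bound.

## Known limitations

Tilt-series alignment itself (fiducial or patch tracking) is out of scope —
the geometry tables are inputs. The CTF estimator is a simplified
single-image version. No ab initio reference generation: refinement and
classification start from a reference or a consensus map. The picking
suite handles spherical surfaces, not general membranes. Execution is
single-process; the bundle driver provides the storage/merge semantics of
parallel processing, not a scheduler.
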