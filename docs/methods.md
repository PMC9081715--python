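# Methods note

This note records the concrete modeling choices behind each pipeline stage,
including every place where the implementation instantiates a method that
published descriptions leave under-specified, and the conventions that
affect numerical results.

## Coordinate conventions

World space is RAS millimetres (anterior = +Y, superior = +Z); voxel
indices are 0-based; the default affine is diagonal with the centre of
voxel (0,0,0) at half a voxel from the origin. Masks are nearest-neighbor
on the DWI grid. These conventions are load-bearing for the
anterior–posterior centroid ranking.

## Synthetic phantom

**Acquisition.** 90 gradient directions split 30 per shell over
b = 1000/2000/3000 s/mm² plus 6 b0 volumes at 1.25 mm isotropic
resolution. Each shell is a seeded random rotation of a spherical
Fibonacci point set, giving near-uniform coverage with a guaranteed
same-shell pairwise dot product < 0.995.

**Geometry.** Five "pathway" tubes (trunk, arm, hand, face, tongue;
medial→lateral, laterally placed patches slightly more anterior) descend
from distinct cortical label patches, merge at mid-height into one compact
stem that pierces a box-shaped internal-capsule (IC) slab and terminates at
an ellipsoidal subthalamic (STN) target. An orthogonal "crossing"
distractor tube intersects the fan at the level of the straight limbs, with
a crossing angle ≥ 45° in every shared voxel. Centerlines are clamped
cubic splines through the control points with an exactly shared stem
segment.

Two deliberate construction details make the phantom's somatotopy property
(segregation at the fan level, overlap in the stem) hold at the voxel
level:

- **Funnel flow.** Inside the stem, each voxel's tangent points toward the
  stem axis with a convergence length `flow_h`
  (`t ∝ [axis_xy − xy, −flow_h]`), so streamline offsets decay as
  `exp(−Δz / flow_h)` on the way down instead of being parallel-transported.
  Without this, each fascicle would occupy a frozen parallel lane inside
  the stem and never intermix.
- **Axis snapping.** The stem axis (merge point, stem bottom, STN centre)
  is snapped to the nearest voxel centre. A stem axis on a voxel boundary
  makes laterally symmetric fascicles quantize onto opposite neighboring
  voxels all the way down, which produces spurious zero overlaps.

**Rasterization.** Every voxel centre within a tube radius of a
centerline receives that tube's local tangent as a compartment. Because
the five pathway tubes share the stem, tangents within 15° of each other
(sign-invariant) are merged into a single fiber population before the
≤ 3-compartment cut; if more than three populations remain, the three
largest are kept and a warning is logged. Bundle voxels carry a total
anisotropic fraction of 0.7 split proportionally to membership.

**Signal.** Ball-and-stick forward model
`S = S0·[(1−Σf_i)·exp(−b·d) + Σ f_i·exp(−b·d·(g·v_i)²)]` with shared
diffusivity d = 1.7×10⁻³ mm²/s and S0 = 1000. Noise is Rician
(magnitude-MR convention) with σ = S0/snr; `snr = inf` returns the
closed-form signal exactly. All randomness is seeded.

## Model fitting

**Tensor.** Log-linear least squares on the lowest shell plus b0s only
(tensor-model validity at high b is poor). Eigenvalues are sorted
descending and clamped at zero before scalar maps;
FA = √(3/2)·‖λ−λ̄‖/‖λ‖ clipped to [0,1]; MD = mean eigenvalue; the DEC map
is |principal eigenvector|·FA with the standard red = left–right,
green = anterior–posterior, blue = superior–inferior convention. Voxels
with nonpositive signal are flagged and zeroed.

**Ball-and-stick.** The published analysis used a Bayesian estimation
procedure; that is substituted here by multi-start bounded nonlinear least
squares (trust-region reflective) over stick counts k = 0…3 with BIC
selection, documented as a design decision — validation rests on parameter
recovery, not posterior shape. Details: stick fractions use a
stick-breaking parametrization so the simplex constraint is enforced by
bounds; initial stick directions come from a non-negative least-squares
fit over a direction dictionary on the outermost shell with 30° peak
suppression; d ∈ [10⁻⁵, 10⁻²]; a residual floor of n·(10⁻⁸·S0)² prevents
BIC degeneracies on noiseless data; a k-stick model must beat the
(k−1)-stick model by ΔBIC > 2. Over a volume, voxels with tensor FA below
a gate (default 0.2) receive a fast vectorized pure-ball fit; the gate can
be disabled.

At SNR 20 with Rician noise the isotropic fraction carries a noise-floor
bias of up to ≈0.12 that is a property of magnitude MR, not of the
estimator; the parameter-recovery suite therefore uses zero-mean Gaussian
noise (clipped at zero) for its noisy arm, while the phantom simulation
keeps Rician noise.

## Model interpolation

Published descriptions cite a data-adaptive kernel regression framework
without restating the algorithm; the concrete instantiation here is:

1. collect voxel models within a support radius (2 × bandwidth) of the
   query position;
2. weight them spatially, `w_j = exp(−‖x−x_j‖²/h²)` with h = 1.0 mm;
3. represent each neighbor stick as a dyadic (outer-product) tensor
   weighted by `w_j·f_i` and cluster the dyadics greedily with a 30°
   sign-invariant angular threshold;
4. retain clusters in decreasing weight until the cumulative weight
   fraction reaches λ = 0.9999 or 3 compartments;
5. each retained cluster yields a stick whose orientation is the principal
   eigenvector of its summed dyadic and whose fraction is its normalized
   weight; S0 and d are weighted means; the ball fraction is the remainder.

An empty neighborhood returns a null model, which the tracker treats as
leaving the data. The dyadic representation makes the whole construction
invariant to stick sign flips.

## Tractography

Bidirectional fixed-step Euler integration, step 0.5 mm. At each step the
model is interpolated at the current point and the stick (fraction ≥ 0.05)
whose sign-resolved orientation minimizes the angle to the incoming
direction is followed. Termination: entering a stop ROI, turning more
than 55° in one step, no eligible stick, leaving the brain mask, or the
step cap. Seeds: 25 per voxel, uniform within each voxel of the M1 and
STN ROIs dilated by one voxel (6-connectivity — the smallest literal
"one-voxel neighborhood"). Both M1 and STN act as stop ROIs; a streamline
is retained only if any of its points falls inside each of the M1, IC and
STN masks (all points, not only endpoints). Duplicates from symmetric
seeding are kept. The integration order (Euler), bidirectional
concatenation, and per-step (not cumulative) angle criterion are
documented design decisions.

## Somatotopy quantification

- Streamlines are assigned exclusively to one fascicle by the label of the
  cortical-side endpoint's voxel (nearest labeled voxel within a 1-voxel
  neighborhood); unassigned streamlines are dropped with a logged count.
- Envelopes are binary voxel masks marking voxels traversed by any
  streamline segment supersampled at ≤ 0.25 mm.
- "Contours" are the filled per-slice envelope masks (Dice on outlines is
  degenerate).
- Analysis levels on the phantom: IC = slab mid-plane, ZI = one slice
  superior to the STN mask top, plus the fan (corona-radiata) level.
- Dice similarity coefficient `2|A∩B|/(|A|+|B|)`, defined as 0 when both
  masks are empty.
- Centroids are means of member-voxel world coordinates; the
  anterior–posterior ranking sorts by descending Y with lexicographic tie
  breaking (ties flagged).
- Std conventions: sample (n−1) std for cross-instance DSC summaries;
  population std for envelope FA/MD statistics.
- The grand mean of a DSC table is the unweighted mean of the 10 per-pair
  means; this convention reproduces the published grand means (0.63 IC /
  0.65 ZI) from the shipped per-pair reference values.

## Reliability

ICC(2,1) — two-way random effects, absolute agreement, single measure —
computed from the ANOVA mean squares
`(MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)`; the form is part of
the API and reported with results. Cronbach's alpha treats raters as the
parallel items, `α = k/(k−1)·(1 − Σ s_i²/s_t²)`, with a 95% confidence
interval by Feldt's F method. Degenerate (zero-variance) tables raise a
dedicated error. Published reliability values are format examples only;
the underlying raw scores are not public, so they are not reproduced.

## Determinism and provenance

A single integer seed drives scheme rotations, noise, multi-start
initialization and seeding; identical configurations yield byte-identical
CSV/JSON outputs. Every run writes a manifest with the package version,
seed, and a SHA-256 hash of the scientific configuration (the output
directory is deliberately excluded from the hash and the serialized
config so runs into different directories remain byte-identical).
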