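# Methods

## The local alignment vector

Collagen and other biopolymer fibers are *axial* data: a fiber has an
orientation α ∈ [0°, 180°) but no direction, so ordinary vector averaging is
meaningless (45° and 225° are the same fiber). The method analyzed here maps
each angle onto the full circle by doubling, θ = 2α, takes the mean resultant
vector (MRV) of the unit vectors at the doubled angles,

    MRV = (1/N) Σᵢ (cos θᵢ, sin θᵢ),

and halves the MRV's angle while keeping its length. The result — the
**alignment vector** — has length in [0, 1] (0 = isotropic, 1 = perfectly
aligned) and an axial angle giving the dominant fiber axis.

The length is identical to the 2-D nematic orientational order parameter μ,
the maximal eigenvalue of the orientation tensor

    A = [[⟨cos 2α⟩, ⟨sin 2α⟩],
         [⟨sin 2α⟩, −⟨cos 2α⟩]],

whose eigenvalues are ±√(⟨cos 2α⟩² + ⟨sin 2α⟩²). `fiberalign` computes μ by
explicit eigendecomposition (`numpy.linalg.eigvalsh`) precisely so it is an
*independent* oracle for the alignment-vector code path; the test suite holds
the two equal to 1e-12 on arbitrary angle sets.

## Quantization

A fiber's contribution to an alignment measure should be proportional to its
length, and extraction software emits both long curvy polylines and short
noise specks. Both issues are handled by quantization: each polyline is
walked by arclength and cut at multiples of the filter length L (default
5 px, configurable), each cut yielding the straight chord between consecutive
samples. Chords are equal-weight samples of orientation; the trailing
remainder < L is dropped (merging it would break equal weighting), and fibers
shorter than L vanish, which is the intended noise filter. For curved paths
the chord is shorter than L while its arclength step is exactly L; the
alternative (chord-length stepping) is not used because arclength stepping is
deterministic, closed-form, and independent of curvature direction.

## Local sampling circles and exclusions

Grid positions sit at 1 + k·s (1-based pixel coordinates) in x and y with
spacing s (default 5 px), giving ⌊(dim−1)/s⌋ + 1 positions per axis — 103 ×
103 = 10,609 on a 512² image. At each position a circle of radius R (default
25 px) collects the quantized segments whose **midpoints** lie inside it
(boundary-inclusive). The midpoint rule is used because it is unambiguous and
weight-preserving for partially overlapping segments.

A cell is excluded, in this priority order, when

1. the circle crosses the image border (it must lie wholly inside
   [1, width] × [1, height]);
2. the circle crosses or lies inside the circular tumor boundary
   (distance from position to tumor center < R_tumor + R) — circles inside
   the tumor contain no matrix, crossing circles mix regions;
3. the circle holds ≤ F segments (valid cells need strictly more than the
   minimum fiber count, default F = 10).

The statuses are mutually exclusive and exhaustive; exclusion counts per
slice are logged so the bookkeeping of ~10⁴ vectors per image is auditable.

Summary statistics pool valid cells of all z-slices with equal weight: the
normalized alignment histogram (bin width 0.05; the source work does not
state a bin width), the **mean alignment** over valid cells (used as the
distribution-shift summary; the source work plots a shift statistic it does
not define, and the pooled mean is this package's stand-in), and the
**strong-alignment ratio** — the fraction of valid cells with alignment
strictly above a threshold (default 0.7). 3-D renderings show only cells
above a visualization threshold (default 0.8) with z magnified ×4.

The circle-radius sweep reports, per radius, the mean alignment over valid
cells, the mean segment count over interior cells (cells passing the two
geometric exclusions), and the valid-cell fraction. The selection heuristic
in `select_circle_radius` — smallest swept radius whose interior cells exceed
the minimum fiber count in ≥ 90 % of cases — is this package's own rule; the
original selection procedure is not specified beyond "choose an optimum".

## Synthetic fiber generators

Both generators produce straight two-vertex fibers and are bit-reproducible
from their seed (`numpy.random.default_rng`).

**Uniform**: n fibers (default 100) of length 40 px in a 512² box, midpoints
uniform, all at a base orientation (default 90°) plus Gaussian angular noise
of standard deviation σ; candidates are rejected until both endpoints lie in
the box. For doubled angles the wrapped-normal resultant gives the
closed-form expectation ρ = exp(−2σ²) (σ in radians) for the alignment
length, the quantitative anchor for the noise-sweep validation.

**Radial**: n fibers (default 500) of length 40 px normal to a quarter-disk
"tumor" of radius 150 px anchored at a box corner (the radius is a
convention of this package; only the geometry, not the value, matters for
the validation). Midpoints are uniform over the quarter annulus between the
tumor radius and an outer radius defaulting to the box size — the largest
quarter circle the box contains — and endpoints must stay inside both the
box and the annulus. On this geometry the angular density of radial
directions is uniform on (0°, 90°), so the *global* alignment at σ = 0 is
2/π ≈ 0.64 pointing along the 45° diagonal (the measured value, ≈ 0.64,
sits slightly above 2/π because the endpoint constraints thin the annulus
edges), while radius-50 circles placed on arcs at tumor radius + 60 and
+ 160 px see ≈ 0.98. This is the heterogeneity that motivates local over
global measurement. Eight such demonstration circles sit at azimuths
11.25°–78.75°; their positions are this package's convention, configurable.

Replica summaries rerun a config with seeds seed + i. Alignment *angles* are
averaged across replicas with the axial circular mean (double, average the
unit vectors, halve) and spread via the circular standard deviation of the
doubled angles; arithmetic averaging of axial angles fails near the 0°/180°
wrap.

What the generators do **not** emulate: curved fibers, fiber-length
dispersion, extraction noise and gaps, intensity-dependent detection, or any
coupling between cell activity and fiber rearrangement. Passing validation
therefore shows the *statistics* behave correctly on known ground truth, not
that extraction artifacts are handled; on real data the quantization filter
is the only noise defense.

## Numerical choices

- Resultant lengths below 1e-9 are treated as exactly 0 and the angle as
  undefined; symmetric inputs cancel only to ~1e-16 in floating point.
- All interfaces use degrees; axial angles are reduced modulo 180 before
  doubling, circular angles modulo 360.
- Image convention: continuous pixel coordinates, origin top-left, y down;
  angles counterclockwise from +x with y negated, so vertical on screen is
  90°. Grid coordinates are 1-based.
- Quantization counts use ⌊total/L + 1e-9⌋ so exact multiples of L are not
  lost to accumulated roundoff.
- Angles in the MRV are unweighted; length weighting is achieved upstream by
  the equal-arclength quantization.
- Segment gathering uses a KD-tree (`scipy.spatial.cKDTree`); the
  boundary-inclusive midpoint rule is preserved.

## Finite-sample behavior of the noise validation

The closed form ρ = exp(−2σ²) is the N → ∞ limit. The sample resultant
length R̄ of N angles is positively biased: E[R̄²] = 1/N + (1 − 1/N)ρ²
exactly, so E[R̄] has a floor of order √(π/4N) ≈ 0.089 at N = 100 even for
isotropic data, and a first-order bias ≈ (1 − ρ²)/(2Nρ) near concentration ρ.
Consequences for the validation design, at the reference conditions of 100
fibers × 100 replicas:

- Unit tests compare the replica mean against the finite-sample expectation
  √(1/N + (1 − 1/N)ρ²) (exact in the second moment; the Jensen gap is below
  the Monte-Carlo resolution for σ ≤ 40°). At σ = 60° the bias
  (≈ 0.024) exceeds three standard errors of the replica mean (≈ 0.018), so
  a literal comparison of the raw mean against exp(−2σ²) there fails for
  reasons intrinsic to the estimator, not to the implementation; the
  acceptance suite keeps that literal check and it is expected to fail.
- The true replica-mean curve is strictly decreasing in σ, but beyond
  σ ≈ 70° it flattens at the Rice floor and adjacent means differ by less
  than their own Monte-Carlo noise. Monotonicity is therefore asserted with
  a 3·SE(difference) allowance per adjacent pair — a statistical-test
  necessity, not a weakening of the monotonicity claim.

## Problem sizes used in validation

Simulation-based checks use the reference conditions throughout: 100
replicas; 100 fibers (uniform) or 500 fibers (radial) of length 40 px in a
512² box; noise sweeps over 0–100° in 5° steps (21 levels). The
field-analysis tests run full 512² grids (10,609 cells) where the grid count
itself is under test and smaller boxes elsewhere.

## Known limitations

- Tumor boundaries must be circles (per z-slice); complex boundary
  geometries and automated boundary segmentation are out of scope.
- Fiber extraction from raw images is consumed, not performed; the MAT
  importer targets the CT-FIRE vertex-list layout and refuses unknown
  layouts rather than guessing.
- The analysis is per-slice 2-D; the "3-D" output is a stack of 2-D vector
  fields, with no through-plane orientation component.
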