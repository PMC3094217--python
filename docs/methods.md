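# Methods

`hepatoseg` implements a four-stage semi-automatic pipeline for surgical
planning on abdominal CT: (1) liver segmentation with a slice-propagated
level set whose speed image is derived from a per-slice Gaussian fit,
(2) segmentation of vessels and adipose nodules inside the liver by
mixture-driven region growing, (3) identification of the three hepatic main
branches and the portal vein by overlap tracking, and (4) geometric
partitioning of the liver into the eight Couinaud regions with four
least-squares planes.  A fifth component — the Sliver07-style disparity
metrics with human-anchored scoring — evaluates segmentations and serves as
the fitness of a real-coded genetic algorithm that tunes the level-set
parameters against reference masks.

## Liver segmentation

**Model.**  Two working hypotheses: the liver parenchyma is roughly
homogeneous (its intensities approximately Gaussian), and the liver's veins
and nodules lie mainly inside the organ.  On each axial slice a Gaussian
`K exp(-(g-μ)²/2σ²)` is fitted (Levenberg–Marquardt) to the intensity
histogram of the current seed region; two thresholds

    T_L = μ − σ·√(−2 ln G_L),   T_H = μ + σ·√(−2 ln G_H)

are the abscissae where the unit-amplitude Gaussian equals the tunable
fractions `G_L`, `G_H`.  They parameterise a piecewise-linear speed image

    P(x) = g(x) − T_L   if g(x) < (T_L+T_H)/2,   else   T_H − g(x),

positive inside `[T_L, T_H]`, zero at the thresholds and negative outside,
so the contour expands over parenchyma-like tissue and stops at its
boundary.  The contour is the zero level of a signed-distance field φ
(negative inside) evolved by

    φ_t = −β·P·|∇φ|_upwind + γ·Z·κ·|∇φ|,

with κ the interface curvature and `Z = P⁺/max P` a spatial modifier that
mutes the smoothing force where `P` fades (near the boundary, where detail
must be preserved).  No advection term is used: liver boundaries cannot be
told apart reliably from neighbouring structures, so there is no robust
feature for an edge-attraction force.  Propagation runs superiorly and
inferiorly from the user-initialised slice, seeding each slice with the
previous result; per-slice 2D hole filling merges fully interior vessels
and nodules into the organ.  A direction terminates at the volume end or
when the contour vanishes — beyond the liver the seed region covers
heterogeneous abdominal tissue, the Gaussian fit collapses onto one texture
phase, most of the seed falls outside `[T_L, T_H]`, and the fragmented
contour is removed by the curvature force.

**Parameters** (defaults are the reference values found by the genetic
search; intensities in the exam's native units, lengths in voxels):

| parameter | default | meaning |
|---|---|---|
| `min_rms` | 0.0209 | convergence threshold on the RMS change of φ per iteration |
| `G_L` | 0.3859 | Gaussian fraction defining `T_L` (≈ μ − 1.38σ) |
| `G_H` | 0.2809 | Gaussian fraction defining `T_H` (≈ μ + 1.59σ) |
| `beta` | −5.1929 | propagation weight; the solver uses its magnitude with the convention that positive propagation expands where P > 0 |
| `gamma` | 217.414 | curvature (smoothing) weight |
| `max_iterations` | 500 | per-slice safety cap |

**Numerics.**  Explicit upwind (Godunov) scheme; central-difference
curvature clamped to ±1/voxel; time step `0.45/(|β|·max P + γ)` (CFL-safe);
signed-distance reinitialisation every 20 iterations; active band ±6
voxels.  Three numerical choices deserve explanation:

* *Shrink-speed clamp.*  Outside the parenchyma range |P| grows without
  bound (air is hundreds of units below `T_L`); clamping `P ≥ −max P` keeps
  the time step on the scale of the motion that matters instead of letting
  one extreme voxel freeze the whole front.
* *Windowed convergence test.*  The RMS change per iteration is measured
  over the interface layer (|φ| ≤ 1) across a 10-iteration window.  A
  single-step RMS cannot distinguish the grid-scale flicker of an explicit
  scheme at a stalled boundary from genuine slow front motion; the window
  averages the flicker to zero while steady advance accumulates.
* *Minimum area.*  A contour below 4 voxels cannot support a discrete
  signed-distance representation and counts as vanished.

The solver is exactly equivariant under a constant intensity shift: all
fits run in mode-anchored abscissae and each slice is processed in
seed-anchored intensities, so a shifted exam yields a bitwise-identical
mask.  There is consequently no intensity windowing or rescaling anywhere.

**Operating regime.**  Because the curvature weight is large relative to
the propagation scale, the front cannot squeeze through gaps narrower than
roughly `γ/(|β|·P_typ)` ≈ 3 voxels.  Slice-to-slice seeding only requires
one-to-two-voxel adjustments per slice, so this matters little in normal
operation, but two consequences are worth knowing: recovery from a far-off
seed arrests early (the user contour should cover most of the liver, which
is also what the method asks for), and an *exactly* uniform region (zero
variance, giving a degenerate single-bin histogram) cannot be expanded into
at all, because the floored fit width (one histogram bin) produces a
propagation force below the curvature force.  Real parenchyma always
carries noise on the scale of ten or more units, where the balance is
strongly in favour of propagation.

## Mixture model and region growing

The histogram of the voxels inside the segmented liver is modelled as a
three-Gaussian mixture `H = G_l + G_c + G_r` (nodules, parenchyma,
vessels), with the centre assumed dominant and side classes separated from
it by at least three of its standard deviations.  Estimation is stepwise:

1. `H_c(x) = min[H(x), H(2·x_max − x)]` symmetrises the histogram about its
   mode; `G_c` is fitted to `H_c`.
2. The left (nodule) component is fitted to the residual `H − G_c` kept
   below the mode, mirrored about its own maximum with a pointwise maximum.
3. The right (vessel) component is fitted the same way to what remains
   above the mode.
4. A joint least-squares refinement polishes the present components.

Two implementation choices: the residual in steps 2–3 subtracts the
*fitted* `G_c`, not the symmetrised `H_c` — the pointwise minimum absorbs
any side bump whose mirror position also carries counts, which would cancel
both side classes when the nodule and vessel means happen to sit nearly
symmetrically about the parenchyma mean; and residual counts within 3σ of
the fitted centre are muted before the side fits, because they are
dominated by symmetrisation and sampling noise (scale √K_c), not by the
side classes the model assumes to be separated.  The joint refit is
accepted only if it improves the fit without moving any component's mean
off its stepwise estimate (beyond 3σ or 3 bins); Levenberg–Marquardt is
tried first and a bound-constrained trust-region solve of the same
objective serves as a fallback candidate.  A side component is declared
absent when its amplitude falls below 1% of the centre amplitude or fewer
than three residual bins support it; this floor is calibrated for
exam-scale voxel counts (10⁵–10⁶) and can misread sampling noise as a
class on very small volumes.

Region growing uses two thresholds per side: seeds are voxels beyond the
intensity at which the side class holds at least 70% of the side+centre
density (found by grid scan refined by bisection to 10⁻³ bin); growth
accepts any 26-connected neighbour beyond the intersection abscissa of the
two components (the root of the log-equality quadratic strictly between the
means, with a grid-scan fallback).  Growing is restricted to the liver
mask and implemented as one connected-component labelling of the
acceptance set — the fixed point of iterated dilation-and-mask.  Only
hypodense (adipose) nodules are segmented.

## Vein identification

Hepatic main branches are tracked without bifurcation analysis: starting
from the most superior slice containing unprocessed vessels, the largest
2D component seeds a candidate that absorbs, slice by slice inferiorly, the
component with the largest footprint overlap; a candidate spanning more
than 15% of the liver height (both in mm, so anisotropic spacing is safe)
is accepted, and every processed candidate is removed from future seeding,
guaranteeing termination.  Accepted branches are labelled right / middle /
left by the clockwise order of their coronal-projection centroids about the
thorax axis (approximated by the liver centroid; anterior view, 12 o'clock
superior, patient right at negative x).  The portal vein is the largest
connected component of the remaining vessels; all other residual components
merge into a touching branch or become auxiliary, so the vessel voxels are
conserved exactly.

## Couinaud partitioning

One near-vertical plane (`x = a·y + b·z + c`) is least-squares fitted to
each hepatic branch and one near-horizontal plane (`z = a·x + b·y + c`) to
the portal vein; the parameterisation itself enforces the orientation
class.  The three vertical planes, ordered right to left by mean predicted
x over the liver, define four slabs; the portal plane splits each slab into
superior/inferior, giving the eight regions (VII/VI, VIII/V, IVa/IVb,
II/III from right to left).  Ties on a plane go deterministically to the
right/inferior side.  This is the plane-bounded reading of the Couinaud
scheme: the caudate lobe (segment I) is drained by the cava vein and cannot
be isolated by four planes; the medial-superior slab approximates it only
loosely.

## Evaluation metrics and scoring

Five disparity metrics compare segmentation and reference: volumetric
overlap error (percent), signed relative volume difference (percent), and
the average / RMS / maximum symmetric surface distance (mm) between
border-voxel centres (border = mask voxel with a 6-neighbour outside; no
sub-voxel surface).  VOE is implemented in error form, `100·(1 − |A∩B|/|A∪B|)`.
Each metric maps to a score `max(0, 100 − 25·|error|/e)` anchored on the
mean human expert error `e` for that metric — 100 for a perfect match, 75
at human-level disagreement, linear in between and clamped at zero.  The
human-error constants are configuration: they belong to the evaluation
campaign, not to the method, and must be supplied explicitly.  The total
score is the mean of the five.

## Genetic parameter search

Each individual carries the five level-set parameters as genes; its fitness
is `F = 100 − S`, where `S` is the total score of its segmentations against
the references aggregated over exams by mean (or minimum), so minimising F
maximises agreement.  The scheme: uniform initialisation in per-gene
ranges; fitness-proportional selection with single-individual elitism;
arithmetic crossover; Gaussian mutation (σ = 5% of range, clipped);
a steady-state fraction of the best individuals carried over unchanged.
Defaults follow the reference configuration — 30 generations × 30
individuals, crossover 0.8→0.65, mutation 0.1→0.8, steady state 0.8→0.2,
all linearly interpolated; two sequenced experiments, the second seeded
with 10% copies of the first's best.  Default gene ranges widen the regimes
in which the parameters are known to behave well: min RMS [0.005, 0.05],
`G_L`/`G_H` [0.1, 0.7], |β| [0.5, 50], γ [0, 1000].  Fitness values are
cached by rounded gene tuple, since the level-set fitness is expensive and
the GA revisits genotypes.

## Synthetic phantom

The phantom emulates the statistical structure the method assumes, at the
default study resolution 96×128×128 voxels with 2×1×1 mm spacing:

* an ellipsoid-like liver (mild sinusoidal lobulation) with parenchyma
  100 ± 15 (arbitrary CT-like units);
* three bright (160 ± 10), near-vertical, slightly bowed and tilted tubes
  spanning ~60% of the liver height (the bow keeps the plane fits
  well-posed — voxels of a perfectly straight tube are nearly collinear);
* a near-horizontal bright portal trunk through mid-liver, strictly
  intraparenchymal so that hole filling can recover it;
* two short bright fragments (~8% of liver height) as distractors for the
  branch-height rule;
* two dark (40 ± 10) spherical nodules of radius 10 mm;
* a surrounding "body" of fine-grained two-phase soft tissue (20 ± 6 /
  70 ± 6, patch scale 1–2 voxels) with air at 0 outside it.

The textured body is essential, not decorative: a liver bordered by a
*uniform* background hands the per-slice Gaussian fit a histogram delta
that out-peaks the parenchyma at the liver ends, and the propagation never
vanishes.  Fine-grained heterogeneous surroundings — what real abdomens
provide — are the method's actual stop mechanism, and the patch scale is
deliberately below the front's curvature-arrest radius.  Additive scanner
noise defaults to zero because each tissue class already carries its own
spread.

Stress presets reproduce the two documented failure modes of the
single-Gaussian parenchyma heuristic: `peripheral-nodule` places a dark
nodule straddling the liver border (excluded from the result, because hole
filling cannot reach a boundary-touching structure) and `big-nodule`
grows a 30 mm nodule (≈17% of the liver) next to an external dark
structure (the bimodal histogram widens the fitted thresholds and the
contour leaks out of the organ).  A nodule that large displaces the
synthetic vein tree rather than avoiding it, as large real lesions do.

**What passing on the phantom does and does not show.**  The phantom has
exactly Gaussian tissue laws, sharp boundaries, no partial-volume effect,
no bias field, no contrast-phase variation, and its vessels are strictly
interior tubes.  Results on it validate the machinery — threshold
derivation, propagation and stop rules, mixture decomposition, tracking
geometry, plane fitting, scoring — not clinical accuracy on patient CT,
which requires contrast-enhanced exams and expert references.  Published
results on the Sliver07 benchmark are not reproducible here because that
dataset and its multi-observer references are not redistributable.

## Problem sizes used in the tests

The test suite and the acceptance script run the full pipeline at the
default 96×128×128 resolution (a single liver segmentation takes a few
seconds), use 48×64×64 or 64×96×96 scaled scenes for structural checks
where absolute scale is immaterial, 12³ random masks against the
brute-force metric oracle, n = 200 000 multinomial draws for mixture
recovery, and the full 30×30 GA configuration with a surrogate quadratic
fitness for search-recovery checks.  Smaller scenes are chosen where the
property under test is scale-free; quality bounds (Jaccard ≥ 0.90) are
asserted at the default resolution, since the curvature-arrest radius
(~3 voxels) is a fixed physical length of the tuned parameters and small
grids distort its ratio to organ size.

## Known limitations

* The five tuned defaults come from contrast-enhanced CT; other protocols
  need retuning (the GA module exists for exactly that).
* The per-slice fit assumes the seed region is mostly liver; a grossly
  wrong initial contour arrests or leaks (see operating regime above).
* With additive noise on a *flat* background the end-of-organ stop rule
  weakens, since the noise forms a fittable Gaussian; heterogeneous
  surroundings are required, as in real exams.
* Exactly three hepatic branches are assumed (the dominant anatomical
  variant); fewer accepted candidates are returned with a warning and
  labels assigned in clock order.
* Planes are flat; real intersegmental boundaries are curved, and segment
  I is only approximated by the medial-superior slab.
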