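# Methods

This note records the models, numerical choices and known limits of each
stage, in the package's own terms. Units throughout: nm for images and
polymers, Å for reaction coordinates, kcal/mol for energies, degrees for
angles, k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹, default temperature 300 K.

## Synthetic molecules and fields

Surface-deposited DNA is modelled as a fully 2D-equilibrated worm-like
chain: the tangent angle performs a Gaussian random walk with per-step
variance `rise/P`, giving the 2D tangent correlation
⟨cos Δθ(s)⟩ = exp(−s/2P) and mean-square end-to-end distance
4PL − 8P²(1 − e^(−L/2P)) for a chain of contour L and (3D-defined)
persistence length P. Defaults: rise 0.30 nm/bp (the calibration observed
for DNA equilibrated on mica, ~10% below the 0.34 nm B-DNA value, which
absorbs projection and deposition effects) and P = 50 nm
(literature-typical). A protein-induced kink is the sharpest possible
model — a single discrete tangent rotation at one position, its angle
drawn from a discrete mixture of bending states, its sign random.

Fields are rendered at 512 × 512 px and 3.9 nm/px by default. Molecules
are placed with random rotation and translation, rejecting placements
that overlap previously placed molecules within a 3-px clearance (up to a
retry limit; total failure is an error naming the offending molecules).
The DNA ridge (apparent height 0.5 nm) and a protein disk (2.0 nm, radius
1.2 px) are max-composed onto the canvas, blurred by a Gaussian tip PSF
(σ = 3 nm), then per-scan-line offsets (σ = 0.02 nm), pixel noise
(σ = 0.05 nm) and optional scar rows and globular artifacts are added.
The apparent heights are generator conventions chosen so the
protein-higher-than-DNA peak heuristic holds, as it does in real imaging;
they are exposed as configuration. The ground truth records every placed
backbone, kink state and angle, scar row and artifact, and round-trips
through JSON.

Not modelled: tip–sample mechanics, real poly-L-lysine chemistry, 3D→2D
projection kinetics, atomistic geometry. Passing recovery tests on these
fields therefore demonstrates correctness of the measurement chain, not
robustness to every artifact of real AFM data.

Umbrella windows are drawn *exactly* from the biased Boltzmann density by
inverse-CDF sampling on a 10⁴-point grid per window. This deliberately
removes the autocorrelation a Langevin sampler would add, so WHAM errors
measure the estimator, not the sampler. Toy conformational ensembles
require family RMSDs > 10× the noise so that label recovery is
well-posed. Sequence backgrounds are i.i.d. with a requested AT fraction;
IUPAC codes in planted motifs resolve uniformly over their allowed bases.

## AFM image stage

Flattening: per scan line, a first-order polynomial is fitted against
background pixels (lower 75% by height, then a 3σ-residual refit) and
subtracted; a global second-order surface fitted the same way removes
bow; scar rows (deviation from both neighbours > 5 robust σ over ≥ 10
consecutive pixels) are repaired by interpolation across rows; the
background median is shifted to zero.

Segmentation: the automatic threshold is Otsu's value floored at
3 robust σ above the background median — on sparse fields the height
histogram is dominated by substrate noise and Otsu alone lands inside
the noise. Isolated specks (≤ 2 px) are dropped, one binary-closing pass
repairs single-pixel dropouts in thin ridges, and components smaller
than 6 px are ignored. Each component is skeletonised; the skeleton
pixel graph (8-connected, edge weights 1/√2 px) is pruned to the longest
endpoint-to-endpoint path; closed loops are skipped and components with
more than 4 endpoints are flagged as aggregates. Thinning erodes roughly
half a ridge width per molecule end, so path ends are extended along
their local direction while foreground continues (≤ 3 px). Trace points
are raw pixel centres (spacing 1 or √2 px) in nm; ordering starts from
the endpoint with the smaller (row, col).

Bend angle: the peak i is the highest point along the contour (ties →
smallest index); a 3-px window {i−1, i, i+1} is excluded and the arm
vectors span the next 4 path points either side, θ = angle between them,
0° = straight. Two refinements keep this heuristic accurate on pixel
grids without changing its 16-nm spatial scale:

- sub-pixel positions: every skeleton node is assigned the
  height²-weighted centroid of its 5 × 5 neighbourhood (clamped to 1 px).
  The PSF-blurred ridge localises the centreline well below the pixel
  size, removing the ±5–7° quantisation noise of raw 4-px chords.
- vertex anchoring for folded molecules: past ~120° of bend the two arms
  merge near the apex into one thick region whose skeleton runs along
  the bisector, and path points adjacent to the peak lie on neither arm.
  For image-derived traces the two arm chords are therefore anchored at
  the sub-pixel apex (the protein sits exactly on the kink vertex) and
  their far points taken 5 steps past the node where the two longest
  skeleton branches diverge. For straight arms this is exact at any fold
  angle and reduces to the plain path heuristic for open molecules.
  Hand-built polyline traces (no skeleton graph) use the pure
  path-index formula.

With these choices, planted kink angles across 40°–160° are recovered
with ~2–3° median absolute error on default fields and straight
molecules read ~2.6° median. Recovery at this precision holds for
molecules rendered with straight (infinite-persistence) arms; with
thermal arms at P = 50 nm the tangent direction itself fluctuates by
~30° (sd) over a 16-nm arm, so the per-molecule angle is dominated by
real polymer fluctuations rather than measurement error — that is a
property of the molecule, not the estimator.

The 50% contour-length filter keeps traces in [0.5·L, 1.5·L] inclusive.
Cluster volumes use the zero-basis convention: Σ max(h, 0)·px² per
labelled cluster, clusters below 6 px dropped.

## Bend-angle mixture

Angles live on [0°, 180°], so every Gaussian — the frozen background
shape and each mode — is truncated to that interval and its bin masses
renormalised; reported (μ, σ) are the untruncated parameters. The
background shape is the truncated-Gaussian MLE of the bare-DNA sample;
in the joint fit only its weight w₀ is free. For m = 0..max modes, the
10° histogram of the protein-present sample is fitted by least squares
with σ = √max(observed, 1), multi-started from histogram local maxima
(ties broken by angle order) plus an evenly spaced fallback; bounds
w ∈ [0,1], μ ∈ [0°,180°], σ ∈ [2°,60°].

Order selection: the primary criterion is the smallest m whose
goodness-of-fit p-value exceeds 0.99. Under honest Poisson sampling the
true model has E[χ²] ≈ ν and p ≈ 0.5, so the strict criterion rarely
fires; the fallback (flagged in the result) picks the smallest
statistically acceptable order (p > 0.05), and failing that the order
with the largest p. This makes background-only data select m = 0 and
well-separated 3-mode data select m = 3.

Estimator precision at n = 2000: narrow modes (σ ≈ 7–9°) recover to
~1°, weights to ~0.02. A broad mode (σ = 30° near the 180° boundary)
recovers its mean only to ~4–5° median — the histogram likelihood is
nearly flat along a (μ, σ, w₀) ridge, and the fitted optimum routinely
has lower χ² than the true parameters, so this is an identifiability
limit of the data size, not an optimisation failure.

Goodness of fit merges adjacent bins until every expectation is ≥ 1 and
uses ν = bins − free parameters. State proportions renormalise the mode
weights over bound molecules only (the background weight is excluded); a
flag on the pipeline could renormalise over all molecules instead, but
bound-only is the default reading.

## Trajectory geometry

The helix axis is the centred 11-point (one helical turn) moving average
of base-pair centres, the window shrinking at the ends — a documented
surrogate for full helical-axis contouring, accurate to ~0.1 nm RMS on
ideal helices but not identical to algorithms that fit local helical
frames. Planarity is 100 × RMS out-of-plane distance / R_g of the axis
(the denominator is a convention; it is configurable). The two-vector
bend angle uses vectors joining axis points `span` bp apart separated by
`gap` bp centred on the site (defaults 30/30), 0° = straight. Kabsch
RMSD excludes reflections. Clustering is average-linkage agglomeration
on the pairwise RMSD matrix cut at k clusters, labels renumbered by
first frame occurrence and representatives chosen by minimum mean
intra-cluster RMSD, making the output deterministic. Hydrogen bonds use
donor–acceptor distance ≤ 3.5 Å and D–H···A angle ≥ 120° (both
boundaries inclusive, with a 10⁻⁹ float guard); per-frame per-residue
counts are capped at 1 so the time average is an occupancy. A standard
polar donor/acceptor atom-name table ships in the module and is
overridable. The default clustering selection in atomistic use is DNA
phosphorus + protein Cα, exposed as a selection argument.

## Free-energy reconstruction

WHAM iterates the standard self-consistent equations on a shared bin
grid (default 0.2 Å) until the largest window free-energy shift changes
by < 10⁻⁶ kcal/mol (max 10⁵ iterations; non-convergence is an error
with the iteration count). No periodicity and no autocorrelation
correction — the synthetic samples are i.i.d. by construction. Adjacent
windows sharing no occupied bin trigger a warning naming the gap. The
PMF is −k_BT ln of the unbiased density, zeroed at its minimum; empty
edge bins are trimmed and interior gaps stay +∞ so the grid remains
uniform.

Coordinate remapping fits x′ = a·x + b by least squares over paired
(raw, target) observations (for windows, the spring constant transforms
as k′ = k/a² so bias energies are preserved). Offset alignment shifts
one PMF so both agree in mean over the unbent-state plateau.

The 2D landscape interpolates each arm's PMF between its bound and
held-away conditions using the *other* arm's coordinate:
λ = clamp((x − x_bound)/(x_away − x_bound), 0, 1), with anchors at the
bound-state minimum and the held-away threshold (configuration values,
~34 Å and 40 Å in the two-arm wrapping geometry); F(x_L, x_R) is the sum
of the two arm terms. P = exp(−F/k_BT) is normalised over the grid
(per-cell probabilities sum to 1; the matching density integrates to 1).
State probabilities give each grid cell per-state weights from the
states' 2D point histograms at grid resolution, normalised per cell
(winner-takes-all behind a flag), then integrate P against the weights
and renormalise to 100%. ΔF between regions is −k_BT ln(ΣP_b/ΣP_a).
Error bars (e.g. bootstrap over windows) are future work.

## Motif scanning

Scores are log₂ odds with pseudocount-padded frequencies
((count + pc·background)/(total + pc)). The exact null distribution of
W_s under the i.i.d. background rounds per-position scores to a 0.01-bit
lattice and convolves the four-outcome distributions; the worst-case
rounding error of a total score is width × 0.005 bits, and the exhaustive
enumeration oracle in the tests checks the distribution to 10⁻¹² total
variation for widths ≤ 6. p(s) = P(W ≥ s) is right-continuous and
nonincreasing; queried scores snap to the nearest lattice point.
Scanning covers both strands by default (the consensus is not
palindromic), reports reverse-strand hits at forward 0-based half-open
coordinates, skips ambiguous-base windows with a counted log message,
and applies p ≤ 0.0002 and/or W_s ≥ 1 thresholds. The background
defaults to uniform 0.25 per base and accepts genome composition.

## Problem sizes and determinism

The test suite and the acceptance script use ≥ 200 kinked molecules
across five planted angles plus 60 straight molecules per run, n = 2000
angle fixtures, 6 umbrella windows × 10⁴ samples, 45-frame toy
trajectories and 1-kb scan sequences — sizes at which every recovery
statistic is stable yet a full run takes about a minute on one CPU. All
generators accept a seed or generator object; pipeline reports contain no
timestamps or absolute paths and are byte-identical under a repeated
seed.

## Known limitations

- The AFM stage measures one angle per molecule and does not attempt
  protein/DNA discrimination beyond the height-peak heuristic, sub-pixel
  spline re-tracing, or multi-protein molecules.
- Above ~160° of bend at 3.9 nm/px the two arms of a folded molecule are
  unresolvable over most of their length; traced contours shorten and
  some molecules fail the length filter or the arm-length requirement
  and are excluded from angle statistics rather than mis-measured.
- The mixture decomposition assumes modes are (truncated) Gaussians and
  the background shape is condition-independent.
- WHAM is 1D only; genuinely 2D-biased sampling and replica exchange are
  out of scope.
- The helix-axis smoothing is a moving-average surrogate, adequate for
  bend angles at the 30-bp scale but not for local helical parameters.
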