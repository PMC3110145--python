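# Methods

`omtgrid` grids single-channel cDNA microarray scans fully automatically:
it locates the separating lines between sub-grids (the blocks printed by
one pin) and then between the spots inside each sub-grid, without being
told the number of sub-grids, the number of spots, the spot size, or the
rotation of the slide. This note describes the model behind each stage,
the choices that were genuinely open, and what the synthetic evaluation
does and does not demonstrate.

## Image model and coordinates

A scan is a matrix `A = {a_ij}` of nonnegative integers (16-bit scanner
units); rows are the image y-axis. All coordinates are 0-based and
intervals half-open; a separating line at coordinate `c` is the boundary
between pixel rows/columns `c-1` and `c`. A layout with `p` sub-grid rows
is described by exactly `p-1` horizontal lines, and the cells induced by
the lines tile their bounding rectangle exactly — geometry can therefore
be serialized and compared without ambiguity.

## Rotation adjustment

Printing and scanning tilt the grid by up to tens of degrees, and the two
structure directions (spot columns and spot rows) need not be tilted by
the same angle (a shear). Each angle is estimated from Radon projections:
the image is rotated by a candidate angle, summed along an axis, the
profile normalized to a distribution, and its Shannon entropy computed.
When the grid structure aligns with the axis the projection concentrates
into sharp peaks separated by deep valleys and the entropy is minimal.

Numerical choices:

* Coarse sweep ±30° in 0.5° steps (one rotation per angle serves both
  axes), then per-axis refinement ±0.5° in 0.05° steps. The sweep runs on
  a block-mean downsampled (≤1024 px), mean-subtracted, zero-clipped
  working copy; the raw image is what finally gets resampled.
* The reported angle is the vertex of a quadratic fitted to the fine
  sweep, not the raw argmin: the curve bottom is locally noisy at the
  0.05° scale (wiggles of a few 0.001 nats), and a single-point argmin
  carries ~0.1° of noise — enough residual tilt to displace lines by a
  pixel at the far edge of a large canvas. The vertex is repeatable to
  better than 0.01°.
* Every candidate rotation is central-cropped to a fixed window — the
  axis-aligned rectangle inscribed in the frame at the *largest* scan
  angle — before projecting. Without this, the zero padding of rotated
  canvases systematically lowers the entropy at extreme angles and the
  sweep locks onto the search boundary.
* An axis whose entropy curve is essentially flat (median − min < 0.01
  nats) carries no structure; its angle is reported as exactly 0 rather
  than the argmin of noise. Real grid images show drops of 0.5–1.5 nats,
  four orders of magnitude above the flat-curve wiggle.
* The correction is a single inverse-mapped affine resample (bilinear)
  whose matrix columns are the two measured structure directions; for
  equal angles this is exactly the inverse rotation, for differing angles
  the corresponding shear composition. Out-of-domain pixels are filled
  with the image's 1st-percentile intensity. Estimates with both angles
  ≤ 0.2° are treated as exactly zero, so an unrotated image passes
  through bit-identical.

## Optimal multilevel thresholding

Row (or column) sums of the rotation-corrected image form a positional
histogram on bins `1..n`, normalized to probabilities `p_i`. A set of `k`
interior thresholds `t_1 < … < t_k` splits the bins into `k+1` contiguous
classes; the between-class variance criterion

    Psi_BC(T) = sum_j omega_j * mu_j^2

(`omega_j` class mass, `mu_j` mass-weighted mean position; a zero-mass
class contributes 0) is maximized exactly by dynamic programming on
prefix sums, O(k·n²) time and O(k·n) memory, with each class score
evaluated in O(1). One DP run yields the optima for *every* k up to the
search bound, which is what makes the model-selection stage affordable.
The kernel is numba-compiled with a pure-NumPy fallback.

Determinism: prefix sums use compensated (Neumaier) summation and scores
are accumulated right-associated, so the DP and the exhaustive
enumeration oracle used in tests agree bitwise. Score ties are resolved
hierarchically — maximize total score, then the smaller `t_1`, then the
larger remaining-suffix score, then the smaller `t_2`, … — because plain
lexicographic minimality is not well defined once rounding can equate the
total scores of partitions whose sub-sums differ by ulps.

Empty last classes are not allowed (`t_k < n`): every class must contain
at least one bin, which keeps the validity indices well defined.

## Choosing the number of classes: the alpha index

Thresholding needs `K` (classes = sub-grid or spot count per axis) as an
input; `K` is chosen by scoring every candidate `K = 2..delta`,
`delta = ceil(sqrt(n))`, with

    I(K)     = ((1/K) * (E_1/E_K) * D_K)^2
    A(K)     = (1/k) * sum_i p(t_i)
    alpha(K) = I(K) / (A(K) + eps)

`I` is the Maulik–Bandyopadhyay cluster-validity index adapted to
weighted 1-D bins (power 2, L1 dispersion `E_K = Σ_k Σ_{i∈ζ_k}
p_i·|i−z_k|` around mass-weighted class centers `z_k`, `D_K` the largest
center separation; zero-mass classes contribute to neither). `A` is the
mean probability at the chosen thresholds — small exactly when the
thresholds fall into empty valleys. `I` alone over-splits (it rewards
cutting a block's internal structure); dividing by `A` suppresses any
partition that has to place thresholds on real mass. `K*` is the argmax
of alpha; ties go to the smaller `K`.

Decisions that were genuinely open:

* `eps` is the profile's *empty-bin level*, `max(P5(p), 1e-12·max p)`
  with `P5` the 5th-percentile probability. With a much smaller eps,
  whichever candidate happens to place a threshold on a bitwise-zero bin
  wins an "eps lottery"; anchoring eps at the valley floor makes
  sub-noise differences between near-empty threshold sets irrelevant
  while leaving the penalty on real mass untouched.
* Each candidate threshold set is canonicalized before scoring by
  centering every threshold in its zero-mass run (all such positions are
  score-equivalent; the DP tie-break returns the run's first bin, which
  hugs the preceding block and would wrongly charge `A` with block-edge
  mass).
* Degenerate dispersions are floored at `1e-12·E_1`.
* No smoothing is applied to the histogram before thresholding or before
  `A` is read off.
* A profile with no pronounced alpha peak (max < 2× median, calibrated on
  flat-noise nulls, where 100/100 seeded realizations stay below the
  bound) is flagged unconfident and treated as "one block, no split" —
  this is how structureless inputs degrade gracefully.

## Profile conditioning

Two operations are applied to a profile before model selection (never to
the raw `intensity_profile`, whose contract stays "plain sums"):

1. **Baseline removal.** Subtract the profile's 1st percentile, clipping
   at zero. Scanner offset plus zero-clipped noise put a pedestal under
   the sums that fills the valleys; published microarray histograms show
   near-empty inter-block valleys, and the pedestal is an artifact of the
   acquisition floor, not of the printed grid.
2. **Support trimming.** Restrict the analysis window to the first..last
   bin holding ≥5% of the conditioned maximum. Wide outer margins (the
   GEO-style layouts have 100+ px of empty border around each block)
   otherwise act as low-mass pseudo-classes that the `I` index is happy
   to split off.

Both steps are parameterless in the method's sense (fixed, data-derived
constants), and both stages — sub-grid and spot — use the same mechanism:
profile → condition → select K → thresholds → lines, per axis,
independently. Detected lines sit on the boundary after their threshold
bin. The spot stage runs inside each sub-grid cell of the (refined)
sub-grid geometry, on the same rotation-corrected image; there is no
per-sub-grid re-rotation.

## Refinement

Each separating line may sit a few pixels off the emptiest position. Every
line is allowed to slide within half the median spacing of its parallel
neighbours (so it can never cross into an adjacent spot row/column),
clamped between its neighbours, and moved to the coordinate whose two
straddling pixel lines sum to the least intensity over the line's bounded
extent. Ties keep the position nearest the original (then the smaller
coordinate), so lines move only on strict improvement; vertical lines are
processed left→right, then horizontal top→bottom, and a second pass runs
only if anything moved. This reaches a fixed point (refinement is
idempotent) and the objective never increases. The two-pixel straddle
makes the objective symmetric in the boundary-line convention; with a
one-pixel objective, perfectly centered lines drift by ±1 px on clean
images.

## Quantification

Within each spot region the spot is segmented by Sobel gradient
magnitude, thresholded with Otsu's criterion via the package's own k=1
thresholding DP on a 128-bin gradient histogram (keeping the stage
parameterless), the closed contour filled, one erosion applied (the
filled contour reaches the *outer* rim of the Sobel band; the erosion
peels it back to the intensity boundary), then a 3×3-cross closing and
opening. A candidate mask whose interior is not at least 1.5× brighter
than its surroundings is discarded as noise — pure-background regions
have gradients too, but no bright interior. The spot *volume* is the
exact integer sum of intensities over the mask; `log2(volume)` is the
expression measurement (undefined and reported missing for empty masks).

For a serial f-fold dilution series, mean log2 volume per step is fitted
against step index by least squares; an exact 2-fold series has reference
slope −1 per step. Steps with no measurable volume are excluded with a
warning. Background subtraction is deliberately out of scope, which
biases late (faint) steps slightly upward; on the synthetic series the
fitted slope is ≈ −0.94 rather than −1.00 exactly.

## Synthetic data: what it emulates

The generator renders three layout presets modeled on published test
suites: `smd` (1910×5550 canvas, 4×12 sub-grids of 18×18 spots, 18 px
spots at 24 px pitch, 30 px sub-grid gaps), `geo` (1900×5500, 4×12
sub-grids of 14×13 spots, 12 px spots at 20 px pitch, 200 px gaps), and
`diln` (2×5 sub-grids of 8×8 spots, 12 px spots, 200/25 px gaps; canvas
derived from the layout, ≈ 604×960). Where the published canvas size and
the published gap distances are mutually inconsistent, the preset keeps
the layout counts and the canvas and derives gaps that fit (SMD), or
keeps the stated gaps and derives the canvas (DILN).

Spots are Gaussian-profiled disks (σ = diameter/4) with per-spot peaks
drawn uniformly from 20 000–45 000, plus a low wide halo (10% of peak,
σ = pitch/2) emulating hybridization glow; both components are rendered
on the spot's cell (box + half-gap ring) and cut there, so inter-sub-grid
gaps stay at background. The halo is essential, not cosmetic: it is what
keeps the valleys between neighbouring spots visibly above the
inter-sub-grid level, the feature the `A` index needs to tell the
spot-scale partition from the sub-grid-scale one — real scans show
exactly this above-background intra-block ripple. Noise is additive
Gaussian (presets: low = 2%, moderate = 5% of the mean peak), clipped to
the 16-bit range over a background offset of 100; a seeded fraction of
spots can be dropped; bright elliptical artifacts can be stamped;
a global rotation is applied with the same bilinear resampling the
rotation module uses. Ground truth (block extents, spot centers and
radii, presence, gap intervals) is recorded pre-noise in the unrotated
frame.

The dilution generator tiles 8 steps across the 8 spot columns with peaks
decaying by exactly the fold per step and constant footprints, so the
*true* volume decay equals the fold (a `shrink_with_step` variant shrinks
diameters down to 3 px for the shrinking-print look; its volume decay is
then faster than the fold by construction).

What the synthetic images do **not** model: donut/comet spot
morphologies, background gradients, channel cross-talk, correlated
(streak) noise, and irregular printing jitter. Passing the synthetic
suites therefore demonstrates the machinery — exact thresholding, count
selection, rotation recovery, refinement, scoring — under controlled
conditions, not performance on any particular scanner's artifacts.

## Line scoring

A detected line is scored against the true spot masks over the line's
bounded extent: crossing a mask interior is *incorrect*; passing within
1 px of a mask without crossing is *marginal*; otherwise *perfect*. The
1 px band is an explicit operationalization of a visual "barely
separates" judgment. Missing lines count as incorrect; surplus lines are
demoted to incorrect (perfect first, then marginal). Percentages are
computed from pooled counts and always sum to 100.

## Problem sizes used in the evaluation

The shipped evaluation runs full-canvas images: 20 SMD-layout images for
sub-grid accuracy, 10 SMD (5% missing spots, moderate noise) and 10 GEO
(low noise) images for spot accuracy, 20 images per layout for count
recovery, a ±5..25° sweep on one image for rotation robustness, and one
8-step dilution series. Batches are seeded and every number a test
asserts is recomputed from scratch at run time.

## Known limitations

* The alpha search is bounded by `delta = ceil(sqrt(n))`; layouts with
  more blocks per axis than that bound cannot be selected.
* Very faint structures below the 5% support threshold (e.g. the last
  steps of a dilution series, 2^-7 of full intensity) are trimmed from
  the analysis window and must be gridded by extrapolation or quantified
  via known geometry.
* Between-class variance assumes roughly comparable block masses per
  class; a single overwhelmingly bright block can absorb several
  thresholds before dimmer blocks are separated.
* Rotation recovery assumes one dominant grid; multiple differently
  rotated grids in one frame are out of scope, as are perspective and
  radial distortions.
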