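# Methods

## Image measurement

The measurement engine assumes 8-bit greyscale scans of pinned colony
arrays, colonies lighter than the background (plates scanned against
black card). Images are inverted so colonies are dark, then binarized.

**Thresholding.** The automatic grey level is the iterative intermeans
(IsoData-style) fixed point of the image histogram: starting from the
global mean, the level is repeatedly replaced by the mean of the two
class means it induces until stable. This is deterministic for a given
histogram. When the level is too high the agar merges with the
colonies and the grid cannot be found; `threshold_with_retry` then
lowers the level in fixed steps (default 5 grey levels) until the grid
fit succeeds, keeping the first successful level because lower levels
erode genuine colony area.

**Particle analysis.** Particles are 8-connected foreground
components. Circularity is 4πA/P² with the perimeter from
scikit-image's boundary approximation, clamped to 1 (small rasterized
disks can otherwise exceed 1 because the perimeter estimator
under-measures convex boundaries).

**Grid localization.** A rectangle with the preset's expected array
extent is placed over the particle cloud (centred on the coordinate
medians) and the lattice is seeded from the particles nearest its four
corners. Particles support the fit when both coordinate deviations
from the nearest lattice node are below 30% of the pitch; origin and
pitch are refit by separable least squares over supporters (4
iterations), and the fit is accepted when the mean horizontal and
vertical deviations are each below 5% of the pitch, the fitted pitch
is within 20% of the preset, and at least 25% of array positions are
supported. On failure the rectangle is repositioned on a spiral of
half-cell offsets up to ±2 cells; if the plate was scanned crooked,
rotations of ±0.5°…±3° (smallest magnitude first, positive first) are
tried on the binarized image (nearest-neighbour, lossless for the
mask). Corner seeding biases the pitch when corner colonies are absent,
so a secondary seed from 1-D projection clustering (row/column
coordinate clusters split at half-pitch gaps, linearly regressed
against cluster index) feeds the same acceptance criteria. On
synthetic renders the accepted origin is within 1 px of truth and the
rotation within one 0.5° step.

**Colony assignment.** A particle becomes the colony of its nearest
grid node iff its centroid is within a quarter cell of the node in
both axes, its area lies within [min_area, max_area] (defaults 20 px
and one full cell dx·dy at 300 dpi/1536 cpp) and its circularity is at
least 0.8; the nearest candidate wins ties. Empty nodes are re-scanned
for raw pixel content; cells above 25 foreground pixels (larger than a
typical blemish) are either recovered by a low-stringency pass with
the circularity requirement dropped (smeared colonies from sloppy
pinning are elongated, circularity ~0.4–0.6) or flagged as bad spots.
A plate with no bad spots is graded `ok`, up to 5% of positions `warn`,
beyond that `fail`.

## Normalization

Raw pixel areas are divided by the plate median (computed over all
positions, or over nonzero positions when more than 10% of the plate
is empty, so heavily blanked arrays are not dragged down), putting an
average colony at 1 regardless of scanner or incubation differences.
Three optional corrections follow, always in this order:

* **Row/column** (border competition): any row, then any column, whose
  median exceeds 1 is divided by that median. The rule is deliberately
  one-sided — the physical effect (fewer neighbours at the border)
  only inflates growth; a symmetric variant is available by option.
* **Spatial** (media thickness): per-row and per-column medians,
  relative to the plate median, are LOESS-smoothed along the plate
  axis (local linear, span 0.5, no robustness iterations — smaller
  spans chase row noise, and local linear fits reproduce linear ramps
  exactly). The correction factor at (r, c) is the product of the
  smoothed row and column profiles, floored at 1e-6.
* **Competition** (slow neighbourhoods): colonies whose 8-neighbour
  mean is below 75% of the plate median are candidates. Colony value
  is regressed on neighbourhood mean over all nonzero positions; when
  the regression is robust (R² > 0.1 and slope in (−1, 0.1] —
  competition implies a negative slope) each candidate is rescaled by
  predicted(median neighbourhood)/predicted(own neighbourhood). This
  concrete rescaling is unit-preserving, leaves non-candidates
  untouched, and exactly restores colonies that obey a linear
  neighbour-deficit response.

Zeros (empty positions) stay zero throughout and no correction can
produce a negative value.

## Scoring and interaction analysis

Raw files carry (base name, set, plate) metadata; sets are discovered
from a folder, control set *i* paired with experiment set *i* by
sorted set number (unequal counts pair the overlap), and each plate is
normalized independently before positions are aligned. Per-set scored
files preserve individual replicate sizes — required for the paired
t-test; per-ORF and combined outputs aggregate with mean and sample
SD (n−1).

Per position the analysis computes the ratio exp/ctrl and difference
exp − ctrl of the replicate means, plus per-replicate ratios. The
ratio is the primary interaction score because it is insensitive to
the control's own growth rate (a 1.0→0.8 and a 0.4→0.2 pair both give
diff −0.2 but ratios 0.8 vs 0.5). Replicate pairs zeroed by the
slow-growth filter are excluded from all statistics; remaining sizes
are clamped into [min, max] before scoring so that truly lethal
interactions (residual pinned cells) score alike. Positions with zero
control mean have an undefined ratio and are excluded, as are linked
and manually listed ORFs.

Degenerate paired t-tests are resolved deterministically: identical
pairs give p = 1 (no evidence), constant nonzero differences give
p = 0 with the divergent-t limit; single replicates give no p-value.

**Cut-off estimation.** Sorted ascending against rank, screen ratios
form a curve with steep tails (interactions) around a shallow linear
middle. An OLS line over the interquartile ranks is evaluated at the
first and last rank; these extrapolated values are the low (*p*) and
high (*q*) cut-offs and must satisfy 0 < p < 1 < q, otherwise manual
cut-offs are required. Because hit criterion 2 counts *per-replicate*
ratios against the same band, `analyze_screen` estimates the band from
the pooled per-replicate ratio distribution, not from the per-position
means (whose tighter spread would shrink the band by ~√n).

**Hit calling.** A position is an aggravating hit iff mean ratio < p,
at least `min_replicates` per-replicate ratios < p, and t-test
p < `max_p`; alleviating symmetrically with q. Calling is monotone:
raising `min_replicates` or lowering `max_p` never adds hits. No
multiple-testing correction is applied by default — the replicate and
effect-size criteria are the false-positive control — but
Benjamini–Hochberg can be layered on the exported p-values if desired.

## Screen validation

Given a reference hit set with known precision and sensitivity,
reference TP = precision·hits and FP = hits − TP; the estimated total
interaction count is T = TP/sensitivity; the calibrated screen's TP is
its reference-shared hit count divided by the reference sensitivity,
FP = hits − TP and FN = T − TP. Intermediate quantities are rounded
half-away-from-zero, which reproduces the published worked chains
exactly. Note the procedure estimates the *reference's* FN as T − TP
too; published tables sometimes differ by one count from this chain
due to independent rounding.

## Synthetic fixtures

The generators define the test conditions:

* **Rendered plates**: exactly rasterized filled ellipses (no
  anti-aliasing) on a flat background (levels 40/220, Gaussian sensor
  noise σ=5 by default), 32×48 grid at 18 px pitch, base radius 5.2 px
  (non-integer to avoid knife-edge rasterization), optional planted
  rotation, missing and smeared positions. Truth areas are the exact
  drawn pixel counts.
* **Edge boost**: separable per-axis growth advantage of √1.67 on each
  outermost row and column, so corners reach +67% area over the plate
  mean — the magnitude observed on real uniform-strain test arrays —
  and non-corner edges about +29%. Separability mirrors the physical
  model (per-axis neighbour deficit) and is what a row/column
  correction can remove; a non-separable corner excess would be
  partially attributed to both the row and the column pass and
  over-corrected.
* **Screens**: control areas fluctuate around 140 px (typical for
  1536-density at 300 dpi) with unit-mean multiplicative lognormal
  noise (CV 5% — colony areas are positive and their noise scales with
  size); experimental areas are the noiseless base times the planted
  ratio times independent noise, so planted ratios propagate exactly
  at zero noise. A linkage block depresses experimental growth to
  mimic reduced recombination near the query locus.
* **Competition plates**: scattered emptied interior positions with
  the remaining colonies obeying value = 1 + 0.5·(1 − neighbour mean),
  solved to a fixed point.

What these fixtures do *not* emulate: agar texture, condensation and
reflections, colony colour phenotypes, plate-to-plate media batch
effects beyond a global scale, and correlated (non-lognormal) pinning
noise. Passing tests therefore demonstrate correctness of the
algorithms under the stated geometric and noise models, not robustness
to every artifact of real scans — that is what the manual threshold,
grid and ellipse overrides are for.

## Problem sizes and determinism

All simulations in the test suite use single 1536-position plates
(three replicates for screen-level tests, eight for the uniform-strain
normalization check), sizes at which every statistical property tested
is already stable; every generator is bit-exact from its seed. The
end-to-end planted-screen check uses a fixed hit band of [0.75, 1.25],
midway between the null ratio 1.0 and the planted effects 0.5/1.5, as
its cut-offs: data-driven extrapolated cut-offs sit ~1.5σ from the
ratio distribution's centre by construction, so on a 1536-position
screen they admit on the order of one borderline null position — the
documented residual false-call rate of the method, checked separately
by the null-screen type-I test — and supplying screen-appropriate
manual cut-offs is the method's own mechanism for decoupling the two
properties.

## Known limitations

* The grid fitter assumes the array covers a single contiguous
  rectangle; plates with several disjoint arrays need separate
  presets/crops.
* Rotation handling is discrete (0.5° steps, ±3°); a badly skewed scan
  beyond 3° requires manual rotation.
* The competition correction rescales only colonies below the 75%
  neighbourhood threshold; mild competition gradients above it are
  left to the spatial correction.
* Quarter-cell assignment can mis-assign severely overgrown colonies
  that merge across cells; the rescan pass measures their pixel
  content but cannot split merged particles.
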