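# Methods

## Scope and model

`perivax` quantifies how naive T cells enter the splenic white pulp: instead
of migrating freely through the red pulp, they latch onto perivascular
tracks ("PT-tracks") that run along blood vessels from the red pulp to the
T zone, and move along them in a strongly one-directional fashion toward the
T zone. Because no imaging data were deposited for this system, the package
pairs every analysis with an agent-based generator that encodes the
qualitative effect structure reported in vivo, so each statistic can be
validated against a known ground truth.

The simulated field is a 2-D rectangle in physical units (µm) containing a
central T-zone disc and polyline tracks radiating from its perimeter into
the red pulp. All statistics implemented here are 2-D; real acquisitions
are 50–110 µm z-stacks, which we represent as a single projected plane. The
consequences are conservative for the quantities computed: distances and
densities carry an explicit slab-depth assumption (below), and the optical
flow statistic is defined per 2-D frame in the original method as well.

### Behavioural phenotypes

* **track_guided** — a biased random walk in arc length along a track
  polyline: each frame the cell steps `speed·Δt` toward the T zone with
  probability `bias_q` and away with `1 − bias_q`. The distal track end
  reflects; the T-zone end absorbs the cell into the disc where it continues
  as a `tzone_walker` (under the CCR7-knockout preset the T-zone end
  reflects instead: the cell reaches the end but cannot complete entry).
* **tzone_walker** — persistent random walk confined to the disc
  (`h ← p·h + (1−p)·u`, normalised; mirror reflection at the rim).
* **redpulp_arrested** — stationary up to 0.3 µm jitter, with rare
  single-frame linear jumps (rate `flow_event_rate`, speed `flow_speed`)
  mimicking passive displacement by blood flow.
* **flow_flyer** — fast straight movers crossing the field (intravascular
  objects), reflected at the field border so they stay renderable.

Lateral wobble of track-guided cells is an Ornstein–Uhlenbeck process *in
arc length travelled*: stationary sd `lateral_sigma` (default 2 µm), 
decorrelation length `lateral_corr_length` (default 20 µm, about two cell
diameters), clipped at the corridor half-width. Tying the wobble to distance
travelled rather than to time matters: lateral excursions are produced by
locomotion, so a drug that halves crawling speed also halves the wobble per
unit time, and the programmed speed ratio between presets survives into the
measured track velocities. An i.i.d. per-frame offset would instead add a
speed-independent displacement floor and destroy programmed speed contrasts.

Cells start at staggered arc positions following the golden-ratio Kronecker
sequence per track (plus ±2% jitter): any prefix of cells is well spread, so
rendered blobs stay separable and adding cells never perturbs existing
trajectories (each cell draws from a substream keyed by `(cohort seed,
cell id)`).

### Perturbation presets

| preset | effect |
|---|---|
| `control` | defaults |
| `ccr7_ko` | `bias_q = 0.5`; T-zone entry forbidden (reflect at track end) |
| `ptx` | all transferred cells become `redpulp_arrested` |
| `integrin_block` | all `speed_mean` halved (exact parameter contract) |
| `lps` | `bias_q = 0.5`; each track cell detaches with `detach_prob = 0.5` after the frame-0 snapshot and is re-seeded in the red pulp |

### Default parameters

pixel size 2 µm/px; field 1000×1000 µm (2000 µm for the crowded image-loop
study); T-zone radius 150 µm; track half-width 15 µm; frame interval 20 s
(acquisitions in this domain run every 15–30 s); control speed 10 ± 2 µm/min
per cell; `bias_q` 0.95; arrest jitter 0.3 µm; flow events 0.01/min at
300 µm/min (occasional sharp displacements; at higher rates the jumps, not
the crawling, would dominate arrested-cell velocity); flyers
300 ± 50 µm/min. No quantitative in vivo speeds are
published for track-guided cells, so the speed scale is an
order-of-magnitude choice from the lymphocyte two-photon literature; all
values are config-overridable and the conclusions tested are ratios,
fractions and null expectations rather than absolute speeds.

## Rendering

Each cell is an isotropic Gaussian blob (σ = 2 px, peak 150) over a constant
background (20) with per-frame Gaussian read noise (sd 5), clipped at 0.
`texture_sd > 0` adds a *static* smoothed random field shared by all frames,
standing in for tissue autofluorescence. This matters for optical flow:
between two pure-noise frames a pyramidal flow estimator hallucinates a
coherent random drift at the coarse pyramid levels, whereas a static texture
anchors cell-free regions at zero flow. Collective-motion scenarios
therefore render with texture (endogenous/tissue channel); detection and
tracking scenarios render without it (clean transferred-cell channel), the
way the two channels behave in real two-colour acquisitions.

## Detection, shape, and linking

Segmentation is a global threshold (Otsu by default, or a fixed intensity
quantile) followed by connected components with a minimum area (default
12 µm²).

Circularity is `4πA/P²` with `A` the pixel count times `pixel_size²` and `P`
the arc length of the traced sub-pixel boundary polygon (marching squares at
level 0.5) smoothed with a periodic Gaussian of σ = 1 vertex. The raw traced
staircase overestimates smooth perimeters by ~6% (which would bias disc
circularity to ~0.89), and chain-code estimators with √2 diagonal weights
carry a similar bias; the light smoothing removes the digitisation
staircase while barely rounding genuine corners. Measured anchors: discs of
radius 10–100 px give c = 0.98–1.00; axis-aligned squares of side ≥ 30 px
give 0.79–0.82 (ideal π/4 ≈ 0.785); a 100×5 px bar gives ≈ 0.15.

Linking is greedy nearest-neighbour in ascending distance order, gated at
`max_speed · Δt · gap` (default 60 µm/min — several times the fastest
expected crawling speed), with gap closure up to `max_gap = 1` missed frame.
Globally optimal assignment is unnecessary at the densities the generator
produces; identity swaps are covered by tests (≥ 99% frame-wise agreement
with ground truth on noise-free renders).

## Track metrics and directionality

Mean velocity is path length / duration; straightness is net displacement /
path length (the common Imaris conventions; the source measurements do not
print their formulas). The displacement curve averages |x(t+τ) − x(t)| over
all tracks and all start offsets (overlapping windows, for variance
reduction) and reports the motility coefficient as the through-origin
least-squares slope versus √τ. Tracks shorter than 10 min are excluded from
metrics and classification.

Directionality is binary per track: compare start and end distance to the
T-zone *centre* with a dead band ε = 5 µm (≈ one cell radius, absorbing
jitter); |Δd| ≤ ε is excluded as no-call. Using the disc boundary instead of
the centre changes nothing for tracks outside the disc. Tracks with > 50% of
their points within `branch_radius = 20 µm` of a track–track junction are
excluded (junction regions are crowded and behaviour there is genuinely
ambiguous; the criterion radius is a design choice, not a published value).
Per-animal fractions use toward/(toward+away); reversing a track's time
order swaps toward and away exactly.

## Collective motion (motion-sensing superpixels)

The frame is tiled into the square grid whose count is closest to 10,000
(side = candidates around √(H·W/10⁴); a 1000×1000 frame gives exactly
10,000 of side 10 px). Dense flow between consecutive contrast-normalised
frames uses pyramidal iterative Lucas–Kanade (`skimage.registration.
optical_flow_ilk`, radius 7, one warp); the translation contract (≤ 0.2 px
mean error for ≤ 5 px shifts) is tested. Superpixel centroids are advected
by the mean flow over their rigid square footprint (integral-image box
means, forward Euler); centroids reaching the border are frozen and
flagged. Each superpixel is summarised by its mean velocity (net
displacement over total time, equal to the mean per-step velocity at
uniform Δt) and mean position.

Vessel-branch axes come from the second central image moments of each
branch mask: the major axis `e1` is the eigenvector of the larger
eigenvalue, sign-corrected toward the T-zone centre; the minor axis is `e1`
rotated +90° so every branch shares one handedness; masks with eigenvalue
ratio < 1.2 are rejected as degenerate. The statistic is the fraction of
superpixels whose mean position lies in a vessel mask (ties between
overlapping masks resolved by nearer branch centroid) and whose mean
velocity projects positively on `e1`; a projection of exactly 0 does not
count. Isotropic motion gives 0.5 in expectation.

The directional null deserves care. A single movie's fraction is *not*
binomial in the superpixel count: superpixels sample the local cell flux,
which is spatially correlated over a cell's path length, so per-movie
fractions fluctuate with the cohort's chance net drift. Two design choices
keep the null calibrated: the null cohort draws a fresh uniform heading
every frame (each cell is diffusive, so per-movie net flux is small — cells
holding one heading for a whole movie would make the per-movie fraction
swing wildly and honestly), and the null is reported as an average over 20
independently seeded movies. The null corridor is 650×50 µm at 1 µm/px with
its distal cap well inside the frame, because flow estimates degrade near
image borders. Measured: per-movie sd ≈ 0.06, 20-movie mean within ±0.03 of
0.5.

## Density and association

ROIs are fixed polygons (frozen at t0 and reused verbatim later, matching
snapshot-based workflows). A 2-D count converts to cells/mm³ via volume =
area × slab depth, default 60 µm (mid-range of typical imaging depths in
this setting; reported alongside outputs). Density change is the per-ROI
ratio t1/t0 with percent loss 100·(1 − ratio); a zero baseline is flagged
rather than raised. The association fraction is on-track / (on-track +
red-pulp) with T-zone cells excluded from both reference regions.

## Problem sizes and numerical choices

The bundled studies use: 5 animals × 60 cells for directionality; 200 cells
per cohort for the image-loop velocity comparison (2000 µm field, 14 tracks,
so blobs stay resolvable); 20 ROIs × 60 cells for the LPS density change;
20 movies × 150 cells × 30 frames at 1000×1000 px for the flow null. These
sizes give sampling errors comfortably below each check's tolerance while a
full run of tests plus studies completes in well under an hour on one core.
Ties and degenerate inputs: empty masks, zero-volume ROIs, texture-free
flow inputs, zero-baseline densities and unknown presets all raise or flag
explicitly rather than producing silent numbers.

## What the generator does and does not emulate

It emulates compartment-dependent motility, strongly one-directional
track-guided migration, the four perturbation effect structures, blob-like
fluorescence rendering with read noise and static tissue texture, and
physical calibration. It does not model 3-D acquisition, photobleaching,
realistic point-spread functions, cell shape change (circularity is
validated on synthetic masks, not on rendered cells), cell–cell adhesion or
volume exclusion, or blood-flow hydrodynamics. Passing tests therefore
demonstrate the correctness and calibration of the measurement pipeline on
data with known ground truth — not that the biological parameter values are
those of the real spleen.

## Known limitations

* The superpixel fraction inherits per-movie flux fluctuations of the cell
  population; single-movie values of the null scatter by ±0.1 and only the
  multi-seed average is a calibrated 0.5.
* Greedy linking degrades in crowded fields (merged blobs); the studies keep
  densities within its validated regime.
* The perimeter estimator slightly over-smooths very small objects
  (radius < 5 px); circularity claims are made for radius ≥ 10 px.
* Velocity through the image loop is inflated by ~2–5% relative to ground
  truth by localisation noise and occasional mislinks; contrasts between
  cohorts are affected far less than absolute values.
* LPS detachment is a single-frame relocation to a red-pulp point. That is
  the right abstraction for density change in fixed ROIs, but the relocation
  jump makes velocity and start/end direction of *detached* cells physically
  meaningless; motility claims under LPS should be restricted to the
  non-detached subpopulation.
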