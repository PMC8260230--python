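# Methods

`streakdyn` quantifies the cell behaviors that establish and maintain
neuromesodermal progenitors (NMPs) — the bipotent axial progenitors of the
amniote primitive streak (PS) that feed both the posterior neural tube and
the paraxial mesoderm. The package implements five analysis stages and one
synthetic-data stage that generates every input with known ground truth, so
each estimator can be scored against the parameters that produced its data.

## Coordinate and labeling conventions

All track modules share one embryo frame: `x` is mediolateral in µm with the
midline fixed at x = 0 (motion toward x = 0 is convergence), `y` is
anteroposterior (AP) and increases posteriorly, time is minutes. Clones are
classified by potency from the tissues of their member cells — neural only
(N), mesoderm only (M), bipotent (NM) — and by axial composition relative to
a caller-supplied AP boundary (in the embryo, the somite-27 level that marks
the transition from primary to secondary neurulation).

## Geometric-series population model

With each division producing two daughters, each of which independently
leaves the epiblast (ingresses) with probability `f`, the expected
non-ingressed population follows

    U_n = q^n · U_0,    q = 2 (1 − f).

For the anterior-PS NMP territory, `f = 0.35` gives `q = 1.3`; starting from
`U_0 = 50` cells, the model passes 530 and 689 cells at n = 9 and 10 rounds,
so reaching ~550 cells brackets to (9, 10) divisions, and doing so in 40 h
implies a ~4 h cell cycle. Rounding of projected counts is half-away-from-
zero (530.15 → 530, 689.29 → 689). `stochastic_growth_sim` is the exact
branching-process counterpart (daughters ~ Binomial(2·count, 1 − f) per
generation); its mean obeys the same geometric law, which the tests verify
by Monte Carlo. `fit_growth` inverts the model by ordinary least squares of
log count on division index (time / assumed cycle time), with a percentile
bootstrap over count rows (default 1000 resamples) for confidence intervals.
The fit requires positive counts and at least three timepoints; constant
counts recover q = 1, i.e. f = 0.5.

## Track kinematics

Tracks are inputs (nucleus detection and linking are upstream concerns).
Velocities are discrete displacements between consecutive samples, attached
to the midpoint time and position; `v_AP = Δy/Δt` and
`v_LM = −sign(x_mid)·Δx/Δt`, so convergence is positive on both sides of the
midline. The angle with the midline is `arctan(|v_LM|/|v_AP|)` in [0°, 90°],
folding convergence and divergence together since only the angle magnitude
is biologically reported; a zero-displacement step is undefined and is
skipped and counted. Angle fractions are computed per track (mean step angle
first, then the fraction of tracks below/above 45°) to avoid overweighting
long tracks; a pooled-step mode is available. The 45° boundary goes to the
upper bin.

`register_to_node` subtracts the interpolated node position from every
sample (no extrapolation outside the node's time span), placing tracks in
the frame comoving with the regressing node. `speed_profile` bins all
velocity samples by (AP position, time) — defaults 50 µm × 30 min, free
parameters since the original binning is not constrained — reporting mean,
SD and n per bin; empty bins are absent, never imputed as zero, and
single-sample bins carry an undefined SD. `track_longevity` follows a t0
cohort per region and reports the fraction still uncensored after 1 and 2 h;
by default a lineage survives through a division (any daughter alive keeps
the lineage alive), toggleable. `interdivision_times` reports intervals only
for tracks whose birth (a recorded parent) and division are both observed,
counting censored tracks separately — note that in a growing population
observed to a fixed horizon, completed intervals are biased short, so tests
score this against a censoring-aware re-simulation rather than the raw
interval distribution. `ingression_intensity` assigns each pixel within a
band (default half-width 50 µm) of a PS-axis polyline an arclength
coordinate, bins mean intensity per timepoint, and fits a line per timepoint
when at least three bins are populated; a positive slope means intensity,
hence cumulative ingression, increases posteriorly.

## Clone calling

Raw three-channel nuclear intensities are normalized per cell to percentage
fractions (`f_i = 100·c_i/Σc`; all-zero cells are rejected with a reason).
Clustering is K-means on the fraction triples — normalization leaves two
effective dimensions — with 25 restarts under a fixed seed for determinism,
followed by per-cell silhouette scores. The cluster count is not known a
priori, so `k = "auto"` sweeps a range (default 2–15) and keeps the k with
the highest mean silhouette, the same statistic used as the per-cell quality
filter; an explicit k overrides. Cells with silhouette strictly greater than
0.4 are kept; filtering never changes assignments, only membership of the
kept set. Silhouettes are computed on the 3-D fraction triples; the planar
ternary embedding is a similarity transform of the simplex, so this choice
only rescales distances and leaves silhouettes unchanged. Ternary (triplot)
coordinates map channel 1, 2, 3 to the vertices (0,0), (1,0), (0.5, √3/2);
the map is affine and exactly invertible. Barcode clones are exact string
groups (24-mers over ACGT); reads containing an ambiguous base are excluded
and logged.

A practical caveat the tests quantify: uniform-hue "ambiguous" cells
injected among tight clones are only partially removed by the 0.4 silhouette
cut (mean ≈ 52% across seeds under the default geometry), because a uniform
draw that lands near a clone's hue center is genuinely indistinguishable
from a clone member. The filter guarantees confident assignments, not
rejection of all unlabeled cells.

## Image-based counting

Counting follows the standard particle-analysis recipe on maximum-intensity
projections: per-channel thresholding at the top tail of the intensity
histogram (default the brightest 1.3%, the value used for SOX2/T stains),
pixelwise AND of the two masks for double positives, 8-connected components,
and a strict upper particle-area bound (default < 500 px²; no lower bound by
default). Because the threshold is a quantile, every count is invariant
under monotone intensity rescaling of either channel. The mitotic index is
100 × (pH3 particles)/(Hoechst particles) inside a square ROI (default side
250 µm); with zero Hoechst particles the index is undefined (NaN). The
dual-threshold variant for live nuclear markers counts bright condensed
chromatin with a high percentile threshold and all nuclei with a lower one,
and verifies the count ordering.

The top-tail fraction should be matched to the channel's expected foreground
fraction. For a sparse channel, a too-deep tail reaches the Gaussian saddle
between neighboring nuclei and fuses them: for blobs of width σ at the
generator's minimum separation 4σ, the saddle is 2e⁻² ≈ 0.27 of peak, so
core radii beyond ≈ 1.6σ risk merging. The worked demonstrations therefore
use 0.8% (10-nucleus channels) and 0.5% (8-nucleus channel) tails, while the
1.3% default reflects denser stains.

## Dynamic genes along pseudotime

The ordering (e.g. diffusion pseudotime) is an input. Per gene, all
contiguous windows of 100 cells (stride 1, ties to the earliest start) are
scanned for the max-mean and min-mean windows; a Welch t-test between those
two sets of 100 values gives the p-value (a pooled-variance flag exists, and
a gene with zero variance in both windows gets p = 1 and a degenerate flag);
Benjamini–Hochberg adjustment across genes controls the FDR at α = 0.01.
Significant genes are z-scaled first, then smoothed with a centred moving
average of 100 cells whose window shrinks at the edges (no padding — peak
ranks near the edges depend on this), and ranked by smoothed-peak position.

This select-then-test construction is deliberately anti-conservative and the
package reports rather than corrects it. The inflation grows with the number
of candidate windows: with 100-cell windows the realized null
false-positive fraction at α = 0.01 is near zero at 300 cells but rises to
≈ 0.8 at 1000 cells (selection drives typical null |t| to ≈ 3, below the BH
line once most genes share that inflation). Significance calls on long
orderings should therefore be read as a ranking device, as in the original
heatmap use, not as calibrated hypothesis tests; the acceptance script
recomputes the realized rate.

## Synthetic data: what it does and does not emulate

The generators are phenomenological and bitwise reproducible per seed. The
track simulator advances cells by node-following AP drift plus an
AP-dependent convergence speed toward the midline (never overshooting it),
with per-frame ingression hazard and division rate profiles and Gaussian
positional noise; divisions end the mother track and spawn two daughters at
her position. Defaults: frame interval 4 min (a typical wide-field
acquisition rate at these stages), seeds uniform over |x| ∈ [80, 400] µm and
y ∈ [0, 1000] µm, node speed 1 µm/min. Cell–cell forces, chemorepulsion,
tissue deformation and z-motion are not modeled, so passing tests show
estimator correctness on the programmed statistical structure, not fidelity
to embryo mechanics. Clone colors draw Gaussian noise on raw intensities
before renormalization (channel noise enters before normalization), with
five default hue centers spread over the simplex. Images are isotropic
Gaussian blobs at integer-pixel centers with ≥ 4σ separation (shared centers
for double positives) and clipped additive noise; real nuclei are neither
isotropic nor equal-intensity. Expression trends are ramp/sigmoid/pulse
shapes of amplitude effect_size × noise_sd (unit scale when noise is zero)
over a latent uniform pseudotime; real data are counts with dropout, which
the Gaussian model ignores.

Problem sizes used in tests and the acceptance script (2000 tracks for
gradient recovery, 400 for angle fractions, 500 genes for the null
simulation, 500 branching replicates, 256² images) were chosen so every
Monte-Carlo tolerance is a small multiple of its standard error.

## Known limitations

- Longevity treats "alive at t" as having a sample at or beyond t; gaps in
  real tracking (lost-and-relinked tracks) are not modeled.
- `ingression_intensity` assumes a registered stack and a static PS axis.
- K-means assumes roughly isotropic hue clusters; strongly unequal cluster
  spreads would favor a Gaussian mixture, which the silhouette sweep cannot
  express.
- The particle counters do not split touching nuclei (no watershed); the
  threshold-matching guidance above is the intended mitigation.
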