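# Methods

This note documents the models and conventions behind `divebottom3d`: what
each stage assumes, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Conventions

All angles are radians internally (degrees only at user surfaces). Depth
is metres, positive down. The local metric frame is East-North-Up with
`z = -depth`; GPS fixes are projected onto an equirectangular tangent
plane anchored at the deployment's first fix, which at dive scales
(< 2 km) keeps projection error well below a metre. Body axes are
longitudinal (forward), lateral (right) and dorsoventral (up); pitch is
positive nose-up, roll positive right-side-down, heading clockwise from
magnetic north in `[0, 2*pi)`. The static accelerometer channel reads +1 g
on the dorsal axis when the animal is level. No declination correction is
applied: tracks are used for dive-scale geometry, not navigation.

## Dive segmentation

Pressure sensors drift slowly, so candidate surface intervals (raw depth
below 10 m) contribute a per-interval median offset that is linearly
interpolated across the record and subtracted. Dives are maximal runs
deeper than 15 m -- a conservative threshold that keeps brief sub-surface
excursions out of the dive set. Within a dive, the 1 Hz vertical speed
(first difference of depth) is modelled with a least-squares polynomial of
degree 4 in time; the bottom phase is the contiguous interval containing
the deepest sample on which the fitted |vertical speed| stays below
0.75 m/s. The polynomial responds to the overall profile shape rather
than to steps in the descent or ascent, and degree 4 accommodates both V-
and U-shaped dives; for a flat-bottomed profile the anchor is the middle
of the deepest run, since its corner samples are where the fit is least
reliable. The 0.75 m/s threshold is taken as given (it was originally
calibrated against manual delineations) and is configurable.

Drift dives (passive resting/digesting descents) are flagged with a
documented stand-in rule, since the original behavioural classifier is a
separate method: a dive is a drift dive when its bottom phase contains a
sub-window of at least 200 s with swim-speed SD below 0.15 m/s and
vertical-rate SD below 0.10 m/s. The sub-window form matters: the
polynomial bottom smooths across the descent/ascent corners, so
whole-bottom statistics are contaminated by transition tails. All three
thresholds are parameters.

## Prey-encounter detection

Dynamic acceleration is extracted per axis with a zero-phase
(forward-backward) order-3 Butterworth high-pass at 2.4 Hz -- just below
the 2.5 Hz Nyquist of the 5 Hz streams, i.e. a normalized cut-off of
0.96; filters are applied in second-order sections for numerical
stability. Each axis is summarised by the SD over non-overlapping 1 s
windows, then by a centered 5 s moving standard deviation of the dynamic
signal, pooled from the per-second SDs (the RMS of the five 1 s SDs).
The pooled form keeps the feature an amplitude envelope: taking instead
the SD *of the SD series* turns the feature into a change detector that
systematically fires twice per capture burst (once per flank of the
filter-smeared envelope, with a gap at the apex), which breaks the
one-event-per-continuous-high-run rule; the envelope reading fires once.

Each axis envelope is split into high/low states by an exact
deterministic two-means clustering (centers initialised at the 10th/90th
percentiles, Lloyd iterations to convergence; a series with range below
1e-6 is all low). A prey encounter event is a maximal run of seconds in
which all three axes are simultaneously high. Two-means on a unimodal
(no-burst) record marks the distribution's upper tail high -- empirically
15-30% of seconds per axis, whatever the scale, because 1-D two-means is
scale-equivariant; with bursts present the high cluster locks onto the
burst level and the per-axis high fraction drops to ~2%.

## Attitude and speed

The gravity and slow magnetic components are isolated with a zero-phase
order-3 Butterworth low-pass at 0.20 Hz. Pitch and roll follow from the
static acceleration direction (`pitch = asin(s1/|s|)`,
`roll = atan2(-s2, s3)`; roll set to 0 by convention in the gimbal case);
heading comes from the magnetic vector de-rotated by pitch and roll into
the horizontal plane. The forward model (attitude -> sensors) and this
inverse are exact mutual inverses on noise-free data.

Swim speed is `|v_z / sin(alpha)|` where the relation is valid: in
descent/ascent with |pitch| >= 20 degrees (the guard is required because
the division blows up near horizontal swimming) and with pitch steady
over the 1 s interval (|pitch rate| < 0.02 rad/s; transition samples are
measurably biased). These samples calibrate a linear least-squares fit of
noise level on log(speed) -- flow-noise power grows roughly log-linearly
with speed over the 0.5-3 m/s range -- whose inverse predicts speed over
whole dives from the noise level alone, clipped to [0, 3] m/s. The
calibration requires at least 100 pairs spanning at least 0.5 m/s. The
package accepts any monotone noise-level series; its own generator
synthesizes `level = a + b log(speed)` directly.

## Dead reckoning

Per-second horizontal displacement is `v * cos(alpha) * (sin(psi),
cos(psi))` using left-endpoint attitude and speed, summed from the
pre-dive GPS fix; the animal is assumed to move along its longitudinal
axis (no sideslip). Integration runs from the anchor fix through the dive
to the closing fix, so the known location really is the track's start --
anchoring instead at the 15 m crossing would offset the whole track by
the (unobserved) sub-surface displacement. The vertical coordinate is
always taken from pressure, a direct measurement. The horizontal mismatch
between the raw endpoint and the closing fix, divided by elapsed time,
gives a constant correction velocity (the effect of a steady current)
applied linearly in time; the corrected track ends on the closing fix to
numerical precision. NaN speed gaps up to 5 s are linearly interpolated
over time; longer interior gaps reject the dive. No positional
uncertainty is estimated.

## Bottom-phase shape

Shape metrics are eigen-decompositions (SVD) of the 3x3 sample covariance
(n-1 denominator) of the bottom-phase positions, eigenvalues sorted
descending, the leading eigenvector's sign fixed along the net horizontal
displacement. MC1 dispersion is `lambda_1 / sum(lambda)`. The MC1
extents use the 10% and 90% quantiles of MC1 scores (robust "ends"),
split into horizontal and vertical parts by the eigenvector's
orientation. Widths are the 10%-90% quantile ranges of *signed*
point-to-plane distances: plane A spans MC1 and the vertical (distances
are horizontal deviations), plane B spans MC1 and plane A's normal
(vertical deviations). Signed ranges reduce to zero for planar-degenerate
clouds, which absolute distances would not. Quantiles are linear
interpolation of order statistics (type 7), the ecosystem default. When
MC1 is within 1 degree of vertical the horizontal direction of plane A is
arbitrary; a fixed east azimuth is used and the metrics flagged.

## Prospected volume and density

The prospected volume is the union of detection spheres (default radii
1.5, 9 and 18 m) centred on every 1 Hz bottom position. Bottom tracks can
revisit themselves, so no closed form applies; the volume is Monte-Carlo
integrated: uniform samples in the track's bounding box expanded by r,
classified by a nearest-neighbour (kd-tree) query that provably agrees
with brute-force all-pairs distances, scaled by the box volume. The
binomial SE of the hit fraction is reported per estimate; the default
2x10^5 samples per dive gives a relative SE well below 1% at these
geometries. A multi-radius profile drawn from one shared sample stream is
monotone in r by construction. The density proxy is
`10^6 * PEE / volume` (uPEE m^-3); its reciprocal is the mean water
volume a predator must prospect per encounter. Track discretization at
1 Hz positions (no segment interpolation) is adequate because at >= 1 m/s
and r >= 1.5 m consecutive spheres overlap heavily.

## Count models

Bottom-phase PEE counts are fitted with a log link and log-volume offset,
so coefficients describe the density while the likelihood remains a count
model. Covariates are standardized to mean 0, SD 1 (effects per SD);
quadratic terms are centered before squaring to limit collinearity; pairs
with |r| > 0.9 are screened out before fitting. The ladder is Poisson
(baseline; its Pearson dispersion diagnoses overdispersion), NB2
(variance `mu + mu^2/theta`), and zero-inflated Poisson/NB with a
logistic mixture for structural zeros -- the zero part models the
probability of an *excess zero*, i.e. absence, not presence. Fits are
maximum likelihood via statsmodels; zero-inflated fits are warm-started
from the corresponding single-component fit and optimised with L-BFGS
(plain BFGS on these likelihoods frequently returns non-finite
log-likelihoods), with non-convergent fits flagged and excluded from
selection. Exhaustive selection enumerates all covariate subsets, ranks
by AIC and returns the lowest-AIC candidate whose every term is
significant at 5% (the intercept-only model conforms trivially, so pure
noise selects an empty model rather than a flagged one). Vuong's
closeness statistic `z = sqrt(n) mean(m_i)/sd(m_i)` on pointwise
log-likelihood ratios compares non-nested families. An all-zero response
has no finite MLE under a log link and yields a flagged degenerate fit
with undefined dispersion.

## The synthetic-data generator

The generator renders a deployment forward from kinematics to raw
sensors. Study conditions follow the system it emulates: dives to a prey
layer centred at 500 m, swim speed 1.5 m/s with SD 0.35 m/s and bottom
durations ~500 s (both matching the reported descriptive statistics of
real bottom phases), steep (55 degree) transits, ~120 s surface
intervals, duty-cycled acoustics (3 h on per 12 h, as in the 2011 tag
programming), a Kerguelen-like magnetic inclination of -64 degrees, and a
pressure offset drifting 0.15 m/h. The prey layer is a hard-edged slab,
50 m thick by default so that simulated bottom vertical widths (~30 m,
10-90% spread) match reported values; prey are a lazy Poisson point
process realized in the bounding box of each dive's through-the-water
path. An encounter is a prey point's first approach within the detection
radius; each encounter stamps a 2 s decaying, phase-aligned,
alternating-sign burst (irregular per-sample magnitudes) on all three
acceleration axes. Propulsive noise is stroking-dominated (a ~0.9 Hz
quasi-periodic component, removed by design by the detector's high-pass)
plus a smaller broadband part whose amplitude switches between activity
levels as a smoothed telegraph process, independent per axis. Attitude
profiles are smoothed and rendered from linearly interpolated angles at
5 Hz, which keeps the gravity norm exactly 1 g at every sample and the
sensor content band-limited well below the 0.20 Hz static cut-off, so the
dead-reckoning inversion is near-exact on noise-free data. A constant
current displaces the animal over ground (GPS fixes) while prey and
swimming live in the water frame. Drift dives replace the bottom with a
passive 0.3 m/s sink without stroking or capture attempts.

Deliberately not emulated: hydrodynamics and species biomechanics, raw
audio waveforms (the noise level series is synthesized directly from
speed), prey avoidance or escape (encounters are geometric), soft layer
edges, and GPS position error. Passing recovery tests therefore shows the
pipeline inverts this forward model faithfully -- not that it is robust
to sensor pathologies the generator does not produce (sideslip, strong
sub-daily drift, magnetic disturbance).

## Problem sizes and numerical notes

The test suite and the acceptance script run the Monte-Carlo geometry
checks at 10^6 samples, dead-reckoning checks on deployments of 5-50
dives, detector characteristics on ~10-dive deployments (~40 encounters),
zero-inflated calibration on 50 replicates of n = 1000 dives, and
end-to-end density recovery on 50-dive deployments at r = 1.5 m, sizes at
which every stochastic criterion has comfortable margin while the whole
suite stays fast. Residual known biases, both quantified in the decision
tests: the detector merges encounters closer than a few seconds (a ~5%
undercount at the default encounter rate), and the polynomial bottom's
smoothed overhang sweeps some prey-free water just outside the layer;
together these leave the end-to-end density proxy ~5-10% below the
generating intensity, well inside its 3-SE acceptance band. An occasional
dive (< 5%) has a degenerate polynomial bottom and is excluded from the
per-dive table, mirroring how unresolvable dives are dropped in practice.
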