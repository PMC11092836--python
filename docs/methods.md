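# Methods

## Model

The package simulates particle clearance over a ciliated epithelium immersed
in aqueous liquid (mucus removed), as in live-imaging experiments where
1 um tracers are recorded right above the cilia tips.

Each multiciliated cell is coarse-grained to a single horizontal point force
(regularized Stokeslet) at one cilia length `h` above a rigid no-slip wall at
z = 0 representing the cell surface. The force points along the cell's power
stroke direction and its magnitude is proportional to the ciliary beat
amplitude; the proportionality constant is the model's only free scale and
is calibrated once against a measured clearance-per-beat benchmark (see
Calibration). Individual cilia, metachronal phase, mucus rheology, and upper
confinement (coverslip, air-liquid interface) are not modeled.

### Wall Green's function

For the Cortez blob `phi_eps(r) = 15 eps^4 / (8 pi (r^2 + eps^2)^{7/2})` the
free-space regularized Stokeslet is

    8 pi mu u_i = f_i (r^2 + 2 eps^2) / R^3 + (f.b) b_i / R^3,   R^2 = r^2 + eps^2.

The no-slip wall is enforced with an image system derived for this blob and
horizontal forces (the only case the model needs). With `b` the displacement
from the image point at depth `-h` and `R^2 = |b|^2 + eps^2`:

    u_image = - S_eps(b) f                    (image Stokeslet)
              - 2 h^2  grad (f.grad)(1/R)     (potential doublet)
              - 2 h    d/dz [S_eps(b) f]      (z-doublet)
              - 4 h    ((z_hat x f) x b)/R^3  (rotlet)
              - 6 h^2 eps^2 f / R^5           (blob correction)

The coefficients were obtained by exact collocation (residuals at machine
precision for arbitrary h, eps) and the combination is analytically
divergence-free; the test suite asserts a wall residual below 1e-6 of the
cilia-plane speed (measured: ~1e-16). In the singular limit eps -> 0 the
construction reduces to the classical image solution by uniqueness. As in
all regularized image methods, the image elements carry smeared forcing of
scale eps centred below the wall; with eps = 2.5 um and h in [5, 8] um this
is the standard approximation of the method.

Far-field behaviour: away from the wall plane the source-plus-images system
decays as a stresslet, `1/r^2`. When source and observation point are both
at fixed height ~h the wall screens interactions to `h z / r^3`. This cubic
in-plane screening is what makes the periodic truncation cheap (below).

### Periodic domain and truncation

The tissue is a doubly periodic rectangle of 51 x 51 cells of 10 um
(510 x 510 um). Hydrodynamic interactions are truncated beyond 250 um: every
periodic copy of a source whose horizontal distance to the target is within
250 um is summed, all farther copies are dropped. Because of the cubic
in-plane screening the neglected tail is small; the test suite bounds the
truncation error against a brute-force 5 x 5 image sum at < 2%.

The velocity field is precomputed on a regular grid (default spacing 2.5 um)
at cilia-tip height and bilinearly interpolated for tracers; grid
interpolation error against direct kernel evaluation is checked at < 3%
(95th percentile) in the tests. The pairwise sum is a compiled (numba) loop
with a pure-NumPy fallback of the same function.

## Tissue generator

The generator produces epithelia conforming to target structural metrics:

- **Cell lattice**: square grid of pitch 10 um, centers jittered by an
  isotropic Gaussian (default sd 1 um, configurable) and wrapped
  periodically. Pixel rasters assign each pixel to the nearest center under
  the periodic metric (periodic Voronoi).
- **Ciliated patches**: patch centers on a triangular lattice (densest
  regular packing, consistent with the ring-like first maximum of C(R)) with
  spacing drawn once per realization from Normal(lambda_mean, lambda_std),
  truncated at the cell diameter. Cells are ranked by distance to the
  nearest patch center and ciliated in order until `round(coverage x
  n_cells)` cells are marked, so realized coverage is exact to one cell and
  patches grow as disks. Ties break by cell index, making generation
  deterministic given the seed.
- **Beat directions**: theta ~ Von Mises(mean direction, kappa), with kappa
  numerically inverted from the target order parameter via
  `OP = I2(kappa)/I0(kappa)` (the second circular moment, matching the
  director-free estimator `sqrt(<sin 2t>^2 + <cos 2t>^2)`). A target of
  exactly 1 uses a delta distribution.
- **Amplitudes**: Normal(amplitude_mean, amplitude_std), floored at 10% of
  the mean.

Feasibility note: patch spacing below ~2 cell diameters at moderate coverage
cannot be imprinted with 10 um cells — the discrete patches fuse and the
realized wavelength is larger than requested. The small gap wavelengths seen
in PneumaCult cultures (13.6 um) co-occur with small cells; tests of
wavelength recovery at 15 um therefore use 6 um cells.

## Tracer transport

Tracers obey `dr/dt = v(r) + sqrt(2D) eta(t)` and are integrated with
Euler-Maruyama on the periodic domain, 20 steps per beat (convergence-tested:
CPB changes < 2% from 20 to 40 steps). Time is measured in beat periods;
velocities are um/beat, so the beat frequency enters only the noise term
(`D dt / CBF`). Defaults follow the study conditions: 500 tracers, 500 beat
periods, uniform initial positions, thermal diffusivity D = 0.4 um^2/s for
ex-vivo-like conditions, CBF 2.9 Hz (measured human ex vivo at room
temperature). Unwrapped trajectories are retained for transport statistics;
track tables are sampled at one frame per beat in the TrackMate dialect.

## Output metrics

- **Eulerian field**: forward-difference track velocities binned by segment
  start (default 2 um bins for experimental tracks; 5 um for simulation
  summaries); per-bin mean over all passages; empty bins flagged.
- **Directionality** `D(R) = |<v>| / <|v|>` over square windows of side R,
  tiled without overlap plus one centred window; windows under 50% occupancy
  are skipped. D is bounded in [0, 1] and rotation-invariant.
- **Correlation length**: D(R) is fitted with `a exp(-R/R0) + c` by least
  squares; the offset c absorbs the long-range plateau (a pure exponential
  after min-subtraction distorts exact exponentials, so the offset is fitted
  rather than subtracted). Fits with R^2 <= 0.8 are rejected. Bootstrap over
  the windows behind each D(R) point gives the R0 spread.
- **DR80**: D(R) interpolated at R = 80 um.
- **CPB**: mean frame-to-frame speed divided by beat frequency; per-FOV
  ratios when paired, ratio of means when recorded separately. Simulated
  CPB uses one frame per beat, so it is the mean per-beat travel distance.
- **CBF**: per-pixel dominant rFFT frequency within a band (default 0.5 Hz
  to Nyquist), restricted to pixels whose temporal standard deviation
  exceeds 2x the median (with an absolute floor so static movies raise a
  no-signal error rather than selecting numerical ripple).
- **Pattern metrics**: C(R) is the unnormalized product estimator averaged
  over integer-rounded circle perimeters; the non-periodic form divides by
  the (m-x)(n-y) overlap (experimental masks), the periodic form by mn
  (simulated rasters). The first local maximum of the lightly smoothed curve
  (moving average of 3, plateau-tolerant comparison, parabolic sub-pixel
  refinement) is the gap wavelength; a featureless curve yields a missing
  value. Known bias: the ring average sits on a sloped background and reads
  up to ~9% low around lambda = 24.5 um with 10 um cells, within the 10%
  recovery contract. COP = 1 - 2 std(lambda)/mean(lambda) across FOVs with
  the sample (n-1) standard deviation. Coverage is cell-count-based when
  flags are available, area-based for masks (mode recorded).

## Calibration and benchmark conditions

The force constant is calibrated by bisection (CPB is monotone in force) so
that the human benchmark tissue — 94% coverage, lambda 24.5 +/- 2.9 um,
cilia length 7.1 um, amplitude 12.9 +/- 0.9 um — yields CPB = 7.75 um/beat
within 2%, with thermal noise. The calibrated model then predicts mean
directionality ~0.997 at that coverage (measured benchmark 0.97 +/- 0.1)
with no further tuning, and field correlation lengths R0 ~ 18-22 um at the
human airway coverage of 85.2% (measured R0 = 23 +/- 8 um, ciliation gap
24.5 um): the patch spacing imprints on the flow.

Standard conditions bundled in `benchmarking`:

| condition | lambda (um) | length (um) | amplitude (um) | beat OP |
|-----------|------------|-------------|----------------|---------|
| human airway (BG0-6) | 24.5 +/- 2.9 | 7.1 | 12.9 +/- 0.9 | 0.85 |
| rat airway (BG0-1)   | 26.8 +/- 2.2 | 5.1 | 8.1 +/- 1.0  | 0.60 |
| PneumaCult culture   | 13.6 +/- 0.5 | 7.0 | 12.8 +/- 0.8 | 0.85 |

Beat-order values are set from the qualitative ordering reported for the
species (human above rat); the printed supplementary tables with the exact
OP/COP values were not available, so these two numbers are package choices.
For the PneumaCult condition the package also fixes coverage = 80% (reported
as compositionally closest to the human ex vivo 85.2%) and an in-vitro
effective diffusivity of 5 um^2/s (an order of magnitude above thermal,
reflecting the extra tracer agitation of immature cultures; the study
estimated per-condition effective diffusivities from tracks, values not
available). With these choices the model predicts PC directionality ~0.98
versus the measured 0.87 +/- 0.04: the pristine simulation saturates
directionality at high coverage, and matching the in-vitro measurement
hinges on the per-condition noise scale. `estimate_effective_diffusivity`
(drift-corrected per-step MSD) is provided to derive that scale from real
track tables when they are available.

## What the synthetic fixtures do and do not show

The fixture generators produce inputs with exactly known ground truth:
crystalline-with-jitter masks, tracks from analytic flow fields plus
Brownian noise, per-pixel sinusoidal beat movies, and composition tables
with a linear link to directionality. Parameter-recovery tests close the
loop for every stage (wavelength within 10%, beat OP within 0.03, CBF within
spectral resolution, diffusivity within 10%, regression coefficients exact
at zero noise). They do not emulate imaging artefacts — tracking errors,
sample warp, uneven illumination, finite tracer density — so passing
recovery tests bounds algorithmic error, not measurement error on real data.

## Problem sizes

Full-scale runs (51 x 51 cells, 2.5 um field grid, 500 tracers x 500 beats)
are used for the benchmark reproduction and prediction-curve checks; unit
tests use smaller tissues (6-20 cells per side) chosen to keep each
statistical check well-powered at its stated tolerance.

## Known limitations

- No mucus layer, double confinement, or free-surface hydrodynamics; the
  model applies to washed, submerged preparations.
- Tracers are confined to the cilia-tip plane (2-D advection).
- The image system is exact on the wall but, like all regularized image
  methods, carries O(eps/h) smeared forcing below it.
- Beat order and COP for the standard conditions are package choices where
  the study's supplementary tables were unavailable.
- The C(R) first-maximum estimator reads a few percent low on dense
  small-wavelength patterns; COP can exceed 1 only through measurement
  noise (it is capped by construction at 1 for exact inputs).
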