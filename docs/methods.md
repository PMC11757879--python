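# Methods

## Model

The estimator treats a GPS recording as a chain of adjacent-point segments
and assigns each segment a metabolic intensity from two published regression
fits, taking their coefficients as given (refitting them from the source
tables is out of scope):

1. **Horizontal METs.** ln(METs) is piecewise linear in speed (km/h):
   slope 0.224528, intercept 0.254354 below 8.69 km/h; slope 0.065439,
   intercept 1.636715 at and above. The threshold is the intersection of the
   two lines, so the exponentiated model is continuous to < 0.01 METs —
   standing still (v = 0) evaluates to 1.29 METs, slightly above the 1 MET
   resting convention, a property of the fit rather than a bug.
2. **Cost of slope.** A quadratic multiplier in slope s (percent):
   `13.6524e-4·s² + 5.1921e-2·s + 1`, valid for s ∈ [−45, 45] %. Its minimum
   sits near s = −19 % (gentle downhill is cheaper than flat; steep downhill
   costs again), and it is positive everywhere in the validity range.
3. **Accumulation.** MET·h per segment = METs_horizontal × Cost × hours;
   cumulative VO₂ = MET·h × 3.5 ml/kg/min × 60 = 210 ml/kg per MET·h; liters
   scale by body mass (mass as worn, gear included); energy uses 5 kcal per
   liter of O₂.

The ACSM walking/running equations are implemented as references.
`acsm_rw` switches walk→run at 8 km/h; `acsm_run` applies the running
equation at *all* speeds. The latter choice is deliberate: the published
validation table is only consistent with that reading (its slow-group
`acsm_run` values exceed `acsm_rw`), even though the accompanying prose
suggests a threshold. ACSM grade input is a decimal fraction; the METs-based
model takes percent. Segments store percent and adapters convert — both
conventions are stated at every boundary.

## Kinematics conventions

* Horizontal distance is haversine on a 6,371 km sphere. "Straight-line"
  distance between 1 Hz fixes (< 10 m apart) differs from the planar value by
  far less than GPS noise; the 3-D distance adds the elevation delta by
  Pythagoras.
* **Speed uses the 3-D distance** (distance actually traveled); **slope uses
  the horizontal distance** as denominator (rise over run). The choice of
  distance feeding speed is genuinely open in the source method; this package
  picks 3-D and documents it here.
* Zero-duration segments (duplicate device timestamps) are dropped and
  counted, not fatal. Segments faster than 40 km/h (default, configurable)
  are dropped as GPS teleports. A purely vertical step receives the slope
  clip bound (±45 %) with the sign of the climb, never an infinite slope.
* Slopes beyond ±45 % are clipped to the model's validity range; clips are
  logged.
* Computed speeds and slopes are snapped to 1e-6 km/h / 1e-6 % — far below
  GPS resolution — so that inputs engineered to sit exactly on a branch
  threshold (8 km/h, 8.69 km/h) select the branch deterministically instead
  of flipping on float round-off.
* Speeds above 20 km/h trigger a warning (the fast branch extrapolates
  exponentially beyond its tabulated range) but are not errors.
* Elevation smoothing (centered moving median, odd window, edge-truncated)
  exists but defaults off; raw device elevations are the reference behavior.
  The CLI defaults — no smoothing, device elevations, clip ±45 %, outlier
  threshold 40 km/h — are the reference configuration.

## Elevation

Elevation comes from the track itself or from any provider implementing
`lookup(lat, lon) -> float | None` (`None` = not covered, so callers can fall
back to device elevation). The packaged provider is an in-memory regular
lat/lon raster with bilinear interpolation (exact for fields linear in
lat/lon; nearest-neighbor switchable for exactness tests). The interpolation
scheme is a package choice — the source method only says point altitudes come
from map data, abstracted here so a web-API adapter can satisfy the same
contract without the core ever touching the network. Default annotation
policy is `fill_missing`: device elevations are authoritative unless
explicitly overridden.

## Validation statistics

Relative error is (method − reference)/reference per subject; its mean is
tested against 0 with a one-sample t-test and reported with a t-based 95 % CI
(df = n − 1). Bland–Altman uses differences method − reference, bias = mean
difference, limits of agreement = bias ± 1.96 × SD. Sample (n − 1) SDs are
used throughout — with n = 10 the t-based CI reproduces the published
(−0.14, 0.08) interval where a normal-z interval would not. The packaged
10-participant table's printed summary SD row corresponds to a population
(n) SD; only its Mean row is used in checks. The table's published
per-minute Bland–Altman biases (3.8 / −3.3 ml/kg/min) depend on finish times
that are not part of the table and are therefore not reproduced; the
cumulative-units bias (−51.2 ml/kg) derived from the printed columns is
tested instead.

## Synthetic tracks

The generator emulates the validation protocol's course structure: legs of
constant 3-D speed, slope and duration over mixed up/down/flat terrain,
sampled at 1 Hz (configurable). Points run along a meridian so the
meters→degrees conversion is latitude-independent; the horizontal step is
sized so the 3-D speed equals the specified speed, consistent with the
kinematics convention. Leg durations are quantized to whole sampling
intervals and the closed-form expected summaries use the quantized durations,
making noise-free pipeline round-trips exact up to float error (observed
≲ 1e-10 relative; tests assert < 1e-3). Optional Gaussian noise (one seeded
generator per bundle) perturbs positions (meters → degrees) and elevations.
This models white jitter only — real GPS error is autocorrelated and
multipath-prone — so passing noise tests demonstrates robustness of the
plumbing, not field accuracy. Elevation noise biases the METs estimate
upward (the slope-cost quadratic is convex), which the noise-sensitivity
test demonstrates rather than hides.

Problem sizes in the test suite are kept small (single legs of 1–20 min at
1 Hz; an 18-cell speed × slope recovery grid; a 10,000-draw Bland–Altman
coverage simulation), sufficient for the properties asserted.

## Known limitations

* Coefficients are fixed constants; no per-athlete calibration, no anaerobic
  or post-exercise components, no heart-rate fusion.
* The METs model extrapolates beyond 20 km/h and below its tabulated walking
  speeds; standing still reads 1.29 METs.
* Haversine + Pythagoras is a short-segment approximation; no map matching,
  Kalman filtering or pause detection.
* The agreement fixture is n = 10 university students on one 5 km course;
  conclusions drawn from it inherit that scope.
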