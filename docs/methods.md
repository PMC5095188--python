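# Methods

## Problem and model

Soaring birds climb in thermals by circling inside a rising air column.
At high altitude the air is thinner, so generating the same lift at the
same posture requires flying faster (and, at fixed bank angle, on wider
circles). `thermalsoar` quantifies this from 1 Hz GPS tracks alone.

The flight model is a balanced turn at constant airspeed `v`, constant
radius `r` and constant bank angle `θ`, drifting with a locally constant
horizontal wind `w`. The force balance per unit mass is

```
l cos θ = g            (vertical: support weight)
l sin θ = v² / r       (horizontal: centripetal)
l = sqrt(g² + (v²/r)²)
θ = atan(v² / (g r))
```

with `g = 9.81 m s⁻²` held constant over altitude (gravity and buoyancy
variation over a few km are negligible against the other error sources).
With the wing loading `m/S` (kg m⁻²) and air density `ρ` (kg m⁻³), the
lift equation gives the dimensionless lift coefficient

```
C_L = 2 l (m/S) / (ρ v²).
```

Two closed-form corollaries are exposed directly:

* **Airspeed compensation.** At constant `C_L` and `m/S`, moving from
  density `ρ_l` to thinner `ρ_h` requires `v_h/v_l = sqrt(ρ_l/ρ_h)`;
  the package reports the fractional increase `sqrt(ρ_l/ρ_h) − 1`.
* **Turning sink-rate penalty.** Banking at `θ` inflates the
  straight-glide sink rate by `cos⁻³ᐟ²θ`; the attainable improvement from
  unbanking is `1 − cos³ᐟ²θ`. The `3/2` exponent follows from the sink
  rate scaling as `v³/…` under the speed and load-factor increase of a
  coordinated turn.

## Pipeline

1. **Reading** (`track_io`). Movebank-style CSV with configurable column
   names. Timestamps are truncated to whole seconds; duplicate timestamps
   keep the first fix; rows with unparseable or out-of-range fields are
   dropped and counted. Bursts split at any gap > 1 s; nothing ever
   crosses a burst boundary. Altitude is the recorded GPS height above
   mean sea level, unsmoothed.
2. **Projection.** Each 31-fix (30 s) window is projected onto a local
   tangent plane by an equirectangular projection about the window
   centroid (`x = R cos φ₀ Δλ`, `y = R Δφ`, `R = 6 371 000 m`). Over the
   ≲ 500 m extent of a loop the projection error is far below GPS noise.
3. **Ground velocity.** Central differences at interior fixes,
   *second-order* one-sided differences at the two ends. First-order
   endpoints would bias each end of the unwrapped heading by ω/2,
   shrinking the cumulative turn to 29/30 of truth (−3.3%); the
   second-order stencil keeps the bias under 0.6% for loop periods
   ≥ 10 s.
4. **Loop segmentation** (`loop_segmentation`). A window qualifies as a
   loop when the unwrapped ground-velocity heading accumulates
   |Δθ| ≥ 2π (strict, no tolerance) and every speed exceeds
   0.5 m s⁻¹ (headings are undefined near zero speed; real thermalling
   is an order of magnitude faster). Windows are scanned greedily left to
   right; an accepted window's last fix is the first fix of the next
   candidate, so accepted 30-s intervals tile the burst without
   overlapping in time. Headings use *ground* velocity because the wind
   is unknown at this stage; over a full circle the net winding is the
   same for air and ground velocity whenever |w| < v. The angular rate is
   ω = |Δθ|/30 s; the magnitude is used so clockwise and counterclockwise
   circles are symmetric, with the sign kept for the wind fit.
5. **Wind and airspeed** (`wind_airspeed`). Ground velocity of a drifting
   circle is a constant plus a rotating vector:
   `v_E = w_E + a cos(ωt + φ)`, `v_N = w_N + s·a sin(ωt + φ)` with
   `s` the turn direction. For fixed ω this is linear in
   `(w_E, w_N, a cos φ, a sin φ)` and solved by least squares; ω is then
   refined by bounded 1-D minimisation of the residual sum of squares
   within ±20% of the heading-based ω (convergence tolerance
   10⁻¹² rad s⁻¹, so noiseless recovery is limited only by floating
   point). Two numerical details matter:
   * the fit uses the **29 interior** velocities only — central
     differences of a sinusoid are exactly sinusoidal (amplitude
     attenuated by `sin(ωΔt)/(ωΔt)`, phase exact), while one-sided
     endpoint differences are not and would contaminate the fit;
   * the fitted amplitude and the mean wind-corrected speed are
     **de-attenuated** by `ωΔt / sin(ωΔt)` (Δt = 1 s), so airspeed is
     unbiased rather than ~2–3% low at typical loop rates.
   A fit is non-converged when the design is ill-conditioned or the
   fitted amplitude is ~0 (straight flight); such segments are dropped.
   Segments where |w| ≥ v are flagged `wind_dominant` (ties flag) and
   excluded, since the method assumes wind slower than the circling bird.
   Airspeed is horizontal only: at ~1 m s⁻¹ climb against ~10 m s⁻¹
   airspeed the vertical component changes the magnitude by < 0.5%.
6. **Kinematics** (`flight_mechanics`). Per segment: `r = v/ω`, then
   `l`, `θ`, and `C_L` with the population wing loading
   `m/S = 10.54 kg m⁻²` (individual mass varies too much with feeding to
   use per-bird values). Air density comes from the input column when
   present, else from the International Standard Atmosphere at the
   segment's mean altitude (`T = 288.15 − 0.0065 h`,
   `p = 101325 (T/288.15)^5.25588`, `ρ = p/(287.058 T)`, valid to
   11 km); segments with no density source are dropped and counted.
   The source used is recorded per segment.
7. **Altitude statistics** (`altitude_analysis`).
   * Equal-count elevation bins (default k = 15): stable rank split, the
     first `N mod k` bins take the extra element; ties keep time order.
     Summaries report mean, quartiles and the 2.5–97.5 percentile
     interval (linear-interpolation percentiles).
   * 5% air-density tail groups (round half up): the lowest-density
     segments are the high-flying group, the highest-density segments
     the low-flying group. Contrasts: density excess `(ρ_l/ρ_h − 1)`,
     radius and airspeed increases relative to the low-flying group, and
     the lift-coefficient difference relative to the *low-flying* value
     (the convention chosen where several denominators were possible).
   * OLS of `v²` on `1/ρ` with intercept, unweighted, one pre-specified
     model (two-sided t for the slope; no multiple-testing machinery).
     At constant `C_L` the theoretical slope is `2 g (m/S)/C_L`.
   * Radius–altitude trend: a constant percentage per km *is* a
     log-linear model, so OLS of `ln r` on altitude (km), reported as
     `(e^slope − 1)·100` % per 1000 m.

## Synthetic data

The simulator generates exactly the motion the analysis assumes — an
exact drifting circle with constant climb — plus white Gaussian GPS noise
(default σ = 0.5 m per horizontal coordinate, typical of 1 Hz GPS),
inverse-projected to lon/lat over the eastern Himalaya and annotated with
ISA densities. Defaults mirror the observed flight regime: airspeed
11 m s⁻¹, radius 30 m, wind (3, −2) m s⁻¹, 1 m s⁻¹ climb, 10-min bursts.
Every 30-s window's true wind, airspeed, ω, r, θ, l, `C_L` and ρ is
recorded for parameter-recovery tests.

`simulate_population` builds the altitude-gradient scenario: 12 density
levels evenly spaced over 1.099 → 0.646 kg m⁻³ (the observed range),
4 birds, one 300-s burst per bird per level, per-track wind drawn
uniformly below 3 m s⁻¹, alternating turn directions. Airspeed per level
inverts the lift equation at constant `C_L = 1.787`
(`v = sqrt(2 g (m/S)/(ρ C_L))`, ≈ 10.3 m s⁻¹ at the dense end), radius
scales as `v²` (constant bank), and each burst's start altitude is set so
its mid-climb altitude sits exactly at the level's density. These sizes
(~480 segments, ~14 000 fixes) make the whole pipeline run in seconds
while leaving every estimator's error an order of magnitude below the
tolerances checked.

What the simulator deliberately does **not** model: thermal updraft
structure (climb is constant), time-varying or sheared wind,
autocorrelated GPS error, flapping, altitude-dependent behaviour beyond
the constant-`C_L` rule. Passing recovery tests therefore demonstrates
the estimators are correct *under the model's assumptions*; on real
tracks, wind variation within a loop and thermal turbulence add error
that these tests do not measure.

## Numerical choices and edge cases

* Projection round-trip is identity to < 10⁻⁶ m for displacements
  < 2 km; the residual end-to-end bias after a long wind drift is
  tangent-plane curvature (≲ 4·10⁻⁴ m s⁻¹ per simulated kilometre of
  drift), well below GPS-noise effects.
* The ω search bracket (±20%) always contains the truth because the
  heading-based ω is biased < 1%.
* Degenerate inputs: straight flight gives a ≈ 0 amplitude →
  non-converged, never an exception; an empty segment list is a valid
  (empty) result, not an error; group statistics require enough segments
  for disjoint tails (N ≥ 2·round(0.05 N) and N ≥ k).
* Rounding: tail-group size uses round-half-up, matching integer group
  sizes at any N.

## Limitations

* Wind is assumed constant per loop and is estimated per loop; no
  smoothing across loops.
* The lift analysis needs a wing-loading value; using a population mean
  makes `C_L` a population-level quantity.
* ISA densities are a fallback, not a reanalysis: real atmospheres
  deviate from ISA by several percent, which propagates linearly into
  `C_L`.
* The 30-s/31-fix window is fixed; birds circling slower than one turn
  per 30 s are invisible to the segmentation by design.
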