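# thermalsoar

Thermalling-flight mechanics from 1 Hz GPS tracks of soaring birds.

Large soaring birds such as Himalayan vultures climb in thermals from
near sea level to over 6000 m, across an almost twofold range of air
densities. Because lift scales with `ρ v²`, a bird that keeps its wing
posture (lift coefficient) fixed must fly faster — and, at constant bank
angle, on wider circles — as the air thins. `thermalsoar` turns raw
biologged GPS tracks into the quantities needed to test that strategy:

* **loop segmentation** — finds 30-s windows (31 fixes) in which the bird
  completes a full circle;
* **wind from loop distortion** — a steady wind displaces successive
  circles; fitting the drifting-circle velocity model
  `v_ground(t) = w + a·(cos(ωt+φ), ±sin(ωt+φ))` to each loop recovers the
  wind vector `w`, and subtracting it yields the airspeed `v`;
* **banked-turn mechanics** — from `v` and the angular rate `ω`:
  radius `r = v/ω`, bank angle `θ = atan(v²/gr)`, lift acceleration
  `l = √(g² + (v²/r)²)`, and lift coefficient
  `C_L = 2 l (m/S)/(ρ v²)` with the wing loading `m/S`;
* **altitude analysis** — equal-count elevation bins, 5% air-density tail
  groups (low- vs high-flying contrast), the OLS fit of `v²` on `1/ρ`
  (theoretical slope `2g(m/S)/C_L` at constant `C_L`), and the
  percent-per-km radius trend;
* **a synthetic flight simulator** with exact ground truth for every
  stage, so wind, airspeed, radius, bank and `C_L` recovery can be
  verified without any field data.

Intended users: movement ecologists and flight-biomechanics researchers
working with high-frequency (1 Hz) GPS biologging data of soaring flight.

## Worked example

```python
import numpy as np
from thermalsoar import (SimulationConfig, simulate_thermalling_track,
                         find_loop_segments, fit_loop_wind, airspeed,
                         angular_rate, circle_radius, bank_angle,
                         lift_acceleration, lift_coefficient, isa_density,
                         airspeed_compensation)

cfg = SimulationConfig(rng_seed=42)          # 10-min burst, v=11 m/s, r=30 m,
track, truth = simulate_thermalling_track(cfg)  # wind (3,-2), 0.5 m GPS noise
segs = find_loop_segments(track)             # -> 20 loop segments

s = segs[0]
est = fit_loop_wind(s)
v = airspeed(s, est)
om = angular_rate(s)
r = circle_radius(v, om)
l = lift_acceleration(v, r)
rho = isa_density(s.mean_altitude)
print(f"wind = ({est.wind_east:.2f}, {est.wind_north:.2f}) m/s")
print(f"airspeed v = {v:.2f} m/s  omega = {om:.3f} rad/s  radius = {r:.1f} m")
print(f"bank = {np.degrees(bank_angle(v, r)):.1f} deg  "
      f"C_L = {lift_coefficient(l, 10.54, rho, v):.2f}")
print(f"compensation 1.099->0.646: {airspeed_compensation(1.099, 0.646):.1%}")
```

prints

```
wind = (3.01, -1.98) m/s
airspeed v = 10.93 m/s  omega = 0.375 rad/s  radius = 29.2 m
bank = 22.7 deg  C_L = 1.69
compensation 1.099->0.646: 30.4%
```

The simulated wind (3, −2) m/s and airspeed 11 m/s are recovered to a few
percent under 0.5 m GPS noise (exactly, at zero noise); the final line is
the closed-form airspeed increase required between the two density
extremes of the vultures' flight band — about 30%, matching the wider,
faster circles seen at altitude.

## Command line

```sh
thermalsoar simulate --seed 5 --out sim/           # track.csv + truth.csv
thermalsoar simulate --population --seed 5 --out sim/  # altitude gradient
thermalsoar analyze --input sim/track.csv --out run/
```

`analyze` writes `segments.csv`, `wind.csv`, `kinematics.csv`, per-bin
summaries, `groups.json` (low- vs high-flying contrast), `model.json`
(the `v²` ~ `1/ρ` fit and radius trend) and `report.json` with the count
at every filter stage. Exit codes: 0 success (an empty result is not an
error), 2 configuration error, 3 stage failure.

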