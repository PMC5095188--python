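"""Per-loop wind estimation from loop distortion, and airspeed.

A bird circling in a steady horizontal wind traces a drifting circle: its
ground velocity is the sum of a constant wind vector and a rotating
air-velocity vector of constant magnitude.  Writing s = +1/-1 for the turn
direction, the model is

    v_E(t) = w_E + a * cos(omega * t + phi)
    v_N(t) = w_N + s * a * sin(omega * t + phi)

with unknowns (w_E, w_N, a, phi, omega).  For fixed omega the model is
linear in (w_E, w_N, a*cos(phi), a*sin(phi)) and solved in closed form;
omega is then refined by 1-D minimisation of the residual sum of squares
in a +/-20% bracket around the heading-based angular rate.

Ground velocities come from central differences of the 1 Hz positions.
Differencing a pure sinusoid attenuates its amplitude by sin(omega*dt) /
(omega*dt) while leaving phase and frequency exact at interior samples,
so the fit uses the 29 interior velocities and de-attenuates the fitted
amplitude; one-sided endpoint differences do not share the sinusoidal
form and are excluded.  On noiseless circular drift the wind vector and
airspeed are then recovered to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .loop_segmentation import LoopSegment, angular_rate

OMEGA_BRACKET = 0.20  # +/- fraction around the heading-based angular rate
_MIN_AMPLITUDE = 1e-9
_MAX_CONDITION = 1e8

QUALITY_OK = "ok"
QUALITY_WIND_DOMINANT = "wind_dominant"


@dataclass
class WindEstimate:
    """Mean horizontal wind over one loop, with fit diagnostics."""

    wind_east: float
    wind_north: float
    airspeed_amplitude: float  # fitted |air velocity|, de-attenuated, m/s
    phase: float  # radians
    omega_fit: float  # rad/s
    rms_residual: float  # m/s
    converged: bool
    n_iterations: int

    @property
    def wind_speed(self) -> float:
        return float(np.hypot(self.wind_east, self.wind_north))

    @property
    def wind_direction_deg(self) -> float:
        """Meteorological direction the wind blows FROM, clockwise from north."""
        return float(np.rad2deg(np.arctan2(-self.wind_east, -self.wind_north)) % 360.0)


def _design(t: np.ndarray, omega: float, s: int) -> np.ndarray:
    """Stacked design matrix for (w_E, w_N, a*cos(phi), a*sin(phi))."""
    c, sn = np.cos(omega * t), np.sin(omega * t)
    n = len(t)
    X = np.zeros((2 * n, 4))
    X[:n, 0] = 1.0
    X[:n, 2] = c
    X[:n, 3] = -sn
    X[n:, 1] = 1.0
    X[n:, 2] = s * sn
    X[n:, 3] = s * c
    return X


def _solve(t, obs, omega, s):
    X = _design(t, omega, s)
    beta, _, rank, sv = np.linalg.lstsq(X, obs, rcond=None)
    resid = obs - X @ beta
    rss = float(resid @ resid)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    return beta, rss, rank, cond


def fit_loop_wind(segment: LoopSegment) -> WindEstimate:
    """Least-squares wind and airspeed amplitude for one loop segment.

    Returns a non-converged estimate (wind set to nan) on degenerate
    geometry, e.g. a straight-flight window passed in by mistake.
    """
    s = segment.turn_direction
    t = segment.window.t[1:-1]
    obs = np.concatenate([segment.velocities[1:-1, 0], segment.velocities[1:-1, 1]])
    omega0 = angular_rate(segment)

    def rss_of(omega: float) -> float:
        return _solve(t, obs, omega, s)[1]

    res = minimize_scalar(
        rss_of,
        bounds=((1.0 - OMEGA_BRACKET) * omega0, (1.0 + OMEGA_BRACKET) * omega0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    omega = float(res.x)
    beta, rss, rank, cond = _solve(t, obs, omega, s)
    w_e, w_n, A, B = beta
    a_raw = float(np.hypot(A, B))
    phase = float(np.arctan2(B, A))
    # undo central-difference attenuation sin(omega*dt)/(omega*dt), dt = 1 s
    atten = np.sin(omega) / omega if omega > 0 else 1.0
    converged = bool(res.success) and rank == 4 and cond < _MAX_CONDITION \
        and a_raw > _MIN_AMPLITUDE
    if not converged:
        w_e = w_n = np.nan
    return WindEstimate(
        wind_east=float(w_e),
        wind_north=float(w_n),
        airspeed_amplitude=a_raw / atten,
        phase=phase,
        omega_fit=omega,
        rms_residual=float(np.sqrt(rss / len(obs))),
        converged=converged,
        n_iterations=int(res.nfev),
    )


def airspeed(segment: LoopSegment, wind: WindEstimate) -> float:
    """Mean horizontal airspeed (m/s) over the loop.

    The wind vector is subtracted from each interior ground velocity; the
    mean residual speed is corrected for the central-difference attenuation
    at the fitted angular rate.  Requires a converged wind estimate.
    """
    if not wind.converged:
        raise ValueError("airspeed requires a converged wind estimate")
    u = segment.velocities[1:-1] - np.array([wind.wind_east, wind.wind_north])
    atten = np.sin(wind.omega_fit) / wind.omega_fit
    return float(np.mean(np.hypot(u[:, 0], u[:, 1])) / atten)


def wind_support_check(segment: LoopSegment, wind: WindEstimate,
                       airspeed_value: float | None = None) -> str:
    """Quality gate: the method assumes wind slower than the circling bird.

    Returns ``"ok"`` when |wind| < airspeed (strict; ties are flagged),
    else ``"wind_dominant"``.  Flagged segments are excluded downstream.
    """
    v = airspeed(segment, wind) if airspeed_value is None else airspeed_value
    return QUALITY_OK if wind.wind_speed < v else QUALITY_WIND_DOMINANT
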