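"""Statistical layer: elevation bins, density-tail groups, and the
squared-airspeed vs inverse-density regression.

Works on a per-segment kinematics table (one row per accepted loop) with at
least the columns ``v`` (airspeed m/s), ``radius`` (m), ``bank`` (rad),
``lift_coeff``, ``rho`` (kg m^-3) and ``altitude`` (m).

Three summaries mirror standard practice for altitude-stratified flight
data:

* equal-count elevation bins (quantile binning by altitude);
* 5% air-density tail groups — the lowest-density segments are the
  high-flying group, the highest-density segments the low-flying group —
  contrasted on density, airspeed, radius, bank and lift coefficient;
* an OLS fit of v^2 on 1/rho.  At constant lift coefficient and wing
  loading the lift equation predicts a straight line through
  v^2 = 2 g (m/S) / C_L * (1/rho), so the slope identifies
  2 g (m/S) / C_L.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, FitError
from .flight_mechanics import G


@dataclass
class GroupComparison:
    """Low-flying vs high-flying contrast on the 5% density tails.

    Percentages follow fixed conventions: density excess and the radius and
    airspeed increases are relative to the *low-flying* (denser-air) group;
    the lift-coefficient difference is (C_L_low - C_L_high) / C_L_low.
    """

    rho_l: float
    rho_h: float
    v_l: float
    v_h: float
    r_l: float
    r_h: float
    C_L_low: float
    C_L_high: float
    theta_l: float  # radians
    theta_h: float
    n_per_group: int
    density_excess_pct: float
    radius_increase_pct: float
    airspeed_increase_pct: float
    C_L_diff_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegressionFit:
    """OLS of response on predictor with intercept."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    predictor: str = "1/rho"
    response: str = "v^2"

    def to_dict(self) -> dict:
        return asdict(self)


def equal_count_bins(values, k: int = 15, order=None) -> np.ndarray:
    """Assign each value to one of ``k`` bins with counts differing by <= 1.

    Values are ranked (stable sort, so ties keep their original — time —
    order, or the explicit ``order`` key) and split into k contiguous rank
    ranges; the first ``N mod k`` bins take the extra element.  Returns
    1-based bin indices aligned with the input.
    """
    values = np.asarray(values, float)
    n = len(values)
    if n < k:
        raise DomainError(f"need at least k={k} values, got {n}")
    if order is None:
        perm = np.argsort(values, kind="stable")  # ties keep input (time) order
    else:
        perm = np.lexsort((np.asarray(order), values))
    ranks = np.empty(n, dtype=int)
    ranks[perm] = np.arange(n)
    base, extra = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:extra] += 1
    edges = np.concatenate(([0], np.cumsum(sizes)))
    bins = np.searchsorted(edges, ranks, side="right")
    return bins.astype(int)


def bin_summaries(df: pd.DataFrame, quantity: str, k: int = 15) -> pd.DataFrame:
    """Per-altitude-bin summary of ``quantity``: mean, quartiles, 95% interval.

    Percentiles use linear interpolation; the 95% interval is the 2.5–97.5
    percentile range.  One row per bin, with the altitude range and count.
    """
    bins = equal_count_bins(df["altitude"].values, k=k)
    rows = []
    for b in range(1, k + 1):
        sub = df.loc[bins == b, quantity].values
        alt = df.loc[bins == b, "altitude"].values
        rows.append(
            {
                "bin": b,
                "altitude_min": float(alt.min()),
                "altitude_max": float(alt.max()),
                "n": len(sub),
                "mean": float(np.mean(sub)),
                "q25": float(np.percentile(sub, 25)),
                "median": float(np.percentile(sub, 50)),
                "q75": float(np.percentile(sub, 75)),
                "p2_5": float(np.percentile(sub, 2.5)),
                "p97_5": float(np.percentile(sub, 97.5)),
            }
        )
    return pd.DataFrame(rows)


def density_tail_groups(df: pd.DataFrame, fraction: float = 0.05
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split off the 5% density tails: (low-flying, high-flying) groups.

    Segments are ranked by air density; the ``n = round(fraction * N)``
    highest-density segments form the low-flying group and the ``n``
    lowest-density segments the high-flying group (round half up).
    """
    if not np.isfinite(df["rho"]).all():
        raise DomainError("every segment needs an air density")
    n_total = len(df)
    n = int(math.floor(fraction * n_total + 0.5))
    if n < 1:
        raise DomainError("tail fraction selects no segments")
    if 2 * n > n_total:
        raise DomainError(f"tail groups of {n} overlap in {n_total} segments")
    order = np.argsort(df["rho"].values, kind="stable")
    high_flying = df.iloc[order[:n]]  # lowest density = highest altitude
    low_flying = df.iloc[order[-n:]]
    return low_flying, high_flying


def compare_groups(low: pd.DataFrame, high: pd.DataFrame) -> GroupComparison:
    """Contrast the low-flying and high-flying groups on their means."""
    if len(low) == 0 or len(high) == 0:
        raise DomainError("groups must be non-empty")
    m_low, m_high = low.mean(numeric_only=True), high.mean(numeric_only=True)
    rho_l, rho_h = float(m_low["rho"]), float(m_high["rho"])
    v_l, v_h = float(m_low["v"]), float(m_high["v"])
    r_l, r_h = float(m_low["radius"]), float(m_high["radius"])
    cl_l, cl_h = float(m_low["lift_coeff"]), float(m_high["lift_coeff"])
    return GroupComparison(
        rho_l=rho_l,
        rho_h=rho_h,
        v_l=v_l,
        v_h=v_h,
        r_l=r_l,
        r_h=r_h,
        C_L_low=cl_l,
        C_L_high=cl_h,
        theta_l=float(m_low["bank"]),
        theta_h=float(m_high["bank"]),
        n_per_group=len(low),
        density_excess_pct=(rho_l / rho_h - 1.0) * 100.0,
        radius_increase_pct=(r_h / r_l - 1.0) * 100.0,
        airspeed_increase_pct=(v_h / v_l - 1.0) * 100.0,
        C_L_diff_pct=(cl_l - cl_h) / cl_l * 100.0,
    )


def contrast_percentages(rho_l: float, rho_h: float, r_l: float, r_h: float,
                         cl_l: float, cl_h: float) -> dict[str, float]:
    """Group contrasts straight from summary means (no segment table needed)."""
    return {
        "density_excess_pct": (rho_l / rho_h - 1.0) * 100.0,
        "radius_increase_pct": (r_h / r_l - 1.0) * 100.0,
        "C_L_diff_pct": (cl_l - cl_h) / cl_l * 100.0,
    }


def fit_speed_density_model(df: pd.DataFrame) -> RegressionFit:
    """OLS of squared airspeed on inverse air density, with intercept.

    Under constant C_L and wing loading m/S (and lift acceleration ~ g) the
    theoretical slope is 2 g (m/S) / C_L.
    """
    if len(df) < 3:
        raise FitError("need at least 3 segments")
    x = 1.0 / df["rho"].values
    y = df["v"].values ** 2
    if np.ptp(x) == 0 or not np.isfinite(x).all():
        raise FitError("degenerate predictor: air density has no variation")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(model.nobs),
    )


def theoretical_speed_density_slope(wing_loading: float, c_l: float) -> float:
    """Slope of v^2 on 1/rho implied by constant C_L: 2 g (m/S) / C_L."""
    return 2.0 * G * wing_loading / c_l


def radius_altitude_trend(df: pd.DataFrame) -> tuple[float, RegressionFit]:
    """Percent change in circling radius per 1000 m of altitude.

    A constant percentage per km is a log-linear model: OLS of ln(radius) on
    altitude in km, trend = (exp(slope) - 1) * 100.
    """
    if len(df) < 3:
        raise FitError("need at least 3 segments")
    if np.ptp(df["altitude"].values) < 1000:
        raise FitError("segments must span at least 1000 m of altitude")
    x = df["altitude"].values / 1000.0
    y = np.log(df["radius"].values)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    fit = RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(model.nobs),
        predictor="altitude_km",
        response="ln(radius)",
    )
    return (math.exp(fit.slope) - 1.0) * 100.0, fit
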