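"""Mortality estimation: length-converted catch curve and empirical M suite.

Total mortality Z comes from the linearized length-converted catch curve:
each length bin is converted to a relative age t_i through the inverse
VBGF, its residence time is dt_i = (1/k) ln((L_inf - L_lower)/(L_inf -
L_upper)), and ln(N_i/dt_i) is regressed on t_i over the descending limb;
Z is minus the slope.  Natural mortality M is taken as the mean of a suite
of thirteen empirical estimators driven by lifespan t_max, the growth
parameters and water temperature.  Fishing mortality follows as F = Z - M
and the exploitation rate as E = F/(F + M).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import GrowthParameters, vbgf_age_at_length
from .lfq import LengthFrequencyData

__all__ = [
    "CatchCurveFit",
    "MortalityEstimates",
    "catch_curve",
    "empirical_m_suite",
    "fishing_mortality",
    "exploitation_rate",
    "f_from_e",
]


@dataclass
class CatchCurveFit:
    """Linearized length-converted catch-curve regression."""

    bin_indices: np.ndarray      # usable bins (original grid indices)
    t_years: np.ndarray          # relative age at bin midpoint
    dt_years: np.ndarray         # residence time in bin
    y: np.ndarray                # ln(N/dt)
    counts: np.ndarray
    used: np.ndarray             # original grid indices entering the regression
    slope: float
    intercept: float
    slope_se: float
    r_squared: float

    @property
    def z_per_year(self) -> float:
        return -self.slope

    @property
    def z_ci(self) -> tuple[float, float]:
        """0.95 normal-approximation interval for Z."""
        half = 1.96 * self.slope_se
        return (self.z_per_year - half, self.z_per_year + half)


def catch_curve(
    lfq: LengthFrequencyData,
    p: GrowthParameters,
    selection: str | tuple[int, int] = "auto",
) -> CatchCurveFit:
    """Fit the linearized length-converted catch curve on pooled counts.

    Parameters
    ----------
    lfq : length-frequency data; columns are pooled (summed) first.
    p : growth parameters used for the length-to-age conversion.
    selection : ``"auto"`` picks the descending limb as the bins after the
        global maximum of ln(N/dt) up to the last occupied bin whose upper
        edge is below 0.95 L_inf; a ``(first, last)`` pair of original grid
        indices selects an explicit inclusive range.

    Bins whose upper edge reaches L_inf are excluded with a warning; fewer
    than 3 usable points is an error.
    """
    counts = lfq.counts.sum(axis=1)
    lower = lfq.bin_lower_edges_mm
    upper = lfq.bin_upper_edges_mm

    beyond = (upper >= p.linf_mm) & (counts > 0)
    if np.any(beyond):
        warnings.warn(
            f"{int(beyond.sum())} occupied bin(s) with upper edge >= L_inf "
            f"({p.linf_mm} mm) excluded from the catch curve",
            stacklevel=2,
        )
    usable = np.nonzero((counts > 0) & (upper < p.linf_mm))[0]
    if usable.size < 3:
        raise ValueError("fewer than 3 usable bins for the catch curve")

    t = vbgf_age_at_length(p, lfq.bin_midpoints_mm[usable])
    dt = np.log((p.linf_mm - lower[usable]) / (p.linf_mm - upper[usable])) / p.k_per_year
    y = np.log(counts[usable] / dt)

    if selection == "auto":
        start = int(np.argmax(y)) + 1
        limit = upper[usable] < 0.95 * p.linf_mm
        if not np.any(limit):
            raise ValueError("no usable bins below 0.95 L_inf")
        end = int(np.nonzero(limit)[0][-1])
    else:
        first, last = selection
        inside = (usable >= first) & (usable <= last)
        pos = np.nonzero(inside)[0]
        if pos.size == 0:
            raise ValueError("explicit selection contains no usable bins")
        start, end = int(pos[0]), int(pos[-1])
    if end - start + 1 < 3:
        raise ValueError("fewer than 3 points selected for the regression")

    sel = slice(start, end + 1)
    res = stats.linregress(t[sel], y[sel])
    return CatchCurveFit(
        bin_indices=usable,
        t_years=t,
        dt_years=dt,
        y=y,
        counts=counts[usable],
        used=usable[sel],
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue) ** 2,
    )


# ---------------------------------------------------------------------------
# Empirical natural-mortality suite
# ---------------------------------------------------------------------------

def empirical_m_suite(
    linf_mm: float, k_per_year: float, tmax_years: float, temp_celsius: float
) -> pd.DataFrame:
    """Evaluate the thirteen empirical natural-mortality estimators.

    Units per row follow each estimator's historical convention: the Pauly
    temperature form takes L_inf in cm with base-10 logs; the Then growth
    form takes L_inf in mm.  Returns a DataFrame with columns
    ``formula_id``, ``formula``, ``m_per_year`` and ``warning`` (set where a
    formula can produce a non-positive rate, which is retained, not
    dropped).  The arithmetic mean of the column is ``df["m_per_year"].mean()``.
    """
    if not (linf_mm > 0 and k_per_year > 0 and tmax_years > 0 and temp_celsius > 0):
        raise ValueError("all inputs to the M suite must be positive")

    linf_cm = linf_mm / 10.0
    k = k_per_year
    tmax = tmax_years
    pauly = 10.0 ** (
        -0.0066
        - 0.279 * math.log10(linf_cm)
        + 0.6543 * math.log10(k)
        + 0.4634 * math.log10(temp_celsius)
    )
    rows = [
        ("m_5_over_tmax", "M = 5/tmax", 5.0 / tmax),
        ("m_2.996_over_tmax", "M = 2.996/tmax", 2.996 / tmax),
        ("m_2.5_over_tmax", "M = 2.5/tmax", 2.5 / tmax),
        (
            "m_exp_decay",
            "M = 3k/(e^(0.38 tmax k) - 1)",
            3.0 * k / (math.exp(0.38 * tmax * k) - 1.0),
        ),
        (
            "m_pauly_temp",
            "M = 10^(-0.0066 - 0.279 log10(Linf_cm) + 0.6543 log10(k)"
            " + 0.4634 log10(T))",
            pauly,
        ),
        ("m_3_over_tmax", "M = 3/tmax", 3.0 / tmax),
        ("m_4.6_over_tmax", "M = 4.6/tmax", 4.6 / tmax),
        (
            "m_then_growth",
            "M = 1.0661 Linf_mm^-0.1172 k^0.5092",
            1.0661 * linf_mm**-0.1172 * k**0.5092,
        ),
        ("m_linear_k", "M = -0.1778 + 3.1687 k", -0.1778 + 3.1687 * k),
        ("m_1.6k", "M = 1.6 k", 1.6 * k),
        ("m_1.5k", "M = 1.5 k", 1.5 * k),
        ("m_1.4k", "M = 1.4 k", 1.4 * k),
        ("m_4.22_over_tmax", "M = 4.22/tmax", 4.22 / tmax),
    ]
    df = pd.DataFrame(rows, columns=["formula_id", "formula", "m_per_year"])
    df["warning"] = df["m_per_year"] <= 0
    if df["warning"].any():
        warnings.warn(
            "one or more empirical M estimators returned a non-positive rate",
            stacklevel=2,
        )
    return df


@dataclass
class MortalityEstimates:
    """Bundle of Z (with CI), the M table, and the derived F and E."""

    z_per_year: float
    z_ci: tuple[float, float]
    m_table: pd.DataFrame
    linf_mm: float
    k_per_year: float
    tmax_years: float
    temp_celsius: float

    @property
    def m_mean_per_year(self) -> float:
        return float(self.m_table["m_per_year"].mean())

    @property
    def f_per_year(self) -> float:
        return fishing_mortality(self.z_per_year, self.m_mean_per_year)

    @property
    def e_rate(self) -> float:
        return exploitation_rate(self.f_per_year, self.m_mean_per_year)


def fishing_mortality(z: float, m: float) -> float:
    """F = Z - M.  A negative result (Z below M) is flagged, not raised."""
    if z < 0 or not m > 0:
        raise ValueError("require z >= 0 and m > 0")
    f = z - m
    if f < 0:
        warnings.warn(
            f"fishing mortality is negative (Z={z} < M={m})", stacklevel=2
        )
    return f


def exploitation_rate(f: float, m: float) -> float:
    """E = F/(F + M) = F/Z."""
    if not m > 0:
        raise ValueError("m must be positive")
    return f / (f + m)


def f_from_e(e: float, m: float) -> float:
    """Invert the exploitation rate: F = E M/(1 - E)."""
    if not 0 <= e < 1:
        raise ValueError("e must lie in [0, 1)")
    if not m > 0:
        raise ValueError("m must be positive")
    return e * m / (1.0 - e)
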