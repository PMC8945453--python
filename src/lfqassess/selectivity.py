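"""Gear selectivity from the catch curve's ascending limb.

Bins to the left of the catch-curve regression range are assumed to be
incompletely selected: back-extrapolating the fitted exponential decline
predicts how many individuals *would* have been caught under full
selection, and the ratio observed/predicted estimates the capture
probability per bin.  A logit-linear fit of those probabilities against
length yields the selection ogive and the length (L50 = Lc) and age (tc)
at first capture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import GrowthParameters, vbgf_age_at_length
from .lfq import LengthFrequencyData
from .mortality import CatchCurveFit

__all__ = [
    "SelectivityOgive",
    "capture_probabilities",
    "fit_logistic_selectivity",
    "age_at_first_capture",
]

_LN3 = math.log(3.0)


@dataclass(frozen=True)
class SelectivityOgive:
    """Logistic retention curve ln(1/P - 1) = s1 - s2 L."""

    s1: float
    s2: float

    def __post_init__(self) -> None:
        if not self.s2 > 0:
            raise ValueError("s2 must be positive (monotone increasing ogive)")

    @property
    def l50_mm(self) -> float:
        return self.s1 / self.s2

    @property
    def l25_mm(self) -> float:
        return (self.s1 - _LN3) / self.s2

    @property
    def l75_mm(self) -> float:
        return (self.s1 + _LN3) / self.s2

    def retention(self, length_mm) -> np.ndarray | float:
        """Retention probability at length (vectorised)."""
        L = np.asarray(length_mm, dtype=float)
        out = 1.0 / (1.0 + np.exp(self.s1 - self.s2 * L))
        return float(out) if out.ndim == 0 else out

    @staticmethod
    def from_l50_l75(l50_mm: float, l75_mm: float) -> "SelectivityOgive":
        if not l75_mm > l50_mm:
            raise ValueError("require l75 > l50")
        s2 = _LN3 / (l75_mm - l50_mm)
        return SelectivityOgive(s1=s2 * l50_mm, s2=s2)


def capture_probabilities(
    fit: CatchCurveFit, lfq: LengthFrequencyData
) -> pd.DataFrame:
    """Per-bin capture probabilities from catch-curve back-extrapolation.

    Ascending-limb bins (usable bins before the regression range) get
    P = min(N/N_hat, 1) with N_hat = exp(intercept + slope t) dt;
    regression-range bins and beyond get P = 1.
    """
    first_used = fit.used[0]
    ascending = fit.bin_indices < first_used
    if not np.any(ascending):
        raise ValueError("no ascending-limb bins: selection ogive not estimable")

    n_hat = np.exp(fit.intercept + fit.slope * fit.t_years) * fit.dt_years
    p = np.where(ascending, np.minimum(fit.counts / n_hat, 1.0), 1.0)
    return pd.DataFrame(
        {
            "bin_index": fit.bin_indices,
            "midpoint_mm": lfq.bin_midpoints_mm[fit.bin_indices],
            "t_years": fit.t_years,
            "n_obs": fit.counts,
            "n_pred": np.where(ascending, n_hat, fit.counts),
            "p_capture": p,
            "ascending": ascending,
        }
    )


def fit_logistic_selectivity(prob_table: pd.DataFrame) -> SelectivityOgive:
    """Fit the logit ogive to bin-level capture probabilities.

    Regresses ln(1/P - 1) on length over bins with 0 < P < 1 (the logit is
    undefined at the extremes).  Requires at least 3 interior points and a
    positive slope parameter s2.
    """
    interior = prob_table[
        (prob_table["p_capture"] > 0) & (prob_table["p_capture"] < 1)
    ]
    if len(interior) < 3:
        raise ValueError(
            "fewer than 3 bins with interior capture probability; "
            "ogive not estimable"
        )
    y = np.log(1.0 / interior["p_capture"].to_numpy() - 1.0)
    L = interior["midpoint_mm"].to_numpy()
    res = stats.linregress(L, y)
    s2 = -float(res.slope)
    if s2 <= 0:
        raise ValueError("non-monotone ogive: estimated s2 <= 0")
    return SelectivityOgive(s1=float(res.intercept), s2=s2)


def age_at_first_capture(ogive: SelectivityOgive, p: GrowthParameters) -> float:
    """tc: age at which the growth curve reaches L50."""
    if ogive.l50_mm >= p.linf_mm:
        raise ValueError("L50 >= L_inf: age at first capture undefined")
    return float(vbgf_age_at_length(p, ogive.l50_mm))
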