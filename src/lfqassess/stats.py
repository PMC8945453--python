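"""Survey summaries and biometric regressions.

CPUE (individuals per trap) by 20-m depth stratum with Welch
heteroscedastic comparisons and Bonferroni post-hoc letters, sex-ratio
chi-square tests, and log-log length-weight regressions with an isometry
t-test and a between-sex slope/intercept comparison (ANCOVA).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .lfq import CatchRecord, TrapSet

__all__ = [
    "LWRFit",
    "cpue_by_stratum",
    "welch_anova",
    "pairwise_welch_bonferroni",
    "sex_ratio_chisq",
    "fit_lwr",
    "allometry_test",
    "compare_lwr_sexes",
]

STRATUM_WIDTH_M = 20.0
STRATUM_RANGE_M = (0.0, 240.0)


def _stratum(depth: float) -> float:
    """Lower bound of the 20-m stratum containing ``depth``."""
    lo, hi = STRATUM_RANGE_M
    return float(np.clip(np.floor(depth / STRATUM_WIDTH_M) * STRATUM_WIDTH_M, lo, hi - STRATUM_WIDTH_M))


def cpue_by_stratum(
    sets: Sequence[TrapSet], records: Sequence[CatchRecord]
) -> pd.DataFrame:
    """Mean CPUE (ind. per trap) per depth stratum, with 0.95 CI and letters.

    Per-set CPUE is the record count divided by the number of traps; only
    valid sets enter.  A record referencing a missing or invalid set is an
    error.  Post-hoc letters come from pairwise Welch t-tests with
    Bonferroni correction across strata (strata with one set get their own
    letter).
    """
    valid = {s.set_id: s for s in sets if s.valid}
    all_ids = {s.set_id for s in sets}
    counts: dict[str, int] = {sid: 0 for sid in valid}
    for r in records:
        if r.set_id not in valid:
            where = "invalid" if r.set_id in all_ids else "missing"
            raise ValueError(f"record references {where} set {r.set_id!r}")
        counts[r.set_id] += 1

    per_set = pd.DataFrame(
        {
            "set_id": list(valid),
            "stratum_lo": [_stratum(s.depth_m) for s in valid.values()],
            "cpue": [counts[sid] / valid[sid].n_traps for sid in valid],
        }
    )
    grouped = per_set.groupby("stratum_lo")["cpue"]
    summary = grouped.agg(n_sets="size", cpue_mean="mean", cpue_sd="std").reset_index()
    summary["stratum_hi"] = summary["stratum_lo"] + STRATUM_WIDTH_M
    se = summary["cpue_sd"] / np.sqrt(summary["n_sets"])
    summary["ci_lower"] = summary["cpue_mean"] - 1.96 * se
    summary["ci_upper"] = summary["cpue_mean"] + 1.96 * se

    groups = {lo: g.to_numpy() for lo, g in grouped}
    testable = {lo: g for lo, g in groups.items() if g.size >= 2 and g.std(ddof=1) > 0}
    letters = {}
    if len(testable) >= 2:
        _, letter_map = pairwise_welch_bonferroni(list(testable.values()))
        letters = dict(zip(testable.keys(), letter_map))
    summary["group"] = [letters.get(lo, "") for lo in summary["stratum_lo"]]
    cols = ["stratum_lo", "stratum_hi", "n_sets", "cpue_mean", "cpue_sd",
            "ci_lower", "ci_upper", "group"]
    return summary[cols]


def welch_anova(groups: Iterable[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic F test for equal group means.

    Uses the weights n_j/s_j^2; returns (F, df1, df2, p).  Each group needs
    at least two observations and positive variance.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    g = len(gs)
    if g < 2:
        raise ValueError("need at least two groups")
    n = np.array([x.size for x in gs])
    if np.any(n < 2):
        raise ValueError("each group needs at least two observations")
    var = np.array([x.var(ddof=1) for x in gs])
    if np.any(var <= 0):
        raise ValueError("zero-variance group: Welch test undefined")
    mean = np.array([x.mean() for x in gs])

    w = n / var
    W = w.sum()
    grand = (w * mean).sum() / W
    a = ((w * (mean - grand) ** 2).sum()) / (g - 1)
    lam = (((1 - w / W) ** 2) / (n - 1)).sum()
    b = 1.0 + 2.0 * (g - 2) / (g**2 - 1.0) * lam
    f = a / b
    df1 = g - 1.0
    df2 = (g**2 - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


def _compact_letters(names, diff) -> dict:
    """Greedy compact letter display: shared letter = not significantly different."""
    letters: list[set] = []  # each entry: set of group names sharing a letter
    for name in names:
        placed = False
        for member_set in letters:
            if all(not diff[frozenset((name, other))] for other in member_set):
                member_set.add(name)
                placed = True
        if not placed:
            letters.append({name})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, member_set in zip(alphabet, letters):
        for name in member_set:
            out[name] += letter
    return out


def pairwise_welch_bonferroni(
    groups: Sequence[np.ndarray],
) -> tuple[pd.DataFrame, list[str]]:
    """All pairwise Welch t-tests with Bonferroni adjustment.

    Returns the adjusted p-value matrix (DataFrame indexed by group number)
    and a compact letter display: groups sharing a letter are not
    significantly different at 0.05.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    g = len(gs)
    if g < 2:
        raise ValueError("need at least two groups")
    n_pairs = g * (g - 1) // 2
    padj = pd.DataFrame(np.ones((g, g)), index=range(g), columns=range(g))
    diff = {}
    for i, j in itertools.combinations(range(g), 2):
        _, p = sps.ttest_ind(gs[i], gs[j], equal_var=False)
        p_adj = min(1.0, float(p) * n_pairs)
        padj.iloc[i, j] = padj.iloc[j, i] = p_adj
        diff[frozenset((i, j))] = p_adj < 0.05
    order = np.argsort([x.mean() for x in gs])
    letters_by_name = _compact_letters(list(order), diff)
    return padj, [letters_by_name[i] for i in range(g)]


def sex_ratio_chisq(n_m: int, n_f: int) -> tuple[float, float, float]:
    """Male:female ratio and the 1-df chi-square test against 1:1.

    Returns (ratio m per female, chi2, p) where
    chi2 = (n_m - n_f)^2 / (n_m + n_f).
    """
    if n_m + n_f <= 0:
        raise ValueError("need at least one sexed individual")
    chi2 = (n_m - n_f) ** 2 / (n_m + n_f)
    p = float(sps.chi2.sf(chi2, df=1))
    ratio = n_m / n_f if n_f > 0 else float("inf")
    return float(ratio), float(chi2), p


@dataclass(frozen=True)
class LWRFit:
    """Length-weight power-law fit WW = a CL^b on the log-log scale."""

    group: str
    n: int
    a: float                 # intercept back-transformed to natural scale
    b: float                 # allometric exponent
    se_log_a: float
    se_b: float
    r_squared: float


def _weighted_records(records: Iterable[CatchRecord], group: str):
    recs = [r for r in records if r.ww_g is not None]
    if group in ("male", "female"):
        recs = [r for r in recs if r.sex == group]
    elif group != "pooled":
        raise ValueError(f"unknown group {group!r}")
    return recs


def fit_lwr(records: Iterable[CatchRecord], group: str = "pooled") -> LWRFit:
    """OLS of ln(WW) on ln(CL); returns a, b, their SEs and r-squared."""
    recs = _weighted_records(records, group)
    if len(recs) < 3:
        raise ValueError(f"fewer than 3 weighted records in group {group!r}")
    x = np.log([r.cl_mm for r in recs])
    y = np.log([r.ww_g for r in recs])
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return LWRFit(
        group=group,
        n=len(recs),
        a=float(np.exp(model.params[0])),
        b=float(model.params[1]),
        se_log_a=float(model.bse[0]),
        se_b=float(model.bse[1]),
        r_squared=float(model.rsquared),
    )


def allometry_test(fit: LWRFit) -> tuple[float, float]:
    """t-test of H0: b = 3 (isometric growth); returns (t, two-sided p)."""
    t = (fit.b - 3.0) / fit.se_b
    p = 2.0 * float(sps.t.sf(abs(t), df=fit.n - 2))
    return float(t), p


def compare_lwr_sexes(records: Iterable[CatchRecord]) -> dict:
    """ANCOVA comparison of the male and female length-weight relationships.

    Fits ln(WW) ~ ln(CL) * sex.  The interaction F-test checks slope
    homogeneity; under a retained common slope, the sex main effect is
    F-tested and the 0.95 CI of the female-minus-male offset on the log
    scale is reported.
    """
    recs = [r for r in records if r.ww_g is not None and r.sex in ("male", "female")]
    n_m = sum(r.sex == "male" for r in recs)
    n_f = sum(r.sex == "female" for r in recs)
    if n_m < 3 or n_f < 3:
        raise ValueError("both sexes need at least 3 weighted records")
    df = pd.DataFrame(
        {
            "lcl": np.log([r.cl_mm for r in recs]),
            "lww": np.log([r.ww_g for r in recs]),
            "sex": [r.sex for r in recs],
        }
    )
    full = smf.ols("lww ~ lcl * C(sex, Treatment('male'))", data=df).fit()
    additive = smf.ols("lww ~ lcl + C(sex, Treatment('male'))", data=df).fit()
    slope_only = smf.ols("lww ~ lcl", data=df).fit()

    inter = full.compare_f_test(additive)       # (F, p, df_diff)
    sexeff = additive.compare_f_test(slope_only)
    coef = "C(sex, Treatment('male'))[T.female]"
    ci = additive.conf_int().loc[coef]
    return {
        "interaction_f": float(inter[0]),
        "interaction_p": float(inter[1]),
        "sex_f": float(sexeff[0]),
        "sex_p": float(sexeff[1]),
        "offset_log": float(additive.params[coef]),
        "offset_ci": [float(ci[0]), float(ci[1])],
        "n_male": n_m,
        "n_female": n_f,
    }
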