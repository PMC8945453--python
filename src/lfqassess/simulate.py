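"""Individual-based simulator of a depth-structured trap survey.

Generates a lobster population with known von Bertalanffy growth
(individual variability in L_inf), annual recruitment pulses, exponential
total mortality, a depth-structured size distribution (smaller
individuals deeper), a length- and depth-dependent sex model, and
sex-specific length-weight laws — then fishes it with a trap survey whose
gear retains individuals according to a logistic selection ogive.  All
true parameter values are carried in the configuration, so every pipeline
stage can be checked against known truth.

The default configuration emulates an 8-month (July-February) survey of
550 trap sets (15 traps each, ~6% invalidated) over 40-222 m depth
catching on the order of 1100 spiny lobsters of 40-175 mm carapace
length, with a female-biased sex ratio and trap selection centred near
102 mm.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .growth import GrowthParameters, vbgf_age_at_length
from .lfq import CatchRecord, LengthFrequencyData, TrapSet, bin_lengths
from .selectivity import SelectivityOgive

__all__ = [
    "SimulationConfig",
    "LFQTruth",
    "default_months",
    "simulate_population",
    "simulate_trap_survey",
    "make_lfq_fixture",
    "expected_decay_lfq",
]


def default_months() -> list[_dt.date]:
    """Eight monthly sampling dates, July 2000 to February 2001."""
    return [
        _dt.date(2000, 7, 15), _dt.date(2000, 8, 15), _dt.date(2000, 9, 15),
        _dt.date(2000, 10, 15), _dt.date(2000, 11, 15), _dt.date(2000, 12, 15),
        _dt.date(2001, 1, 15), _dt.date(2001, 2, 15),
    ]


def _default_density() -> dict[float, float]:
    # relative lobster density per 20-m stratum, peaking at 80-120 m
    return {40: 0.6, 60: 0.8, 80: 1.0, 100: 1.0, 120: 0.8,
            140: 0.7, 160: 0.6, 180: 0.5, 200: 0.4}


@dataclass(frozen=True)
class SimulationConfig:
    """True parameter values and survey design of the synthetic survey."""

    seed: int | None = None
    months: list[_dt.date] = field(default_factory=default_months)
    n_sets: int = 550
    traps_per_set: int = 15
    invalid_fraction: float = 34.0 / 550.0
    depth_range_m: tuple[float, float] = (40.0, 222.0)
    density_by_stratum: dict[float, float] = field(default_factory=_default_density)
    mean_catch_per_set: float = 1128.0 / 516.0
    # growth / mortality truth
    linf_mm: float = 176.76
    k_per_year: float = 0.07
    cv_linf: float = 0.05
    t_anchor: float = 0.0
    pulse_sd_years: float = 0.15
    z_per_year: float = 0.19
    m_per_year: float = 0.13
    # gear: selection span set so retention of <40 mm juveniles is
    # negligible, matching a trap survey that lands essentially no recruits
    gear_l50_mm: float = 101.65
    gear_l75_mm: float = 110.0
    # sex model: logit P(female) = b0 + b_len (L - 110) + b_depth (depth - 130);
    # intercept calibrated so the caught sex ratio is female-biased near 0.6:1
    sex_b0: float = 0.75
    sex_b_length: float = -0.04
    sex_b_depth: float = -0.006
    # length-weight (a, b, lognormal sigma) per sex
    lwr_male: tuple[float, float, float] = (0.002, 2.839, 0.1)
    lwr_female: tuple[float, float, float] = (0.003, 2.769, 0.1)
    length_precision_mm: float = 0.1
    pool_size: int = 20000

    def __post_init__(self) -> None:
        if not (self.linf_mm > 0 and self.k_per_year > 0 and self.z_per_year > 0
                and self.m_per_year > 0):
            raise ValueError("growth and mortality rates must be positive")
        if not self.gear_l50_mm < self.gear_l75_mm < self.linf_mm:
            raise ValueError("require gear L50 < L75 < L_inf")
        if not 0 <= self.invalid_fraction < 1:
            raise ValueError("invalid_fraction must lie in [0, 1)")
        if self.cv_linf < 0 or self.pulse_sd_years < 0:
            raise ValueError("cv_linf and pulse_sd_years must be non-negative")
        if self.n_sets < 1 or self.traps_per_set < 0 or self.pool_size < 1:
            raise ValueError("survey sizes must be positive")

    @property
    def ogive(self) -> SelectivityOgive:
        return SelectivityOgive.from_l50_l75(self.gear_l50_mm, self.gear_l75_mm)

    @property
    def tmax_years(self) -> float:
        return 3.0 / self.k_per_year


def _fractional_dates(months) -> np.ndarray:
    from ._utils import fractional_year

    return np.array([fractional_year(d) for d in months])


def _draw_cohort_lengths(
    rng: np.random.Generator,
    n: int,
    sample_fy: float,
    linf: float,
    k: float,
    cv_linf: float,
    z: float,
    t_anchor: float,
    pulse_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Ages and lengths of ``n`` individuals alive at decimal year ``sample_fy``.

    Ages follow a truncated exponential with rate ``z`` on (0, tmax]; birth
    dates are snapped to annual pulses at ``integer + t_anchor`` with
    Gaussian jitter; per-individual L_inf is lognormal with the given CV.
    """
    tmax = 3.0 / k
    out_age = np.empty(0)
    out_len = np.empty(0)
    while out_age.size < n:
        todo = n - out_age.size
        u = rng.random(int(todo * 1.4) + 8)
        ages = -np.log(1.0 - u * (1.0 - math.exp(-z * tmax))) / z
        birth = sample_fy - ages
        pulse = np.round(birth - t_anchor) + t_anchor
        if pulse_sd > 0:
            pulse = pulse + rng.normal(0.0, pulse_sd, pulse.size)
        ages = sample_fy - pulse
        keep = (ages > 0.02) & (ages <= tmax)
        ages = ages[keep]
        if cv_linf > 0:
            sigma = math.sqrt(math.log(1.0 + cv_linf**2))
            linf_i = rng.lognormal(math.log(linf) - sigma**2 / 2.0, sigma, ages.size)
        else:
            linf_i = np.full(ages.size, linf)
        lengths = linf_i * (1.0 - np.exp(-k * ages))
        out_age = np.concatenate([out_age, ages])
        out_len = np.concatenate([out_len, lengths])
    return out_age[:n], out_len[:n]


def simulate_population(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate the population pool available in each sampling month.

    Returns a DataFrame with one row per individual and columns
    ``month_index, age_years, length_mm, recorded_length_mm, pref_depth_m,
    sex, weight_g``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fys = _fractional_dates(config.months)
    lo_d, hi_d = config.depth_range_m

    frames = []
    for mi, fy in enumerate(fys):
        ages, lengths = _draw_cohort_lengths(
            rng, config.pool_size, fy, config.linf_mm, config.k_per_year,
            config.cv_linf, config.z_per_year, config.t_anchor,
            config.pulse_sd_years,
        )
        # preferred depth: stratum drawn from the density profile, shifted
        # so smaller individuals sit deeper (smaller-deeper pattern)
        strata = sorted(config.density_by_stratum)
        weights = np.array([config.density_by_stratum[s] for s in strata])
        base = np.asarray(strata, dtype=float)[
            rng.choice(len(strata), size=ages.size, p=weights / weights.sum())
        ] + rng.random(ages.size) * 20.0
        pref = base + 0.35 * (110.0 - lengths) + rng.normal(0.0, 15.0, ages.size)
        pref = np.clip(pref, lo_d, hi_d)
        logit_f = (
            config.sex_b0
            + config.sex_b_length * (lengths - 110.0)
            + config.sex_b_depth * (pref - 130.0)
        )
        p_female = 1.0 / (1.0 + np.exp(-logit_f))
        female = rng.random(ages.size) < p_female
        a_m, b_m, s_m = config.lwr_male
        a_f, b_f, s_f = config.lwr_female
        a = np.where(female, a_f, a_m)
        b = np.where(female, b_f, b_m)
        s = np.where(female, s_f, s_m)
        weight = a * lengths**b * np.exp(rng.normal(0.0, 1.0, ages.size) * s)
        prec = config.length_precision_mm
        recorded = np.maximum(np.round(lengths / prec) * prec, prec)
        frames.append(
            pd.DataFrame(
                {
                    "month_index": mi,
                    "age_years": ages,
                    "length_mm": lengths,
                    "recorded_length_mm": recorded,
                    "pref_depth_m": pref,
                    "sex": np.where(female, "female", "male"),
                    "weight_g": weight,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_trap_survey(
    population: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[list[CatchRecord], list[TrapSet]]:
    """Fish the simulated population with a trap survey.

    Sets are spread evenly across months with depths drawn uniformly over
    the survey depth range.  Each individual occupies depths around its
    preferred depth (a normalised Gaussian kernel); a set's expected catch
    is proportional to the local abundance retained by the gear, and caught
    individuals are drawn with probability proportional to local presence
    times retention.  With a fully non-selective gear the catch is
    therefore an unbiased length sample of the population.  A configurable
    fraction of sets is marked invalid and yields no usable records.
    """
    if population.empty:
        raise ValueError("population is empty")
    rng = np.random.default_rng(seed)
    lo_d, hi_d = config.depth_range_m
    ogive = config.ogive
    kernel_sd = 25.0

    if config.traps_per_set == 0:
        return [], []

    n_months = len(config.months)
    base, extra = divmod(config.n_sets, n_months)
    sets_per_month = [base + (1 if i < extra else 0) for i in range(n_months)]

    from scipy.stats import norm as _norm

    sets: list[TrapSet] = []
    records: list[CatchRecord] = []
    set_no = 0
    for mi, date in enumerate(config.months):
        pool = population[population["month_index"] == mi]
        lengths = pool["length_mm"].to_numpy()
        retained = ogive.retention(lengths)
        pref = pool["pref_depth_m"].to_numpy()
        # per-individual kernel normalisation: depth structures where an
        # animal is caught without changing its overall catchability
        kernel_mass = _norm.cdf((hi_d - pref) / kernel_sd) - _norm.cdf(
            (lo_d - pref) / kernel_sd
        )

        n_sets_m = sets_per_month[mi]
        depths = lo_d + rng.random(n_sets_m) * (hi_d - lo_d)
        valid_flags = rng.random(n_sets_m) >= config.invalid_fraction
        # local retained abundance per set, normalised to the survey mean so
        # the average catch per set matches the configured rate
        presence = (
            np.exp(-0.5 * ((depths[:, None] - pref[None, :]) / kernel_sd) ** 2)
            / kernel_mass[None, :]
        )
        local_b = presence @ retained
        lam = config.mean_catch_per_set * local_b / local_b.mean()

        for s_i in range(n_sets_m):
            set_no += 1
            sid = f"S{set_no:04d}"
            depth = float(depths[s_i])
            sets.append(
                TrapSet(sid, date, depth, config.traps_per_set,
                        bool(valid_flags[s_i]))
            )
            if not valid_flags[s_i]:
                continue
            n_catch = int(rng.poisson(lam[s_i]))
            if n_catch == 0:
                continue
            w = presence[s_i] * retained
            total = w.sum()
            if total <= 0:
                continue
            n_catch = min(n_catch, int((w > 0).sum()))
            idx = rng.choice(pool.index.to_numpy(), size=n_catch, replace=False,
                             p=w / total)
            for i in idx:
                row = pool.loc[i]
                records.append(
                    CatchRecord(
                        set_id=sid,
                        date=date,
                        depth_m=depth,
                        sex=str(row["sex"]),
                        cl_mm=float(row["recorded_length_mm"]),
                        ww_g=max(float(round(row["weight_g"], 1)), 0.1),
                    )
                )
    return records, sets


@dataclass(frozen=True)
class LFQTruth:
    """True parameters behind a shortcut LFQ fixture."""

    linf_mm: float = 176.0
    k_per_year: float = 0.07
    t_anchor: float = 0.0
    z_per_year: float = 0.19
    cv_linf: float = 0.05
    # sharper pulses than the survey simulator: this fixture emulates
    # well-separated annual cohorts for growth-recovery tests
    pulse_sd_years: float = 0.05


def make_lfq_fixture(
    truth: LFQTruth,
    n: int,
    seed: int | None = None,
    months: list[_dt.date] | None = None,
    bin_width_mm: float = 2.0,
) -> tuple[LengthFrequencyData, LFQTruth]:
    """Draw ``n`` individual lengths from the cohort mixture and bin them.

    A fast generator for unit tests: no survey layer, no gear selection.
    Returns the LFQ together with the truth for recovery assertions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    months = months or default_months()
    rng = np.random.default_rng(seed)
    fys = _fractional_dates(months)
    per, extra = divmod(n, len(months))

    records = []
    for mi, (date, fy) in enumerate(zip(months, fys)):
        n_m = per + (1 if mi < extra else 0)
        if n_m == 0:
            continue
        _, lengths = _draw_cohort_lengths(
            rng, n_m, fy, truth.linf_mm, truth.k_per_year, truth.cv_linf,
            truth.z_per_year, truth.t_anchor, truth.pulse_sd_years,
        )
        lengths = np.maximum(np.round(lengths, 1), 0.1)
        for L in lengths:
            records.append(
                CatchRecord(set_id="FIX", date=date, depth_m=100.0,
                            sex="unknown", cl_mm=float(L))
            )
    return bin_lengths(records, bin_width_mm=bin_width_mm), truth


def expected_decay_lfq(
    p: GrowthParameters,
    z_per_year: float,
    bin_width_mm: float = 2.0,
    l_min_mm: float = 40.0,
    l_max_mm: float | None = None,
    scale: float = 1000.0,
    selection=None,
    date: _dt.date | None = None,
) -> LengthFrequencyData:
    """Noiseless catch-curve fixture: N_i = scale * e^(-Z t_i) * dt_i.

    Expected single-sample counts under exponential decay at rate ``z``,
    optionally multiplied by a selection curve evaluated at bin midpoints
    (for ascending-limb/selectivity fixtures).  Bins stay strictly below
    L_inf so every bin is usable by the catch curve.
    """
    if l_max_mm is None:
        l_max_mm = 0.95 * p.linf_mm
    origin = 2.0 * math.floor(l_min_mm / 2.0)
    n_bins = int(math.floor((l_max_mm - origin) / bin_width_mm))
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    mid = origin + (np.arange(n_bins) + 0.5) * bin_width_mm
    lower = mid - bin_width_mm / 2.0
    upper = mid + bin_width_mm / 2.0
    t = vbgf_age_at_length(p, mid)
    dt = np.log((p.linf_mm - lower) / (p.linf_mm - upper)) / p.k_per_year
    counts = scale * np.exp(-z_per_year * t) * dt
    if selection is not None:
        counts = counts * np.asarray(selection(mid), dtype=float)
    return LengthFrequencyData(
        mid, [date or _dt.date(2000, 7, 15)], counts[:, None], bin_width_mm
    )
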