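"""End-to-end assessment pipeline and its JSON report.

Runs the full analysis sequence on either a simulated survey or user CSV
files: binning -> ELEFAN restructuring -> GA growth fit with bootstrap ->
length-converted catch curve -> empirical M suite -> F and E ->
selection ogive -> Beverton-Holt per-recruit reference points -> survey
statistics.  The report is a validated (pydantic) document whose
regeneration under the same seed is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel

from . import __version__
from .growth import (
    GASettings,
    GrowthParameters,
    SearchBounds,
    elefan_ga_boot,
)
from .lfq import (
    bin_lengths,
    read_catch_records_csv,
    read_lfq_csv,
    write_catch_records_csv,
    write_lfq_csv,
)
from .mortality import catch_curve, empirical_m_suite
from .per_recruit import (
    PerRecruitInputs,
    lc_sensitivity,
    reference_points,
)
from .selectivity import (
    age_at_first_capture,
    capture_probabilities,
    fit_logistic_selectivity,
)
from . import stats as _stats
from .simulate import SimulationConfig, simulate_population, simulate_trap_survey

__all__ = ["AssessmentReport", "StageError", "run_pipeline", "load_config"]

log = logging.getLogger("lfqassess")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Report schema
# ---------------------------------------------------------------------------

class CpueStratumRow(BaseModel):
    stratum_lo: float
    stratum_hi: float
    n_sets: int
    cpue_mean: float
    ci_lower: float | None
    ci_upper: float | None
    group: str


class LwrReport(BaseModel):
    group: str
    n: int
    a: float
    b: float
    se_b: float
    r_squared: float
    allometry_t: float
    allometry_p: float


class SurveyReport(BaseModel):
    n_records: int
    n_sets_valid: int | None = None
    cpue_strata: list[CpueStratumRow] = []
    sex_ratio: dict[str, float] | None = None
    lwr: list[LwrReport] = []
    lwr_sex_comparison: dict | None = None


class GrowthReport(BaseModel):
    """Growth estimates: the assessment uses the bagged (bootstrap-mean)
    parameters, which are markedly more stable than a single GA fit on the
    flat ELEFAN score ridge; the best single fit is kept under ``point``."""

    linf_mm: float
    k_per_year: float
    t_anchor: float
    phi_prime: float
    rn: float
    n_boot: int
    point: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]


class MTableRow(BaseModel):
    formula_id: str
    formula: str
    m_per_year: float
    warning: bool


class MortalityReport(BaseModel):
    z_per_year: float
    z_ci: tuple[float, float]
    r_squared: float
    m_table: list[MTableRow]
    m_mean_per_year: float
    f_per_year: float
    e_rate: float
    temp_celsius: float
    tmax_years: float


class SelectivityReport(BaseModel):
    s1: float
    s2: float
    l25_mm: float
    l50_mm: float
    l75_mm: float
    tc_years: float


def _finite(x) -> float | None:
    """Non-finite reference points (e.g. Fmax at Emax = 1) map to null."""
    x = float(x)
    return x if np.isfinite(x) else None


class ReferencePoints(BaseModel):
    e10: float | None
    e50: float | None
    emax: float | None
    f10: float | None
    fmax: float | None


class LcSensitivityRow(BaseModel):
    lc_mm: float
    tc_years: float
    f10: float | None
    fmax: float | None
    e50: float | None
    e10: float | None
    emax: float | None


class PerRecruitReport(BaseModel):
    knife_edge: ReferencePoints
    ogive_mode: ReferencePoints | None = None
    lc_sensitivity: list[LcSensitivityRow]


class AssessmentReport(BaseModel):
    """Validated end-to-end assessment report."""

    version: str
    seed: int | None
    settings: dict
    survey: SurveyReport
    growth: GrowthReport
    mortality: MortalityReport
    selectivity: SelectivityReport
    per_recruit: PerRecruitReport


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULTS = {
    "binning": {"bin_width_mm": 2.0, "ma_window": 5},
    "growth": {"n_boot": 50, "population_size": 60, "generations": 45},
    "mortality": {"temp_celsius": 18.0},
    "per_recruit": {"lc_factors": [0.8854, 1.0, 1.1146]},
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _merged(config: dict, block: str) -> dict:
    out = dict(DEFAULTS.get(block, {}))
    out.update(config.get(block) or {})
    return out


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    plots: bool = True,
) -> AssessmentReport:
    """Execute the full assessment sequence and return the validated report.

    ``config`` is a dict (or a YAML path) with optional blocks
    ``simulation`` (synthetic-survey parameters), ``data`` (CSV paths),
    ``binning``, ``growth``, ``mortality``, ``per_recruit``.  Defaults are
    applied and logged for anything omitted.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = config.get("seed")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    # ---- data -----------------------------------------------------------
    try:
        records, sets, lfq = _stage_data(config, seed, out_path)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("data", str(exc)) from exc
    log.info("data: %d records, %d sets, LFQ %d bins x %d samples",
             len(records), len(sets), lfq.n_bins, lfq.n_samples)

    # ---- survey statistics ---------------------------------------------
    try:
        survey = _stage_stats(records, sets)
    except Exception as exc:
        raise StageError("stats", str(exc)) from exc

    # ---- growth ---------------------------------------------------------
    gcfg = _merged(config, "binning") | _merged(config, "growth")
    try:
        ga = GASettings(
            population_size=int(gcfg["population_size"]),
            generations=int(gcfg["generations"]),
        )
        bounds = SearchBounds.from_lfq(lfq)
        if "linf_bounds" in gcfg:
            bounds = SearchBounds(
                linf_mm=tuple(gcfg["linf_bounds"]),
                k_per_year=tuple(gcfg.get("k_bounds", (0.01, 1.0))),
            )
        else:
            log.info("growth: default search bounds applied: %s", bounds)
        boot = elefan_ga_boot(
            lfq,
            search=bounds,
            ga=ga,
            n_boot=int(gcfg["n_boot"]),
            seed=seed,
            ma_window=int(gcfg["ma_window"]),
        )
    except Exception as exc:
        raise StageError("growth", str(exc)) from exc
    point = boot.point
    if boot.n_boot > 1:
        # bagged estimate: averaging over resample refits stabilises the
        # flat Linf-k ridge of the ELEFAN score surface
        p = GrowthParameters(
            boot.mean["linf_mm"], boot.mean["k_per_year"], point.t_anchor
        )
    else:
        p = point
    growth_rep = GrowthReport(
        linf_mm=p.linf_mm,
        k_per_year=p.k_per_year,
        t_anchor=p.t_anchor,
        phi_prime=p.phi_prime,
        rn=boot.score.rn,
        n_boot=boot.n_boot,
        point={
            "linf_mm": point.linf_mm,
            "k_per_year": point.k_per_year,
            "t_anchor": point.t_anchor,
            "phi_prime": point.phi_prime,
        },
        ci_lower=boot.ci_lower,
        ci_upper=boot.ci_upper,
    )
    log.info("growth: Linf=%.2f mm, k=%.3f /yr, Rn=%.3f", p.linf_mm,
             p.k_per_year, boot.score.rn)

    # ---- mortality ------------------------------------------------------
    mcfg = _merged(config, "mortality")
    try:
        fit = catch_curve(lfq, p)
        tmax = 3.0 / p.k_per_year
        m_table = empirical_m_suite(
            p.linf_mm, p.k_per_year, tmax, float(mcfg["temp_celsius"])
        )
        m_mean = float(m_table["m_per_year"].mean())
        z = fit.z_per_year
        f = z - m_mean
        e = f / z
    except Exception as exc:
        raise StageError("mortality", str(exc)) from exc
    mortality_rep = MortalityReport(
        z_per_year=z,
        z_ci=fit.z_ci,
        r_squared=fit.r_squared,
        m_table=[MTableRow(**row) for row in m_table.to_dict("records")],
        m_mean_per_year=m_mean,
        f_per_year=f,
        e_rate=e,
        temp_celsius=float(mcfg["temp_celsius"]),
        tmax_years=tmax,
    )
    log.info("mortality: Z=%.3f, mean M=%.3f, F=%.3f, E=%.3f", z, m_mean, f, e)

    # ---- selectivity ----------------------------------------------------
    try:
        prob = capture_probabilities(fit, lfq.pooled())
        ogive = fit_logistic_selectivity(prob)
        tc = age_at_first_capture(ogive, p)
    except Exception as exc:
        raise StageError("selectivity", str(exc)) from exc
    selectivity_rep = SelectivityReport(
        s1=ogive.s1, s2=ogive.s2, l25_mm=ogive.l25_mm, l50_mm=ogive.l50_mm,
        l75_mm=ogive.l75_mm, tc_years=tc,
    )
    log.info("selectivity: L50=%.1f mm, tc=%.2f yr", ogive.l50_mm, tc)

    # ---- per recruit ----------------------------------------------------
    pcfg = _merged(config, "per_recruit")
    try:
        lc = ogive.l50_mm
        knife = reference_points(
            PerRecruitInputs(p.linf_mm, p.k_per_year, m_mean, lc_mm=lc)
        )
        knife_rp = ReferencePoints(
            e10=_finite(knife.e10), e50=_finite(knife.e50),
            emax=_finite(knife.emax), f10=_finite(knife.f10),
            fmax=_finite(knife.fmax),
        )
        lwr_pooled = next((x for x in survey.lwr if x.group == "pooled"), None)
        ogive_rp = None
        if lwr_pooled is not None:
            og = reference_points(
                PerRecruitInputs(
                    p.linf_mm, p.k_per_year, m_mean, ogive=ogive,
                    weight_a=lwr_pooled.a, weight_b=lwr_pooled.b,
                ),
                e_step=5e-3,
            )
            ogive_rp = ReferencePoints(
                e10=_finite(og.e10), e50=_finite(og.e50), emax=_finite(og.emax),
                f10=_finite(og.f10), fmax=_finite(og.fmax),
            )
        lc_list = [f * lc for f in pcfg["lc_factors"]]
        sens = lc_sensitivity(p.linf_mm, p.k_per_year, m_mean, lc_list, growth=p)
    except Exception as exc:
        raise StageError("per_recruit", str(exc)) from exc
    per_recruit_rep = PerRecruitReport(
        knife_edge=knife_rp,
        ogive_mode=ogive_rp,
        lc_sensitivity=[
            LcSensitivityRow(
                lc_mm=row["lc_mm"], tc_years=row["tc_years"],
                f10=_finite(row["f10"]), fmax=_finite(row["fmax"]),
                e50=_finite(row["e50"]), e10=_finite(row["e10"]),
                emax=_finite(row["emax"]),
            )
            for row in sens.to_dict("records")
        ],
    )

    settings = {
        "binning": _merged(config, "binning"),
        "growth": {k: v for k, v in gcfg.items()},
        "mortality": mcfg,
        "per_recruit": pcfg,
        "simulation": bool(config.get("simulation") is not None),
    }
    report = AssessmentReport(
        version=__version__,
        seed=seed,
        settings=settings,
        survey=survey,
        growth=growth_rep,
        mortality=mortality_rep,
        selectivity=selectivity_rep,
        per_recruit=per_recruit_rep,
    )

    if out_path is not None:
        (out_path / "report.json").write_text(report.model_dump_json(indent=2))
        m_table.to_csv(out_path / "m_table.csv", index=False)
        sens.to_csv(out_path / "lc_sensitivity.csv", index=False)
        if plots:
            _write_plots(out_path, lfq, p, fit, ogive, knife)
    return report


def _stage_data(config: dict, seed, out_path):
    sim_cfg = config.get("simulation")
    data_cfg = config.get("data") or {}
    bcfg = _merged(config, "binning")
    if sim_cfg is not None:
        kwargs = {k: v for k, v in (sim_cfg or {}).items() if k != "seed"}
        sim = SimulationConfig(**kwargs)
        sim_seed = (sim_cfg or {}).get("seed", seed)
        pop = simulate_population(sim, seed=sim_seed)
        records, sets = simulate_trap_survey(
            pop, sim, seed=None if sim_seed is None else sim_seed + 1
        )
        if out_path is not None:
            write_catch_records_csv(
                records, sets, out_path / "catch_records.csv", out_path / "sets.csv"
            )
    elif "records" in data_cfg:
        records, sets = read_catch_records_csv(
            data_cfg["records"], data_cfg.get("sets")
        )
    elif "lfq" in data_cfg:
        records, sets = [], []
    else:
        raise ValueError("config needs a 'simulation' or 'data' block")

    if "lfq" in data_cfg:
        lfq = read_lfq_csv(data_cfg["lfq"])
    else:
        lfq = bin_lengths(records, bin_width_mm=float(bcfg["bin_width_mm"]))
        if out_path is not None:
            write_lfq_csv(lfq, out_path / "lfq.csv")
    return records, sets, lfq


def _stage_stats(records, sets) -> SurveyReport:
    survey = SurveyReport(n_records=len(records))
    if not records:
        return survey
    if sets:
        survey.n_sets_valid = sum(1 for s in sets if s.valid)
        cpue = _stats.cpue_by_stratum(sets, records)
        survey.cpue_strata = [
            CpueStratumRow(
                stratum_lo=row.stratum_lo, stratum_hi=row.stratum_hi,
                n_sets=int(row.n_sets), cpue_mean=row.cpue_mean,
                ci_lower=None if np.isnan(row.ci_lower) else row.ci_lower,
                ci_upper=None if np.isnan(row.ci_upper) else row.ci_upper,
                group=row.group,
            )
            for row in cpue.itertuples()
        ]
    n_m = sum(r.sex == "male" for r in records)
    n_f = sum(r.sex == "female" for r in records)
    if n_m + n_f > 0 and n_f > 0:
        ratio, chi2, pval = _stats.sex_ratio_chisq(n_m, n_f)
        survey.sex_ratio = {"ratio_m_per_f": ratio, "chi2": chi2, "p": pval,
                            "n_male": n_m, "n_female": n_f}
    for group in ("pooled", "male", "female"):
        try:
            fit = _stats.fit_lwr(records, group)
        except ValueError:
            continue
        t, pv = _stats.allometry_test(fit)
        survey.lwr.append(
            LwrReport(
                group=group, n=fit.n, a=fit.a, b=fit.b, se_b=fit.se_b,
                r_squared=fit.r_squared, allometry_t=t, allometry_p=pv,
            )
        )
    try:
        survey.lwr_sex_comparison = _stats.compare_lwr_sexes(records)
    except ValueError:
        survey.lwr_sex_comparison = None
    return survey


def _write_plots(out_path: Path, lfq, p, fit, ogive, knife) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from ._utils import fractional_year

    # LFQ with cohort growth curves
    fig, ax = plt.subplots(figsize=(9, 5))
    fy = np.array([fractional_year(d) for d in lfq.sample_dates])
    width_t = 0.8 / 12.0
    for j, t0 in enumerate(fy):
        col = lfq.counts[:, j]
        if col.max() > 0:
            ax.barh(lfq.bin_midpoints_mm, width_t * col / col.max(), left=t0,
                    height=lfq.bin_width_mm, color="steelblue", alpha=0.7)
    tt = np.linspace(fy.min() - 45, fy.max(), 400)
    for a in range(int(fy.min()) - 45, int(fy.max()) + 1):
        ages = tt - (a + p.t_anchor)
        L = np.where(ages > 0, p.linf_mm * (1 - np.exp(-p.k_per_year * ages)), np.nan)
        ax.plot(tt, L, "k-", lw=0.6)
    ax.set_xlim(fy.min() - 0.1, fy.max() + 0.2)
    ax.set_ylim(0, lfq.bin_midpoints_mm.max() + 10)
    ax.set_xlabel("year")
    ax.set_ylabel("carapace length (mm)")
    fig.savefig(out_path / "lfq_growth.png", dpi=110)
    plt.close(fig)

    # catch curve
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(fit.t_years, fit.y, "o", mfc="none")
    used_mask = np.isin(fit.bin_indices, fit.used)
    ax.plot(fit.t_years[used_mask], fit.y[used_mask], "ko")
    xs = np.array([fit.t_years[used_mask].min(), fit.t_years[used_mask].max()])
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-")
    ax.set_xlabel("relative age (years)")
    ax.set_ylabel("ln(N/dt)")
    ax.set_title(f"Z = {fit.z_per_year:.2f} /yr")
    fig.savefig(out_path / "catch_curve.png", dpi=110)
    plt.close(fig)

    # selection ogive
    fig, ax = plt.subplots(figsize=(6, 4))
    L = np.linspace(lfq.bin_midpoints_mm.min(), lfq.bin_midpoints_mm.max(), 300)
    ax.plot(L, ogive.retention(L))
    for q, lab in ((ogive.l25_mm, "L25"), (ogive.l50_mm, "L50"), (ogive.l75_mm, "L75")):
        ax.axvline(q, ls=":", c="grey")
    ax.set_xlabel("carapace length (mm)")
    ax.set_ylabel("retention probability")
    fig.savefig(out_path / "ogive.png", dpi=110)
    plt.close(fig)

    # per-recruit curves
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(knife.e_grid, knife.yr / knife.yr.max(), label="Y'/R (scaled)")
    ax.plot(knife.e_grid, knife.br, label="B/B0")
    for e, lab in ((knife.e10, "E10"), (knife.e50, "E50"), (knife.emax, "Emax")):
        ax.axvline(e, ls=":", c="grey")
    ax.set_xlabel("exploitation rate E")
    ax.legend()
    fig.savefig(out_path / "per_recruit.png", dpi=110)
    plt.close(fig)
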