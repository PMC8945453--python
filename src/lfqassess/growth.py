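"""Growth estimation: von Bertalanffy function, ELEFAN scoring, GA fit, bootstrap.

Growth follows a modified von Bertalanffy growth function (VBGF) with the
theoretical age-at-length-zero parameter removed, so L(0) = 0:

    L(t) = L_inf * (1 - exp(-k * t))

Candidate parameter sets (L_inf, k, t_anchor) are scored against a
"restructured" length-frequency matrix with the ELEFAN criterion: the
explained sum of peaks (ESP) accumulated by the family of cohort growth
trajectories, over the available sum of peaks (ASP), reported as
Rn = 10^(ESP/ASP) / 10.  The score is maximised with a generational
genetic algorithm, and sampling uncertainty is quantified by refitting
multinomial resamples of each monthly column.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

from ._utils import fractional_year
from .lfq import LengthFrequencyData, RestructuredLFQ, restructure

__all__ = [
    "GrowthParameters",
    "ElefanScore",
    "SearchBounds",
    "GASettings",
    "BootstrapGrowthResult",
    "vbgf_length_at_age",
    "vbgf_age_at_length",
    "lifespan",
    "growth_performance_index",
    "elefan_score",
    "elefan_ga_fit",
    "elefan_ga_boot",
]


@dataclass(frozen=True)
class GrowthParameters:
    """Modified-VBGF parameters.

    ``t_anchor`` is a fractional year in [0, 1) positioning the annual
    cohort birth pulses in calendar time.
    """

    linf_mm: float
    k_per_year: float
    t_anchor: float = 0.0

    def __post_init__(self) -> None:
        if not self.linf_mm > 0:
            raise ValueError("linf_mm must be positive")
        if not self.k_per_year > 0:
            raise ValueError("k_per_year must be positive")
        if not 0 <= self.t_anchor < 1:
            raise ValueError("t_anchor must lie in [0, 1)")

    @property
    def phi_prime(self) -> float:
        """Growth performance index phi' = log10(k) + 2 log10(L_inf)."""
        return growth_performance_index(self.linf_mm, self.k_per_year)


@dataclass(frozen=True)
class ElefanScore:
    esp: float
    asp: float

    @property
    def rn(self) -> float:
        """Fit score Rn = 10^(ESP/ASP)/10, at most 1."""
        return 10.0 ** (self.esp / self.asp) / 10.0


@dataclass(frozen=True)
class SearchBounds:
    """GA search box; a collapsed interval (lo == hi) pins a parameter."""

    linf_mm: tuple[float, float]
    k_per_year: tuple[float, float] = (0.01, 1.0)
    t_anchor: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("linf_mm", self.linf_mm),
            ("k_per_year", self.k_per_year),
            ("t_anchor", self.t_anchor),
        ):
            if hi < lo:
                raise ValueError(f"degenerate bounds for {name}: {lo} > {hi}")
        if self.linf_mm[0] <= 0 or self.k_per_year[0] <= 0:
            raise ValueError("lower bounds for linf_mm and k_per_year must be > 0")

    @staticmethod
    def from_lfq(lfq: LengthFrequencyData) -> "SearchBounds":
        """Default box: L_inf in [0.9, 1.3] x largest occupied bin upper edge."""
        occupied = np.nonzero(lfq.counts.sum(axis=1) > 0)[0]
        lmax = float(lfq.bin_upper_edges_mm[occupied[-1]])
        return SearchBounds(linf_mm=(0.9 * lmax, 1.3 * lmax))


@dataclass(frozen=True)
class GASettings:
    population_size: int = 50
    generations: int = 30
    mutation_prob: float = 0.1
    mutation_sigma: float = 0.1
    elitism: int = 2
    tournament_size: int = 3
    crossover_prob: float = 0.9


@dataclass
class BootstrapGrowthResult:
    point: GrowthParameters
    score: ElefanScore
    n_boot: int
    seed: int | None
    mean: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    samples: "np.ndarray" = field(repr=False, default=None)  # (n_boot, 3): linf, k, phi'


# ---------------------------------------------------------------------------
# VBGF
# ---------------------------------------------------------------------------

def vbgf_length_at_age(p: GrowthParameters, t) -> np.ndarray | float:
    """Length (mm) at age ``t`` years under L(t) = L_inf (1 - e^(-k t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be non-negative")
    out = p.linf_mm * (1.0 - np.exp(-p.k_per_year * t))
    return float(out) if out.ndim == 0 else out


def vbgf_age_at_length(p: GrowthParameters, length_mm) -> np.ndarray | float:
    """Age (years) at which the growth curve reaches ``length_mm``."""
    L = np.asarray(length_mm, dtype=float)
    if np.any(L < 0):
        raise ValueError("length must be non-negative")
    if np.any(L >= p.linf_mm):
        raise ValueError(
            f"length {float(np.max(L))} >= L_inf {p.linf_mm}: age undefined"
        )
    out = -np.log(1.0 - L / p.linf_mm) / p.k_per_year
    return float(out) if out.ndim == 0 else out


def lifespan(k_per_year: float) -> float:
    """Approximate lifespan t_max = 3/k (years)."""
    if not k_per_year > 0:
        raise ValueError("k must be positive")
    return 3.0 / k_per_year


def growth_performance_index(linf_mm: float, k_per_year: float) -> float:
    """Pauly-Munro phi' = log10(k) + 2 log10(L_inf), with L_inf in mm."""
    if not (linf_mm > 0 and k_per_year > 0):
        raise ValueError("linf_mm and k_per_year must be positive")
    return math.log10(k_per_year) + 2.0 * math.log10(linf_mm)


# ---------------------------------------------------------------------------
# ELEFAN score
# ---------------------------------------------------------------------------

def _positive_runs(rcol: np.ndarray) -> np.ndarray:
    """Label maximal contiguous runs of positive scores; -1 elsewhere."""
    labels = np.full(rcol.size, -1, dtype=int)
    run = -1
    inside = False
    for i, v in enumerate(rcol):
        if v > 0:
            if not inside:
                run += 1
                inside = True
            labels[i] = run
        else:
            inside = False
    return labels


def elefan_score(r: RestructuredLFQ, p: GrowthParameters) -> ElefanScore:
    """Score growth parameters against a restructured LFQ.

    ASP sums, over columns, the maximum score of each positive run
    ("peak").  ESP sums the scores of the bins crossed by the cohort
    trajectories L(t) = L_inf (1 - e^(-k (t - (a + t_anchor)))) for every
    integer birth year ``a`` whose curve intersects the observed length
    range during the sampling window; within a column each bin counts at
    most once and each peak is credited at most once (by its largest
    crossed score).
    """
    rv = r.rvalues
    if not np.any(rv > 0):
        raise ValueError("no positive restructured values: ELEFAN score undefined")

    cache = getattr(r, "_score_cache", None)
    if cache is None:
        runs_by_col = [_positive_runs(rv[:, j]) for j in range(rv.shape[1])]
        asp_cached = 0.0
        for j, runs in enumerate(runs_by_col):
            for lab in range(runs.max() + 1):
                asp_cached += rv[runs == lab, j].max()
        cache = (runs_by_col, asp_cached)
        r._score_cache = cache
    runs_by_col, asp_cached = cache

    fy = np.array([fractional_year(d) for d in r.sample_dates])
    origin = r.bin_midpoints_mm[0] - r.bin_width_mm / 2.0
    n_bins = r.bin_midpoints_mm.size
    top = min(origin + n_bins * r.bin_width_mm, p.linf_mm * (1 - 1e-9))
    if top <= max(origin, 0.0):
        raise ValueError("growth curve cannot reach the observed length range")
    # oldest age at which a cohort is still inside the grid, capped at the
    # lifespan 3/k — cohorts older than the species plausibly lives are not
    # drawn, which keeps low-L_inf candidates from piling phantom cohorts
    # against their asymptote
    age_top = min(
        -math.log(1.0 - top / p.linf_mm) / p.k_per_year, 3.0 / p.k_per_year
    )
    a_min = math.floor(fy.min() - age_top) - 1
    a_max = math.floor(fy.max())
    births = np.arange(a_min, a_max + 1) + p.t_anchor

    asp = asp_cached
    esp = 0.0
    for j in range(rv.shape[1]):
        col = rv[:, j]
        runs = runs_by_col[j]

        ages = fy[j] - births
        ages = ages[ages > 0]
        lengths = p.linf_mm * (1.0 - np.exp(-p.k_per_year * ages))
        idx = np.floor((lengths - origin) / r.bin_width_mm).astype(int)
        idx = np.unique(idx[(idx >= 0) & (idx < n_bins)])
        if idx.size == 0:
            continue
        hit_runs = runs[idx]
        # troughs and zero bins count fully; each peak only by its best hit
        esp += col[idx[hit_runs < 0]].sum()
        for lab in np.unique(hit_runs[hit_runs >= 0]):
            esp += col[idx[hit_runs == lab]].max()

    return ElefanScore(esp=esp, asp=asp)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

def _decode(genes: np.ndarray, bounds: SearchBounds) -> GrowthParameters:
    # k is decoded on a log scale: growth coefficients span orders of
    # magnitude and a linear gene would squeeze slow growers into a corner
    (l_lo, l_hi), (k_lo, k_hi), (a_lo, a_hi) = (
        bounds.linf_mm,
        bounds.k_per_year,
        bounds.t_anchor,
    )
    anchor = a_lo + genes[2] * (a_hi - a_lo)
    return GrowthParameters(
        linf_mm=l_lo + genes[0] * (l_hi - l_lo),
        k_per_year=k_lo * (k_hi / k_lo) ** genes[1] if k_hi > k_lo else k_lo,
        t_anchor=anchor % 1.0,
    )


def elefan_ga_fit(
    lfq: LengthFrequencyData,
    search: SearchBounds | None = None,
    ga: GASettings | None = None,
    seed: int | None = None,
    ma_window: int = 5,
    return_history: bool = False,
    _restructured: RestructuredLFQ | None = None,
):
    """Maximise the ELEFAN Rn score with a generational genetic algorithm.

    Tournament selection, uniform crossover, Gaussian mutation (the cohort
    anchor wraps around the year), and elitism; deterministic for a fixed
    seed.  Returns the best parameters together with their score; with
    ``return_history`` also the best Rn per generation (non-decreasing
    thanks to elitism).
    """
    search = search or SearchBounds.from_lfq(lfq)
    ga = ga or GASettings()
    restr = _restructured if _restructured is not None else restructure(lfq, ma_window)
    rng = np.random.default_rng(seed)

    def fitness(genes: np.ndarray) -> float:
        return elefan_score(restr, _decode(genes, search)).rn

    pop = rng.random((ga.population_size, 3))
    fits = np.array([fitness(g) for g in pop])
    history = [float(fits.max())]

    for gen in range(ga.generations):
        order = np.argsort(fits)[::-1]
        elite = pop[order[: ga.elitism]].copy()
        # mutation width anneals so late generations refine the optimum
        sigma = ga.mutation_sigma * (1.0 - 0.85 * gen / max(ga.generations - 1, 1))
        children = []
        while len(children) < ga.population_size - ga.elitism:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population_size, ga.tournament_size)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            if rng.random() < ga.crossover_prob:
                mask = rng.random(3) < 0.5
                child = np.where(mask, parents[0], parents[1])
            else:
                child = parents[0].copy()
            mutate = rng.random(3) < ga.mutation_prob
            child = child + mutate * rng.normal(0.0, sigma, 3)
            child[:2] = np.clip(child[:2], 0.0, 1.0)
            child[2] = child[2] % 1.0
            children.append(child)
        pop = np.vstack([elite, np.array(children)])
        fits = np.array([fitness(g) for g in pop])
        history.append(float(fits.max()))

    best = pop[np.argmax(fits)]
    params = _decode(best, search)
    score = elefan_score(restr, params)
    if return_history:
        return params, score, history
    return params, score


def _resample_columns(
    lfq: LengthFrequencyData, rng: np.random.Generator
) -> LengthFrequencyData:
    """Redraw each column as a multinomial with its own total and cell probs."""
    counts = np.zeros_like(lfq.counts)
    for j in range(lfq.n_samples):
        col = lfq.counts[:, j]
        total = int(round(col.sum()))
        if total > 0:
            counts[:, j] = rng.multinomial(total, col / col.sum())
    return LengthFrequencyData(
        lfq.bin_midpoints_mm.copy(), list(lfq.sample_dates), counts, lfq.bin_width_mm
    )


def elefan_ga_boot(
    lfq: LengthFrequencyData,
    search: SearchBounds | None = None,
    ga: GASettings | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    ma_window: int = 5,
) -> BootstrapGrowthResult:
    """Bootstrap the GA fit by refitting multinomial column resamples.

    Reports, per parameter (L_inf, k, phi'), the bootstrap mean and the
    2.5/97.5 percentile interval.  Columns with a zero total stay all-zero
    in every replicate.  Deterministic for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    search = search or SearchBounds.from_lfq(lfq)
    ga = ga or GASettings()
    rng = np.random.default_rng(seed)
    fit_seed = int(rng.integers(0, 2**31 - 1))
    point, score = elefan_ga_fit(lfq, search, ga, seed=fit_seed, ma_window=ma_window)

    samples = np.empty((n_boot, 3))
    for b in range(n_boot):
        replicate = _resample_columns(lfq, rng)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        p, _ = elefan_ga_fit(replicate, search, ga, seed=rep_seed, ma_window=ma_window)
        samples[b] = (p.linf_mm, p.k_per_year, p.phi_prime)

    names = ["linf_mm", "k_per_year", "phi_prime"]
    mean = {n: float(samples[:, i].mean()) for i, n in enumerate(names)}
    lo = {n: float(np.percentile(samples[:, i], 2.5)) for i, n in enumerate(names)}
    hi = {n: float(np.percentile(samples[:, i], 97.5)) for i, n in enumerate(names)}
    return BootstrapGrowthResult(
        point=point,
        score=score,
        n_boot=n_boot,
        seed=seed,
        mean=mean,
        ci_lower=lo,
        ci_upper=hi,
        samples=samples,
    )
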