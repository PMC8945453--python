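# Methods

This note documents the models behind `lfq-assess`, the conventions and
defaults that matter for interpreting its output, and the limits of what the
synthetic-survey tests demonstrate.

## Growth model

Growth follows a modified von Bertalanffy growth function with the
theoretical age-at-length-zero parameter removed:

    L(t) = L∞ (1 − e^(−k t)),      L(0) = 0.

`L∞` is the asymptotic carapace length (mm), `k` the growth coefficient
(year⁻¹). Cohorts are positioned in calendar time by `t_anchor ∈ [0, 1)`,
the fractional year of the annual birth pulse. The model is deterministic
and non-seasonal; there is no seasonal oscillation term and no `t₀`.
Derived scalars: lifespan `tmax = 3/k` and the growth performance index
`φ′ = log₁₀ k + 2 log₁₀ L∞` with `L∞` in **mm** and base-10 logs.

## ELEFAN restructuring and score

LFQ matrices bin carapace length on a uniform grid (default 2 mm,
half-open bins `[lower, upper)`, origin the even-mm floor of the smallest
observation) by calendar month. Restructuring, per monthly column:

1. centred moving average (MA) of the counts over `window` bins
   (default 5). Edge windows average over the bins actually on the grid,
   so a flat column restructures to exactly zero everywhere;
2. `qᵢ = Nᵢ/MAᵢ` (0 where the MA is 0);
3. `rᵢ = qᵢ/q̄ − 1` about the column mean quotient;
4. positive scores are divided by `(nzᵢ + 1)`, `nzᵢ` = number of
   zero-count immediate neighbours (off-grid neighbours count as zero);
5. negative scores are rescaled by one per-column factor so the column sums
   to zero (skipped when only one sign is present).

Restructuring is scale-invariant per column. ELEFAN dialects differ between
implementations; this one is fixed and the tests of downstream behaviour do
not depend on its constants.

The fit score for a candidate `(L∞, k, t_anchor)` draws one growth
trajectory per birth year whose curve intersects the observed length range
during the sampling window, **capped at age 3/k**: without the lifespan cap,
candidates with a low asymptote accumulate arbitrarily many phantom cohorts
piled against `L∞`, which distorts the score in a way that has no biological
reading. Per column, the score sums the restructured values of the bins the
trajectories cross at that sampling date (each bin at most once; each
positive run — a "peak" — credited at most once, by the largest crossed
value). The total is ESP; ASP is the sum over columns of each peak's
maximum; `Rn = 10^(ESP/ASP)/10 ≤ 1`.

## Genetic-algorithm fit, bootstrap, bagging

The GA is generational with tournament selection (size 3), uniform
crossover (rate 0.9), per-gene Gaussian mutation (probability 0.1) whose
width anneals from 0.1 to 0.015 over the run, and elitism (2). Defaults:
population 50, 30 generations; everything is configurable, and the
recovery tests use a larger budget (60 × 60) because the score surface has
many local optima. Genes are normalised to [0, 1]; `k` is decoded on a
**log scale** (growth coefficients span orders of magnitude, and a linear
gene crowds slow-growing species into a corner of the search space);
`t_anchor` wraps circularly. Default search box: `L∞` in
`[0.9, 1.3] ×` the largest occupied bin's upper edge, `k ∈ [0.01, 1]`.
Fits are deterministic for a fixed seed.

The bootstrap redraws every monthly column as a multinomial with that
column's total (months are fixed design points, so whole-column resampling
is not used), refits each replicate, and reports per-parameter means and
2.5/97.5 percentile intervals. The pipeline's downstream stages use the
**bagged** (bootstrap-mean) `L∞` and `k` rather than the single best fit:
the ELEFAN score surface has a long flat ridge in `(L∞, k)` along which a
single fit lands noisily, and averaging over resample refits was markedly
more stable in our synthetic experiments (catch-curve Z from bagged
parameters tracked the simulated truth within a few percent where single
fits erred by 30–40%).

## Catch curve

Monthly columns are pooled. For each occupied bin strictly below `L∞`:
relative age `tᵢ` from the inverse VBGF at the bin midpoint, residence
time `Δtᵢ = (1/k) ln((L∞ − Lᵢ,lower)/(L∞ − Lᵢ,upper))`, response
`ln(Nᵢ/Δtᵢ)`. Automatic limb selection regresses from the bin after the
global maximum of the response to the last occupied bin whose upper edge is
below `0.95 L∞`; an explicit index range can override. `Z = −slope`, with a
normal-approximation 0.95 CI from the slope's SE. Bins reaching `L∞` are
excluded with a warning; fewer than three usable points is an error.

## Empirical natural mortality

Thirteen estimators are evaluated exactly as published, each with its
historical unit convention: Pauly's temperature formula takes `L∞` in
**cm** with base-10 logs; the Then growth formula takes `L∞` in **mm**
(only that convention reproduces its tabulated value); the `c/tmax` and
`c·k` families are unit-free. The suite mean is the arithmetic mean of all
thirteen. The linear-in-k estimator `M = −0.1778 + 3.1687 k` can go
negative for very slow growth; the value is retained and flagged rather
than dropped. Two published values for this species cannot be regenerated
from their printed inputs under the published formulas — the temperature
formula evaluates to ≈0.30 (not 0.45) and the exponential-decay formula,
which algebraically reduces to ≈1.41 k when `tmax = 3/k`, to ≈0.10 (not
0.18). The implementation is formula-faithful and reports the recomputed
values; the same applies to φ′ printed from rounded inputs (3.34/3.19/3.24
recomputed vs 3.32/3.32/3.26 printed) and to `E = F/Z` from rounded
`F = 0.06, Z = 0.19` (0.316, printed 0.33). These are upstream rounding
artefacts, not model disagreements.

## Selectivity

Bins left of the catch-curve regression range are treated as incompletely
selected. Expected fully-selected counts come from back-extrapolating the
regression (`N̂ᵢ = e^(a + b tᵢ) Δtᵢ`); capture probability is
`Pᵢ = min(Nᵢ/N̂ᵢ, 1)`, and bins in or beyond the regression range get
`P = 1`. The ogive is a logit-linear least-squares fit
`ln(1/P − 1) = s1 − s2 L` over bins with `0 < P < 1` (at least three
required; `s2 > 0` required). `L50 = s1/s2`, `L25/75 = (s1 ∓ ln 3)/s2`; the
ogive is symmetric on the logit scale. `tc` is the inverse-VBGF age at
`L50`, evaluated with the same growth parameters as the catch curve.

## Per-recruit analysis

Knife-edge mode uses the Beverton–Holt relative formulation with
`U = 1 − Lc/L∞` and `m = (1 − E)/(M/k)`:

    Y′/R = E U^(M/k) [1 − 3U/(1+m) + 3U²/(1+2m) − U³/(1+3m)]
    B/B₀ = (1 − E) · bracket(E)/bracket(0)

where `bracket` is the cubic factor. `B/B₀` is 1 at `E = 0` and strictly
decreasing. Reference points: `Emax` maximises `Y′/R` (grid step 1e-3,
refined by bounded scalar minimisation to 1e-9; if the curve is still
rising at `E = 1`, `Emax = 1` with a warning and `Fmax` is reported as
null); `E10` solves `dY′/dE = 0.1 × dY′/dE|₀` (central differences,
`h = 1e-5`, smallest root, bracketed on the grid and refined by Brent);
`E50` solves `B/B₀ = ½` (Brent, tolerance 1e-6). `F = E·M/(1−E)` and
`E = F/(F+M)` are exact mutual inverses.

The length-structured mode integrates survival through length classes
(default 0.5 mm) under an arbitrary selection curve: `Zᵢ = M + F sᵢ`,
survivors decay by `e^(−Zᵢ Δtᵢ)`, catch accrues as
`(F sᵢ/Zᵢ) Nᵢ (1 − e^(−Zᵢ Δtᵢ))`, weight-at-length is `a L^b`, and the
terminal class absorbs survivors. With a step ogive and isometric weight it
is proportional to the knife-edge closed form (within 1% at 0.5-mm
classes). The two modes disagree about how the reference points move with
`Lc`: under knife-edge selection `E10` and `Emax` increase with `Lc`
(a later first capture flattens the yield curve), whereas ogive-based
integration — the mode the original software for this assessment family
evidently used — can give the opposite ordering. Both modes are exposed in
the pipeline report so the question can be examined directly; the E-type
reference values themselves are model-mode dependent and should be read
accordingly.

## Survey statistics

CPUE is individuals per trap per set; sets are grouped into 20-m depth
strata over 0–240 m, summarised as mean ± 1.96·SE, and compared by Welch's
heteroscedastic F test (weights `nⱼ/sⱼ²`) with pairwise Welch t tests and
Bonferroni correction rendered as a compact letter display. Sex ratios use
the two-cell χ² against 1:1, reported as males per female. Length–weight
`WW = a·CL^b` is fitted by OLS on natural logs (the intercept is
back-transformed without bias correction); isometry is a t test of
`b = 3` with `n − 2` df; the between-sex comparison is an ANCOVA
(`ln WW ~ ln CL × sex`): interaction F test for slope homogeneity, then a
common-slope model for the sex offset with its 0.95 CI. Records of unknown
sex enter all length-based analyses and are excluded from sex-specific ones.
Report rounding is half-up: lengths 0.1 mm, rates 2 decimals.

## Synthetic survey

The generator emulates an 8-month (July–February) trap survey: 550 sets of
15 traps over 40–222 m, ~6% of sets invalidated, about 1100 animals caught.
Individuals have truncated-exponential ages (rate Z = 0.19/yr on
(0, tmax]), birth dates snapped to annual pulses (SD 0.15 yr),
per-individual lognormal `L∞` (mean 176.76 mm, CV 5%), k = 0.07/yr, a
depth preference drawn from a stratum density profile peaking at 80–120 m
and shifted so smaller animals sit deeper, a logistic sex model in length
and depth calibrated to a female-biased catch near 0.6 males per female,
and sex-specific length–weight laws (males a = 0.002, b = 2.839; females
a = 0.003, b = 2.769; lognormal σ = 0.1). The gear ogive has L50 =
101.65 mm with L75 = 110 mm, chosen so the catch of sub-40-mm juveniles is
negligible, as in a real trap survey of this species. Set catch counts are
Poisson with mean proportional to the *local retained abundance* (each
individual occupies depths around its preference under a normalised 25-m
Gaussian kernel), so a fully non-selective gear samples the population's
length structure without bias — the property the generator's equivalence
test checks. `make_lfq_fixture` is a faster shortcut for unit tests that
draws lengths directly from the cohort mixture with sharper pulses
(SD 0.05 yr) and no survey layer.

What the simulator does **not** emulate: moulting (growth is continuous,
not stepwise), movement and seasonal migration, recruitment variability
between years, sex-specific growth, environmental effects on catchability,
and measurement error beyond 0.1-mm rounding. Passing recovery tests on
this substrate therefore show internal consistency of the estimation chain
under its own assumptions, not robustness to the ways real crustacean data
violate them.

## Known limitations

* **ELEFAN's `L∞` is weakly identified and biased low on these data.** The
  score surface has a flat ridge trading `L∞` against `k`, and the sparse
  near-asymptote bins (old cohorts are rare) penalise the true curve, so
  the global score optimum sits ~5–12% below the true `L∞` on synthetic
  surveys with 5% individual growth variability. Bagging over bootstrap
  refits stabilises, but does not remove, this bias; catch-curve `Z` and
  the `E`-reference points are much less sensitive to it than `k` itself.
* With gear-truncated catches (few animals below `Lc`) the growth signal is
  weak and single GA fits can wander; use the bootstrap/bagged output, not
  a single fit.
* The empirical-M mean depends on which estimators are in the suite; the
  thirteen used here follow the published assessment, and the mean at the
  published growth inputs is 0.11/yr (the published average, 0.13/yr,
  includes the two irreproducible rows discussed above).
* The knife-edge and ogive per-recruit modes answer slightly different
  questions; reference points should not be mixed across modes.
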