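"""Between-group inference for small animal cohorts.

Group comparisons use the Mann–Whitney U test (nonparametric, no normality
assumption) with the tie-corrected, continuity-corrected normal approximation
as the default p-value method for all sample sizes; an exact-enumeration mode
is available for verification at small n. Effect sizes are Cohen's d with a
pooled standard deviation and a large-sample 95% confidence interval.

Interval-level comparisons over TGR matrices report per-group medians and
IQRs alongside U, p and d. Multiplicity corrections (Bonferroni and
Benjamini–Hochberg) are attached exclusively to diagonal intervals — the
consecutive-day rates that share no measurement and therefore satisfy the
independence assumptions of those procedures; off-diagonal intervals overlap
and are reported uncorrected by design.

Power assessment resamples random subsets of each group without replacement
and contrasts two analysis routes on each subset: conventional (per-day
Mann–Whitney tests; power = mean fraction of days with p < 0.05) and
exponential (Mann–Whitney on fitted growth rates after R² filtering; power =
percent of surviving subsets reaching p < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from tgrkit.growth import FitConfig, GrowthFit, fit_exponential
from tgrkit.matrix import TGRMatrix
from tgrkit.model import InsufficientDataError, Study


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "asymptotic",
    continuity: bool = True,
) -> tuple[float, float]:
    """Mann–Whitney U statistic for sample ``a`` and a two-sided p-value.

    ``method="asymptotic"`` (default) uses the normal approximation with tie
    correction (and, by default, continuity correction) at every sample size;
    ``method="exact"`` enumerates the null distribution (no ties) for
    verification. Note that with 3 animals per group no two-sided
    continuity-corrected approximate p can fall below 0.081, and no exact p
    below 0.1 — groups that small cannot reach 0.05 significance here.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = _st.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=continuity,
    )
    return float(res.statistic), float(res.pvalue)


def cohens_d(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, tuple[float, float]]:
    """Cohen's d = (mean_a − mean_b)/pooled SD with a 95% CI.

    Pooled SD weights the sample variances by (n−1). The CI is the
    large-sample normal interval d ± 1.96·sqrt((n_a+n_b)/(n_a·n_b) +
    d²/(2(n_a+n_b−2))). Identical pooled-zero-variance samples give d = 0;
    zero pooled SD with unequal means signals an infinite effect.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled_var = (
        (na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)
    ) / (na + nb - 2)
    diff = float(np.mean(a) - np.mean(b))
    if pooled_var == 0:
        if diff == 0:
            return 0.0, (0.0, 0.0)
        d = math.copysign(math.inf, diff)
        return d, (d, d)
    d = diff / math.sqrt(pooled_var)
    se = math.sqrt((na + nb) / (na * nb) + d * d / (2 * (na + nb - 2)))
    return d, (d - 1.96 * se, d + 1.96 * se)


def effect_size_label(d: float) -> str:
    """Conventional magnitude label: small 0.2–0.5, medium 0.5–0.8, large ≥ 0.8."""
    m = abs(d)
    if m >= 0.8:
        return "large"
    if m >= 0.5:
        return "medium"
    if m >= 0.2:
        return "small"
    return "negligible"


def percent_reduction(r_treated: float, r_control: float) -> float:
    """Growth-rate reduction of treated vs control in percent: 100·(1 − r_t/r_c)."""
    if r_control == 0:
        raise ValueError("control rate must be nonzero")
    return 100.0 * (1.0 - r_treated / r_control)


@dataclass
class GroupComparison:
    """Whole-study growth-rate comparison between two groups (treated − control
    orientation for d)."""

    n_valid_a: int
    n_valid_b: int
    mean_r_a: float
    mean_r_b: float
    median_r_a: float
    median_r_b: float
    U: float
    p: float
    d: float
    d_ci: tuple[float, float]
    d_label: str


def compare_growth_rates(
    group_a_fits: Sequence[GrowthFit],
    group_b_fits: Sequence[GrowthFit],
    config: FitConfig | None = None,
) -> GroupComparison:
    """Compare fitted growth rates of two groups after R² validity filtering.

    Group a is conventionally the treated group so that d < 0 and a positive
    percent reduction both mean slower growth under treatment.
    """
    config = config or FitConfig()
    ra = [f.r for f in group_a_fits if f is not None and f.valid]
    rb = [f.r for f in group_b_fits if f is not None and f.valid]
    if len(ra) < 2 or len(rb) < 2:
        raise InsufficientDataError(
            f"need ≥2 valid fits per group (got {len(ra)}, {len(rb)})"
        )
    U, p = mann_whitney_u(ra, rb)
    d, ci = cohens_d(ra, rb)
    return GroupComparison(
        n_valid_a=len(ra), n_valid_b=len(rb),
        mean_r_a=float(np.mean(ra)), mean_r_b=float(np.mean(rb)),
        median_r_a=float(np.median(ra)), median_r_b=float(np.median(rb)),
        U=U, p=p, d=d, d_ci=ci, d_label=effect_size_label(d),
    )


@dataclass
class IntervalComparison:
    """Between-group test of one TGR interval r_{x→y}."""

    interval: tuple[float, float]
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    U: float
    p: float
    d: float
    d_ci: tuple[float, float]
    diagonal: bool
    p_bonferroni: Optional[float] = None
    q_bh: Optional[float] = None


def compare_interval(
    matrices_a: Sequence[TGRMatrix],
    matrices_b: Sequence[TGRMatrix],
    x_day: float,
    y_day: float,
    grid: Optional[Sequence[float]] = None,
) -> IntervalComparison:
    """Compare per-animal localized rates r_{x→y} between two groups.

    Statistics always run on individual-animal rates (never on group
    aggregates). The interval is diagonal when y is the immediate successor
    of x in the day grid; only diagonal comparisons later receive
    multiplicity corrections.
    """
    key = (x_day, y_day)
    ra = [m.rates[key] for m in matrices_a if key in m.rates]
    rb = [m.rates[key] for m in matrices_b if key in m.rates]
    if len(ra) < 2 or len(rb) < 2:
        raise InsufficientDataError(
            f"interval {x_day}→{y_day}: need ≥2 animals per group "
            f"(got {len(ra)}, {len(rb)})"
        )
    if grid is None:
        grid = matrices_a[0].days
    grid = sorted(grid)
    diagonal = (
        x_day in grid
        and y_day in grid
        and grid.index(y_day) == grid.index(x_day) + 1
    )
    U, p = mann_whitney_u(ra, rb)
    d, ci = cohens_d(ra, rb)

    def _iqr(v):
        q1, q3 = np.percentile(v, [25, 75])
        return float(q3 - q1)

    return IntervalComparison(
        interval=key, n_a=len(ra), n_b=len(rb),
        median_a=float(np.median(ra)), median_b=float(np.median(rb)),
        iqr_a=_iqr(ra), iqr_b=_iqr(rb),
        U=U, p=p, d=d, d_ci=ci, diagonal=diagonal,
    )


def correct_diagonal(
    comparisons: Sequence[IntervalComparison],
) -> list[IntervalComparison]:
    """Attach Bonferroni and Benjamini–Hochberg corrections to diagonal intervals.

    Off-diagonal intervals share measurements and violate the independence
    assumptions of both procedures, so passing one is a contract error.
    Bonferroni multiplies by the family size and caps at 1; BH q-values are
    the standard step-up values (monotone by construction).
    """
    comparisons = list(comparisons)
    for c in comparisons:
        if not c.diagonal:
            raise ValueError(
                f"interval {c.interval} is not diagonal; corrections apply "
                "to consecutive-day intervals only"
            )
    if not comparisons:
        return []
    pvals = np.array([c.p for c in comparisons])
    bonf = np.minimum(pvals * len(pvals), 1.0)
    _, q_bh, _, _ = multipletests(pvals, method="fdr_bh")
    for c, pb, q in zip(comparisons, bonf, q_bh):
        c.p_bonferroni = float(pb)
        c.q_bh = float(q)
    return comparisons


def compare_all_intervals(
    matrices_a: Sequence[TGRMatrix],
    matrices_b: Sequence[TGRMatrix],
    grid: Sequence[float],
) -> list[IntervalComparison]:
    """Every testable interval on the grid, with diagonal corrections attached."""
    out: list[IntervalComparison] = []
    grid = sorted(grid)
    for i, x in enumerate(grid):
        for y in grid[i + 1:]:
            try:
                out.append(compare_interval(matrices_a, matrices_b, x, y, grid))
            except InsufficientDataError:
                continue
    correct_diagonal([c for c in out if c.diagonal])
    return out


@dataclass
class PowerResult:
    """Resampling power estimate for one (n_a, n_b) scenario."""

    n_a: int
    n_b: int
    n_subsets: int
    n_valid: int
    power_conventional: float
    power_exponential: float
    r2_threshold: float
    seed: int
    alpha: float = 0.05


def assess_power(
    study: Study,
    group_a: str,
    group_b: str,
    n_a: int,
    n_b: int,
    n_subsets: int = 20,
    seed: int = 0,
    config: FitConfig | None = None,
    alpha: float = 0.05,
) -> PowerResult:
    """Estimate statistical power of both analysis routes by subset resampling.

    For each of ``n_subsets`` seeded draws (without replacement within each
    group, independent across subsets — repeated subsets are possible):

    * conventional — a two-sided Mann–Whitney test at every study day where
      both subset groups have ≥ 2 measured animals; the subset's score is the
      fraction of tested days with p < alpha. Power is the mean score × 100.
    * exponential — per-animal fits filtered at the R² threshold; subsets
      with < 2 valid animals in either group are excluded; the rest are
      scored significant/nonsignificant by a Mann–Whitney test on the rates.
      Power is 100 × significant/valid subsets.
    """
    config = config or FitConfig()
    if n_subsets < 1:
        raise ValueError("n_subsets must be at least 1")
    animals_a = study.group(group_a)
    animals_b = study.group(group_b)
    if n_a > len(animals_a) or n_b > len(animals_b):
        raise ValueError(
            f"requested subset sizes ({n_a}, {n_b}) exceed availability "
            f"({len(animals_a)}, {len(animals_b)})"
        )
    rng = np.random.default_rng(seed)
    day_fractions: list[float] = []
    n_valid = 0
    n_significant = 0

    for _ in range(n_subsets):
        sub_a = [animals_a[i] for i in rng.choice(len(animals_a), n_a, replace=False)]
        sub_b = [animals_b[i] for i in rng.choice(len(animals_b), n_b, replace=False)]

        # conventional: per-day tests on available animals
        days = sorted(
            {m.day for a in sub_a for m in a.usable_measurements()}
            & {m.day for a in sub_b for m in a.usable_measurements()}
        )
        tested = 0
        hits = 0
        for day in days:
            va = [m.value for a in sub_a for m in a.usable_measurements() if m.day == day]
            vb = [m.value for a in sub_b for m in a.usable_measurements() if m.day == day]
            if len(va) < 2 or len(vb) < 2:
                continue
            _, p = mann_whitney_u(va, vb)
            tested += 1
            hits += p < alpha
        if tested:
            day_fractions.append(hits / tested)

        # exponential: rate comparison after validity filtering
        ra = [
            f.r for a in sub_a
            if (f := fit_exponential(a, config)) is not None and f.valid
        ]
        rb = [
            f.r for a in sub_b
            if (f := fit_exponential(a, config)) is not None and f.valid
        ]
        if len(ra) < 2 or len(rb) < 2:
            continue
        n_valid += 1
        _, p = mann_whitney_u(ra, rb)
        n_significant += p < alpha

    return PowerResult(
        n_a=n_a, n_b=n_b, n_subsets=n_subsets, n_valid=n_valid,
        power_conventional=100.0 * float(np.mean(day_fractions)) if day_fractions else 0.0,
        power_exponential=100.0 * n_significant / n_valid if n_valid else 0.0,
        r2_threshold=config.r2_threshold, seed=seed, alpha=alpha,
    )


def exact_mann_whitney_p(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney p by full enumeration of rank assignments.

    Brute-force reference for tie-free small samples: enumerates every
    ``choose(n_a+n_b, n_a)`` split of the pooled sample and counts splits with
    a U statistic at least as extreme (two-sided, via min(U_a, U_b)).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    na = len(a)

    def u_of(sample_a, sample_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b
        )

    u_obs = u_of(a, b)
    u_min_obs = min(u_obs, na * len(b) - u_obs)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        sel = set(idx)
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u = u_of(sa, sb)
        total += 1
        if min(u, na * len(sb) - u) <= u_min_obs + 1e-12:
            count += 1
    return u_obs, count / total
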