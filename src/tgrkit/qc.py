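"""Automated quality control: homogeneity scoring, outlier detection, filtering.

Homogeneity of a group is scored from the coefficient of variation of
baseline values (each animal's first positive recorded measurement) through a
piecewise-linear base score with excellent/poor thresholds ε=15 and π=30,
multiplied by small-sample penalty factors. The base score is implemented
verbatim as published and is deliberately discontinuous at CV = π: the score
is 80 at CV = 30 but jumps to just under 100 immediately above. This is
documented rather than silently "fixed".

Outliers are found by six criteria with fixed severities, applied per point
or per animal, using IQR fences on log-transformed data. Sensitivity adapts
to group size: small groups get wide fences (4× IQR) and lax per-day change
limits so that scarce animals are not excluded lightly; large groups get
tight fences (2× IQR). Quartiles use the linear-interpolation convention
(numpy default, type 7) — fence positions depend on this choice.

Filtering is non-destructive: points are marked excluded, never deleted, and
three modes are offered — complete (no filtering), animal-level (whole
animals with selected-severity flags removed), and point-level (flagged
points excluded, animals kept while ≥ 3 valid points remain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _st

from tgrkit.model import AnimalSeries, InsufficientDataError, Study


# --------------------------------------------------------------------------
# homogeneity scoring
# --------------------------------------------------------------------------

@dataclass
class HomogeneityConfig:
    """Thresholds for the homogeneity quality score.

    ``epsilon`` — CV (%) at or below which baseline spread is excellent
    (score 100). ``pi`` — CV (%) above which the score decays twice as fast
    toward 0. ``s_small``/``s_verysmall`` — multiplicative penalties applied
    when fewer than 5 (resp. 3) animals contribute a baseline.
    """

    epsilon: float = 15.0
    pi: float = 30.0
    s_small: float = 0.9
    s_verysmall: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < self.pi:
            raise ValueError("need 0 < epsilon < pi")
        if not (0 < self.s_small <= 1 and 0 < self.s_verysmall <= 1):
            raise ValueError("sample-size factors must lie in (0, 1]")


@dataclass
class HomogeneityReport:
    """Homogeneity score for one group at one assessment stage."""

    cv: float
    n: int
    base_score: float
    factor: float
    score: float
    stage: str  # "pre_filter" | "post_filter"


def baseline_cv(group: Sequence[AnimalSeries]) -> tuple[float, int]:
    """Coefficient of variation (%) of the group's baseline values.

    The baseline is each animal's first positive recorded measurement;
    animals with no positive value are excluded. Sample SD (ddof=1) is used;
    a single contributing animal yields CV 0.
    """
    if not group:
        raise InsufficientDataError("empty group")
    baselines = [
        b for a in group if (b := a.first_positive_value()) is not None
    ]
    if not baselines:
        raise InsufficientDataError("no positive baseline values in group")
    n = len(baselines)
    if n == 1:
        return 0.0, 1
    mean = float(np.mean(baselines))
    sd = float(np.std(baselines, ddof=1))
    return 100.0 * sd / mean, n


def homogeneity_base_score(cv: float, config: HomogeneityConfig | None = None) -> float:
    """Piecewise-linear base score on [0, 100] from the baseline CV (%).

    cv ≤ ε → 100; ε < cv ≤ π → 95 − (cv − ε); cv > π → max(0, 100 − 2(cv − π)).
    Discontinuous at cv = π by construction (see module docstring).
    """
    config = config or HomogeneityConfig()
    if cv < 0:
        raise ValueError("CV must be non-negative")
    if cv <= config.epsilon:
        return 100.0
    if cv <= config.pi:
        return 95.0 - (cv - config.epsilon)
    return max(0.0, 100.0 - 2.0 * (cv - config.pi))


def sample_size_factor(n: int, config: HomogeneityConfig | None = None) -> float:
    """Small-sample penalty: ×s_small when n<5, additionally ×s_verysmall when n<3."""
    config = config or HomogeneityConfig()
    if n < 1:
        raise ValueError("n must be at least 1")
    factor = 1.0
    if n < 5:
        factor *= config.s_small
    if n < 3:
        factor *= config.s_verysmall
    return factor


def assess_homogeneity(
    group: Sequence[AnimalSeries],
    config: HomogeneityConfig | None = None,
    stage: str = "pre_filter",
) -> HomogeneityReport:
    """Score one group's baseline homogeneity (run before AND after filtering)."""
    config = config or HomogeneityConfig()
    cv, n = baseline_cv(group)
    base = homogeneity_base_score(cv, config)
    factor = sample_size_factor(n, config)
    return HomogeneityReport(
        cv=cv, n=n, base_score=base, factor=factor,
        score=base * factor, stage=stage,
    )


# --------------------------------------------------------------------------
# outlier detection
# --------------------------------------------------------------------------

class Criterion(Enum):
    IMPOSSIBLE_VALUE = "IMPOSSIBLE_VALUE"
    EXTREME_GROWTH = "EXTREME_GROWTH"
    EXTREME_DECLINE = "EXTREME_DECLINE"
    INTRA_OUTLIER = "INTRA_OUTLIER"
    GROUP_OUTLIER = "GROUP_OUTLIER"
    LAST_DAY_DROP = "LAST_DAY_DROP"


class Severity(Enum):
    critical = 3
    high = 2
    medium = 1


#: severity is fixed by criterion
SEVERITY_OF: Mapping[Criterion, Severity] = {
    Criterion.IMPOSSIBLE_VALUE: Severity.critical,
    Criterion.EXTREME_GROWTH: Severity.critical,
    Criterion.EXTREME_DECLINE: Severity.critical,
    Criterion.INTRA_OUTLIER: Severity.high,
    Criterion.GROUP_OUTLIER: Severity.medium,
    Criterion.LAST_DAY_DROP: Severity.medium,
}


@dataclass(frozen=True)
class OutlierFlag:
    """One QC finding. ``day`` is None for whole-animal flags."""

    animal_id: str
    criterion: Criterion
    severity: Severity
    day: Optional[float] = None
    detail: str = ""


@dataclass(frozen=True)
class SensitivityProfile:
    """Detection sensitivity tier, normally selected from group size."""

    level: str
    iqr_multiplier: float
    growth_limit_pct_per_day: float
    decline_limit_pct_per_day: float
    require_multiple_indicators: bool
    last_day_drop_pct_per_day: float = 50.0


ULTRA_CONSERVATIVE = SensitivityProfile(
    "ultra_conservative", 4.0, 5000.0, 90.0, True)
CONSERVATIVE = SensitivityProfile("conservative", 3.0, 2500.0, 80.0, False)
MODERATE = SensitivityProfile("moderate", 2.0, 1000.0, 67.0, False)


def select_sensitivity(n: int, preset: str = "detector") -> SensitivityProfile:
    """Pick the sensitivity tier from the number of animals in the group.

    ``preset="detector"`` (default): n<5 ultra-conservative (4× IQR),
    5–10 conservative (3×), >10 moderate (2×). ``preset="coarse"`` uses the
    alternative cut points n<8 / 8–12 / >12 with the same three profiles.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if preset == "detector":
        cuts = (5, 10)
    elif preset == "coarse":
        cuts = (8, 12)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    if n < cuts[0]:
        return ULTRA_CONSERVATIVE
    if n <= cuts[1]:
        return CONSERVATIVE
    return MODERATE


#: absolute slack on log-scale fences so exactly-collinear data (zero IQR)
#: are not flagged for float rounding noise
_FENCE_TOL = 1e-9


def _iqr_fences(values: np.ndarray, k: float) -> tuple[float, float]:
    """median ± k·IQR with type-7 (linear interpolation) quartiles."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return med - k * iqr - _FENCE_TOL, med + k * iqr + _FENCE_TOL


def _per_day_fold(n_prev: float, n_next: float, dt: float) -> float:
    """Per-day fold change f with N_next = N_prev · f^dt."""
    return (n_next / n_prev) ** (1.0 / dt)


def detect_outliers(
    study: Study,
    profiles: Optional[Mapping[str, SensitivityProfile]] = None,
) -> list[OutlierFlag]:
    """Run the six-criteria detector over every animal and measurement.

    ``profiles`` maps group name → :class:`SensitivityProfile`; groups not
    listed get a tier selected automatically from their size. The detector is
    total: a criterion that lacks sufficient data is silently skipped.

    Criteria (severity):
      1. IMPOSSIBLE_VALUE (critical) — value ≤ 0.
      2. EXTREME_GROWTH (critical) — per-day growth above the tier limit.
      3. EXTREME_DECLINE (critical) — per-day decline above the tier limit.
      4. INTRA_OUTLIER (high) — log residual from the animal's Theil–Sen
         trend outside median ± k·IQR of its residuals.
      5. GROUP_OUTLIER (medium) — log value at a day outside the group's
         median ± k·IQR at that day.
      6. LAST_DAY_DROP (medium) — final-interval per-day decline > 50 %/day
         with no earlier declining interval.
    """
    profiles = dict(profiles or {})
    for g in study.group_names:
        if g not in profiles:
            profiles[g] = select_sensitivity(len(study.group(g)))

    flags: list[OutlierFlag] = []

    for animal in study.animals:
        prof = profiles[animal.group]
        ms = [m for m in animal.measurements if not m.excluded]

        # 1. impossible values
        for m in ms:
            if m.value <= 0:
                flags.append(OutlierFlag(
                    animal.animal_id, Criterion.IMPOSSIBLE_VALUE,
                    Severity.critical, m.day,
                    f"value {m.value!r} ≤ 0"))

        pos = [m for m in ms if m.value > 0]

        # 2–3. extreme per-day growth / decline on consecutive usable pairs
        for prev, nxt in zip(pos, pos[1:]):
            dt = nxt.day - prev.day
            if dt <= 0:
                continue
            f = _per_day_fold(prev.value, nxt.value, dt)
            growth_pct = 100.0 * (f - 1.0)
            decline_pct = 100.0 * (1.0 - f)
            if growth_pct > prof.growth_limit_pct_per_day:
                flags.append(OutlierFlag(
                    animal.animal_id, Criterion.EXTREME_GROWTH,
                    Severity.critical, nxt.day,
                    f"{growth_pct:.0f} %/day > {prof.growth_limit_pct_per_day:.0f}"))
            elif decline_pct > prof.decline_limit_pct_per_day:
                flags.append(OutlierFlag(
                    animal.animal_id, Criterion.EXTREME_DECLINE,
                    Severity.critical, nxt.day,
                    f"{decline_pct:.0f} %/day > {prof.decline_limit_pct_per_day:.0f}"))

        # 4. intra-animal residual outliers about a robust trend
        if len(pos) >= 4:
            t = np.array([m.day for m in pos])
            ln = np.log([m.value for m in pos])
            slope, intercept, *_ = _st.theilslopes(ln, t)
            resid = ln - (intercept + slope * t)
            lo, hi = _iqr_fences(resid, prof.iqr_multiplier)
            for m, res in zip(pos, resid):
                if res < lo or res > hi:
                    flags.append(OutlierFlag(
                        animal.animal_id, Criterion.INTRA_OUTLIER,
                        Severity.high, m.day,
                        f"log residual {res:.3f} outside [{lo:.3f}, {hi:.3f}]"))

        # 6. abrupt drop confined to the final interval
        if len(pos) >= 3:
            declines = []
            for prev, nxt in zip(pos, pos[1:]):
                dt = nxt.day - prev.day
                declines.append(100.0 * (1.0 - _per_day_fold(prev.value, nxt.value, dt)))
            if (
                declines[-1] > prof.last_day_drop_pct_per_day
                and all(d <= 0 for d in declines[:-1])
            ):
                flags.append(OutlierFlag(
                    animal.animal_id, Criterion.LAST_DAY_DROP,
                    Severity.medium, pos[-1].day,
                    f"final-interval decline {declines[-1]:.0f} %/day"))

    # 5. group-level outliers at each shared day
    for gname in study.group_names:
        members = study.group(gname)
        prof = profiles[gname]
        day_values: dict[float, list[tuple[str, float]]] = {}
        for a in members:
            for m in a.measurements:
                if not m.excluded and m.value > 0:
                    day_values.setdefault(m.day, []).append(
                        (a.animal_id, math.log(m.value)))
        for day, pairs in day_values.items():
            if len(pairs) < 4:
                continue
            vals = np.array([v for _, v in pairs])
            lo, hi = _iqr_fences(vals, prof.iqr_multiplier)
            for animal_id, v in pairs:
                if v < lo or v > hi:
                    flags.append(OutlierFlag(
                        animal_id, Criterion.GROUP_OUTLIER,
                        Severity.medium, day,
                        f"ln value {v:.3f} outside group fence "
                        f"[{lo:.3f}, {hi:.3f}]"))

    return flags


def exclusion_recommendations(
    flags: Iterable[OutlierFlag],
    profiles: Mapping[str, SensitivityProfile],
    group_of: Mapping[str, str],
) -> list[str]:
    """Animal IDs recommended for whole-animal exclusion.

    Under a tier with ``require_multiple_indicators`` (small samples), an
    animal is recommended only with ≥ 2 distinct criteria or ≥ 1 critical
    flag; otherwise any flag suffices.
    """
    by_animal: dict[str, list[OutlierFlag]] = {}
    for f in flags:
        by_animal.setdefault(f.animal_id, []).append(f)
    recommended = []
    for animal_id, fl in by_animal.items():
        prof = profiles.get(group_of.get(animal_id, ""), MODERATE)
        criteria = {f.criterion for f in fl}
        has_critical = any(f.severity is Severity.critical for f in fl)
        if prof.require_multiple_indicators:
            if len(criteria) >= 2 or has_critical:
                recommended.append(animal_id)
        else:
            recommended.append(animal_id)
    return sorted(recommended)


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

@dataclass
class FilterLog:
    """Record of exclusions applied, for transparent reporting."""

    mode: str
    removed_animals: list[str] = field(default_factory=list)
    excluded_points: list[tuple[str, float]] = field(default_factory=list)
    emptied_groups: list[str] = field(default_factory=list)


def apply_filter(
    study: Study,
    flags: Sequence[OutlierFlag],
    mode: str = "complete",
    severities: Optional[set[Severity]] = None,
    log: Optional[FilterLog] = None,
) -> Study:
    """Apply one of the three analysis modes; never destructive.

    ``complete`` returns a copy unchanged. ``animal_level`` removes whole
    animals carrying any flag with a selected severity. ``point_level`` marks
    flagged points excluded, then drops animals left with fewer than 3 valid
    points. Emptied groups are warned about and kept in ``group_names``.
    """
    import warnings as _w

    if mode not in ("complete", "animal_level", "point_level"):
        raise ValueError(f"unknown filter mode {mode!r}")
    severities = severities or {Severity.critical, Severity.high, Severity.medium}
    out = study.copy()
    if log is None:
        log = FilterLog(mode=mode)
    log.mode = mode

    if mode == "complete":
        return out

    selected = [f for f in flags if f.severity in severities]

    if mode == "animal_level":
        bad = {f.animal_id for f in selected}
        log.removed_animals = sorted(bad)
        out.animals = [a for a in out.animals if a.animal_id not in bad]
    else:  # point_level
        point_flags: dict[str, set[float]] = {}
        whole: set[str] = set()
        for f in selected:
            if f.day is None:
                whole.add(f.animal_id)
            else:
                point_flags.setdefault(f.animal_id, set()).add(f.day)
        kept = []
        for a in out.animals:
            if a.animal_id in whole:
                log.removed_animals.append(a.animal_id)
                continue
            days = point_flags.get(a.animal_id, set())
            for m in a.measurements:
                if m.day in days:
                    m.excluded = True
                    log.excluded_points.append((a.animal_id, m.day))
            if len(a.usable_measurements()) >= 3:
                kept.append(a)
            else:
                log.removed_animals.append(a.animal_id)
        out.animals = kept

    for g in study.group_names:
        if not any(a.group == g for a in out.animals):
            log.emptied_groups.append(g)
            _w.warn(f"filtering emptied group {g!r}", stacklevel=2)
    if not out.animals:
        raise InsufficientDataError("filtering removed every animal")
    return out
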