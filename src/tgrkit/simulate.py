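"""Synthetic cohort generation under the exponential growth model.

Trajectories are generated exactly under the model the analysis assumes:
each animal draws a true rate r and baseline N0, and measurements are
N0·e^{r·t}·ε_t with multiplicative lognormal noise, ln ε_t ~ N(0, σ²) where
σ = sqrt(ln(1 + (cv/100)²)) so that the measurement coefficient of variation
equals ``noise_cv`` percent. Lognormal noise makes log-linear least squares
the maximum-likelihood fit, which is the regime the framework targets.

Optional features exercise the QC and standardization stages: right-censoring
dropout (a humane-endpoint analogue that also yields heterogeneous euthanasia
days and terminal weights), and planted single-point anomalies (10× spikes,
10× drops, non-positive values) whose positions are recorded in the returned
truth table so detectors can be validated against ground truth.

``daskalakis_preset`` mirrors the structure of the public glioma-xenograft
reference dataset: 8 control + 10 treated animals on the 13-day grid
0,3,4,5,6,7,10,11,12,13,14,17,18, with group mean rates 0.257 and 0.175
day⁻¹ (the published filtered estimates) and 20% measurement CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from tgrkit.model import AnimalSeries, Measurement, Study, Unit


@dataclass
class GroupSpec:
    """True-parameter distribution for one experimental group.

    ``r_mean``/``r_sd`` — normal distribution of per-animal true rates
    (day⁻¹). ``n0_gmean``/``n0_gcv_pct`` — lognormal baseline: geometric mean
    in the study unit and geometric CV in percent.
    """

    label: str
    n_animals: int
    r_mean: float
    r_sd: float = 0.0
    n0_gmean: float = 100.0
    n0_gcv_pct: float = 30.0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be at least 1")
        if self.r_sd < 0 or self.n0_gcv_pct < 0 or self.n0_gmean <= 0:
            raise ValueError("invalid group parameter")


@dataclass
class DropoutPlan:
    """Right-censoring: ``fraction`` of animals lose all days after a censor
    day drawn uniformly from [min_day, max_day]."""

    fraction: float
    min_day: float
    max_day: float


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic cohort; deterministic given ``seed``."""

    group_specs: list[GroupSpec]
    schedule: list[float]
    noise_cv: float = 20.0
    dropout: Optional[DropoutPlan] = None
    outlier_plan: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0
    unit: Unit = Unit.volume_mm3
    weight_per_burden: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.group_specs:
            raise ValueError("at least one group required")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if list(self.schedule) != sorted(set(self.schedule)):
            raise ValueError("schedule must be strictly increasing")
        for kind, count in self.outlier_plan:
            if kind not in ("spike", "drop", "nonpositive"):
                raise ValueError(f"unknown outlier kind {kind!r}")
            if count < 0:
                raise ValueError("outlier count must be non-negative")


def _lognormal_sigma(cv_pct: float) -> float:
    return math.sqrt(math.log(1.0 + (cv_pct / 100.0) ** 2))


def simulate_cohort(spec: SyntheticSpec) -> tuple[Study, pd.DataFrame]:
    """Generate a :class:`Study` and its ground-truth table.

    The truth table has one row per animal: true r, true N0, censor day (if
    any) and a semicolon-joined list of planted anomalies ``kind@day``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma_noise = _lognormal_sigma(spec.noise_cv)
    animals: list[AnimalSeries] = []
    truth_rows = []

    for gspec in spec.group_specs:
        sigma_n0 = _lognormal_sigma(gspec.n0_gcv_pct)
        for k in range(gspec.n_animals):
            animal_id = f"{gspec.label}_{k + 1:02d}"
            r_true = float(rng.normal(gspec.r_mean, gspec.r_sd))
            n0_true = float(gspec.n0_gmean * math.exp(rng.normal(0.0, sigma_n0)))
            days = list(spec.schedule)
            censor_day = None
            if spec.dropout is not None and rng.random() < spec.dropout.fraction:
                censor_day = float(
                    rng.uniform(spec.dropout.min_day, spec.dropout.max_day)
                )
                days = [d for d in days if d <= censor_day]
                if len(days) < 2:  # keep at least a stub trajectory
                    days = list(spec.schedule[:2])
                    censor_day = days[-1]
            values = [
                n0_true * math.exp(r_true * d) * math.exp(rng.normal(0.0, sigma_noise))
                for d in days
            ]
            measurements = [Measurement(day=d, value=v) for d, v in zip(days, values)]
            euthanasia_day = days[-1]
            terminal_weight = None
            if spec.weight_per_burden is not None:
                terminal_weight = float(
                    spec.weight_per_burden
                    * n0_true * math.exp(r_true * euthanasia_day)
                    * math.exp(rng.normal(0.0, sigma_noise))
                )
            animals.append(AnimalSeries(
                animal_id=animal_id, group=gspec.label,
                measurements=measurements,
                terminal_weight=terminal_weight,
                euthanasia_day=euthanasia_day,
            ))
            truth_rows.append({
                "animal_id": animal_id, "group": gspec.label,
                "true_r": r_true, "true_N0": n0_true,
                "censor_day": censor_day, "anomalies": "",
            })

    truth = pd.DataFrame(truth_rows).set_index("animal_id")

    # plant anomalies on interior days of randomly chosen animals
    for kind, count in spec.outlier_plan:
        for _ in range(count):
            animal = animals[int(rng.integers(len(animals)))]
            interior = animal.measurements[1:-1]
            if not interior:
                continue
            m = interior[int(rng.integers(len(interior)))]
            if kind == "spike":
                m.value *= 10.0
            elif kind == "drop":
                m.value *= 0.1
            else:
                m.value = -1.0
            prev = truth.at[animal.animal_id, "anomalies"]
            tag = f"{kind}@{m.day:g}"
            truth.at[animal.animal_id, "anomalies"] = (
                f"{prev};{tag}" if prev else tag
            )

    return Study(animals=animals, unit=spec.unit), truth


DASKALAKIS_SCHEDULE: Sequence[float] = (0, 3, 4, 5, 6, 7, 10, 11, 12, 13, 14, 17, 18)


def daskalakis_preset(seed: int = 20250101) -> SyntheticSpec:
    """Cohort spec emulating the public glioma-xenograft reference dataset.

    8 control and 10 treated animals over 13 time points (78 TGR intervals),
    group mean rates 0.257 (control) vs 0.175 (treated) day⁻¹ — a 31.9%
    growth-rate reduction — with 0.04 day⁻¹ between-animal rate SD, baseline
    geometric mean 100 mm³ (30% geometric CV) and 20% measurement CV.
    """
    return SyntheticSpec(
        group_specs=[
            GroupSpec("control", 8, r_mean=0.257, r_sd=0.04),
            GroupSpec("treated", 10, r_mean=0.175, r_sd=0.04),
        ],
        schedule=list(DASKALAKIS_SCHEDULE),
        noise_cv=20.0,
        seed=seed,
    )
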