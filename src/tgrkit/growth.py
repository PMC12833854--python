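"""Exponential growth modelling on the log scale.

The model is N(t) = N0·e^{r·t}. Taking natural logs gives the linear form
ln N = ln N0 + r·t, so ordinary least squares on (t, ln N) is the maximum
likelihood estimator under multiplicative lognormal measurement noise. All
derived quantities (R², standard errors, doubling time ln(2)/r) live on that
log scale; R² is therefore invariant under any unit rescaling of the values,
and r is dimensionally day⁻¹ regardless of the burden unit.

Relative standard errors (RSE = 100·SE/|estimate|) quantify fit precision.
For the intercept, the standard error of ln N0 IS the first-order relative
error of N0, so RSE(N0) = 100·se(ln N0). Uncertainty propagates forward in
time as RSE(N(t)) = sqrt(RSE²(N0) + t²·(100·se_r)²): the growth-rate term
scales quadratically with time because ln N is linear in r·t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _st

from tgrkit.model import AnimalSeries, InsufficientDataError


@dataclass
class FitConfig:
    """Quality-filtering configuration for exponential fits.

    ``r2_threshold`` — log-scale R² a fit must exceed to be ``valid``
    (default 0.8, configurable in [0, 1]). ``min_points`` — minimum positive,
    non-excluded measurements required to attempt a fit (floor 3).
    ``r2_scale`` — scale on which R² is computed: ``"log"`` (default, the
    scale the regression is performed on) or ``"raw"``.
    """

    r2_threshold: float = 0.8
    min_points: int = 3
    r2_scale: str = "log"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.min_points < 3:
            raise ValueError("min_points must be at least 3")
        if self.r2_scale not in ("log", "raw"):
            raise ValueError("r2_scale must be 'log' or 'raw'")


@dataclass
class GrowthFit:
    """Per-animal exponential parameters and their uncertainties."""

    animal_id: str
    N0: float
    se_log_N0: float
    rse_N0: float
    r: float
    se_r: float
    rse_r: float
    r_squared: float
    n_points: int
    valid: bool

    @property
    def doubling_time(self) -> Optional[float]:
        """ln(2)/r in days; undefined (None) for non-growing tumors."""
        if self.r <= 0:
            return None
        return math.log(2.0) / self.r


def fit_exponential(
    series: AnimalSeries, config: FitConfig | None = None
) -> Optional[GrowthFit]:
    """Fit N(t) = N0·e^{rt} by least squares on (t, ln N).

    Uses only positive, non-excluded measurements. Returns ``None`` (not an
    error) when fewer than ``config.min_points`` such points remain — the
    animal is then reported invalid for insufficient data downstream.

    Raises
    ------
    InsufficientDataError
        All usable measurement days identical (degenerate design).
    """
    config = config or FitConfig()
    pts = series.usable_measurements()
    if len(pts) < config.min_points:
        return None
    t = np.array([m.day for m in pts], dtype=float)
    y = np.log([m.value for m in pts])
    if np.ptp(t) == 0:
        raise InsufficientDataError(
            f"animal {series.animal_id!r}: all measurement days identical"
        )

    res = _st.linregress(t, y)
    r = float(res.slope)
    se_r = float(res.stderr)
    log_n0 = float(res.intercept)
    se_log_n0 = float(res.intercept_stderr)

    if config.r2_scale == "log":
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            # constant log-burden: the zero-slope line reproduces the data
            r_squared = 1.0
        else:
            r_squared = float(res.rvalue) ** 2
    else:
        raw = np.exp(y)
        pred = np.exp(log_n0 + r * t)
        ss_res = float(np.sum((raw - pred) ** 2))
        ss_tot = float(np.sum((raw - raw.mean()) ** 2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r_squared = min(max(r_squared, 0.0), 1.0)

    return GrowthFit(
        animal_id=series.animal_id,
        N0=math.exp(log_n0),
        se_log_N0=se_log_n0,
        rse_N0=100.0 * se_log_n0,
        r=r,
        se_r=se_r,
        rse_r=100.0 * se_r / abs(r) if r != 0 else math.inf,
        r_squared=r_squared,
        n_points=len(pts),
        valid=r_squared > config.r2_threshold,
    )


def ellipsoid_volume(length: float, width: float) -> float:
    """Caliper tumor volume V = L·W²/2 (mm³) from length and width (mm).

    Length must be the longer axis; swapped inputs are corrected with a
    warning rather than silently producing the wrong volume.
    """
    if length <= 0 or width <= 0:
        raise ValueError("caliper dimensions must be positive")
    if width > length:
        warnings.warn(
            f"width {width} > length {length}: axes swapped", stacklevel=2
        )
        length, width = width, length
    return length * width * width / 2.0


def propagate_rse(rse_N0: float, se_r_pct: float, t: float) -> float:
    """Forward-propagated relative standard error of N(t), in percent.

    ``se_r_pct`` is the absolute standard error of r expressed in percent
    (100·se_r); its contribution grows linearly in t inside the quadrature,
    i.e. RSE(N(t)) = sqrt(RSE²(N0) + t²·se_r_pct²).
    """
    if rse_N0 < 0 or se_r_pct < 0 or t < 0:
        raise ValueError("propagate_rse inputs must be non-negative")
    return math.sqrt(rse_N0**2 + (t * se_r_pct) ** 2)


def predict_size(fit: GrowthFit, t: float) -> float:
    """Model burden N0·e^{r·t} at study day t, in the study's input unit."""
    return fit.N0 * math.exp(fit.r * t)


def predict_weight(
    terminal_weight: float,
    euthanasia_day: float,
    r: float,
    target_day: float,
) -> float:
    """Standardize a terminal tumor weight to a common study day.

    Carries the measured weight forward (or backward) along the animal's own
    fitted exponential: w(target) = w·e^{r·(target − euthanasia)}. Animals
    euthanized early at humane endpoints can thereby enter a single
    common-day comparison.
    """
    if terminal_weight <= 0:
        raise ValueError("terminal weight must be positive")
    return terminal_weight * math.exp(r * (target_day - euthanasia_day))


def prediction_error(experimental: float, predicted: float) -> float:
    """Absolute relative error in percent: 100·|exp − pred|/exp."""
    if experimental <= 0:
        raise ValueError("experimental weight must be positive")
    return 100.0 * abs(experimental - predicted) / experimental
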