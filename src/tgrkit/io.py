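"""CSV dialects: wide input study table, enhanced results export, TGR export.

The input table is one row per animal with columns ``Animal``, ``Group``, one
column per study day (bare numeric header or ``Day_<x>``/``D<x>``) and an
optional ``Tumor_Weight``. Empty cells are absent measurements; a literal 0 is
a recorded value that quality control will flag. All files are plain UTF-8
CSV with "." decimal marks, and floats are written with ``repr`` precision so
a read → write → read round trip is bit-identical in decimal text.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from typing import Mapping, Optional, Sequence

from tgrkit.model import (
    AnimalSeries,
    FormatError,
    Measurement,
    Study,
    Unit,
    ValidationError,
)

_DAY_HEADER = re.compile(r"^(?:Day[_ ]?|D)?(-?\d+(?:\.\d+)?)$", re.IGNORECASE)

#: columns that are never parsed as time points
_RESERVED = {"animal", "group", "tumor_weight", "euthanasia_day"}


def _parse_day_header(header: str) -> Optional[float]:
    header = header.strip()
    if header.lower() in _RESERVED:
        return None
    m = _DAY_HEADER.match(header)
    return float(m.group(1)) if m else None


def _fmt(x: Optional[float]) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def read_study_csv(path, unit: Unit | str = Unit.volume_mm3) -> Study:
    """Read a wide study table into a :class:`Study`.

    Parameters
    ----------
    path : path-like
        CSV file with mandatory ``Animal`` and ``Group`` columns, time-point
        columns (numeric header or ``Day_<x>``/``D<x>``), and an optional
        ``Tumor_Weight`` column filling each animal's terminal weight.
    unit : Unit or str
        Declared measurement unit for every value in the table.

    Raises
    ------
    FormatError
        Missing ``Animal``/``Group`` column, no parseable time-point column,
        or an unparseable cell (the error names the offending line).
    ValidationError
        Duplicate animal identifiers.
    """
    unit = Unit(unit)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        rows = list(reader)

    lower = [h.strip().lower() for h in header]
    for required in ("Animal", "Group"):
        if required.lower() not in lower:
            raise FormatError(f"{path}: missing required column {required!r}")
    animal_i = lower.index("animal")
    group_i = lower.index("group")
    weight_i = lower.index("tumor_weight") if "tumor_weight" in lower else None
    euth_i = lower.index("euthanasia_day") if "euthanasia_day" in lower else None

    day_cols: list[tuple[int, float]] = []
    for i, h in enumerate(header):
        if i in (animal_i, group_i, weight_i, euth_i):
            continue
        day = _parse_day_header(h)
        if day is not None:
            day_cols.append((i, day))
    if not day_cols:
        raise FormatError(f"{path}: no parseable time-point column in header")

    animals: list[AnimalSeries] = []
    for lineno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue  # blank line
        if len(row) < len(header):
            row = row + [""] * (len(header) - len(row))
        animal_id = row[animal_i].strip()
        group = row[group_i].strip()
        if not animal_id:
            raise FormatError(f"{path}: line {lineno}: empty Animal cell")
        measurements = []
        for i, day in day_cols:
            cell = row[i].strip()
            if cell == "":
                continue
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric value {cell!r} "
                    f"in column {header[i]!r}"
                ) from None
            measurements.append(Measurement(day=day, value=value))
        terminal_weight = None
        if weight_i is not None and row[weight_i].strip():
            terminal_weight = float(row[weight_i])
        euthanasia_day = None
        if euth_i is not None and row[euth_i].strip():
            euthanasia_day = float(row[euth_i])
        elif measurements:
            euthanasia_day = measurements[-1].day
        animals.append(
            AnimalSeries(
                animal_id=animal_id,
                group=group,
                measurements=measurements,
                terminal_weight=terminal_weight,
                euthanasia_day=euthanasia_day,
            )
        )

    ids = [a.animal_id for a in animals]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate animal id(s): {dupes}")
    if not animals:
        raise FormatError(f"{path}: no data rows")
    return Study(animals=animals, unit=unit)


def write_study_csv(study: Study, path) -> None:
    """Write a study back to the wide input dialect (days as bare headers)."""
    days = study.all_days()
    has_weight = any(a.terminal_weight is not None for a in study.animals)
    header = ["Animal", "Group"] + [_fmt(d) for d in days]
    if has_weight:
        header.append("Tumor_Weight")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for a in study.animals:
            by_day = {m.day: m.value for m in a.measurements}
            row = [a.animal_id, a.group] + [
                _fmt(by_day[d]) if d in by_day else "" for d in days
            ]
            if has_weight:
                row.append(_fmt(a.terminal_weight))
            w.writerow(row)


def write_enhanced_csv(
    study: Study,
    fits: Mapping[str, "GrowthFit | None"],
    flags: Sequence["OutlierFlag"] = (),
    predictions: Optional[Mapping[str, float]] = None,
    path=None,
) -> None:
    """Write the enhanced per-animal export.

    One row per animal with the original measurement columns followed by the
    fitted exponential parameters (N0 with relative standard error, growth
    rate r with relative standard error, doubling time ln(2)/r, log-scale R²,
    validity flag), a summary of QC flags, and the standardized predicted
    weight when supplied. Animals without a fit get empty derived cells and a
    ``UserWarning`` is emitted.
    """
    if path is None:
        raise TypeError("path is required")
    days = study.all_days()
    flags_by_animal: dict[str, list] = {}
    for f in flags:
        flags_by_animal.setdefault(f.animal_id, []).append(f)

    header = (
        ["Animal", "Group"]
        + [_fmt(d) for d in days]
        + [
            "N0",
            "RSE_N0_pct",
            "r_per_day",
            "RSE_r_pct",
            "Doubling_Time_days",
            "R2",
            "Valid",
            "N_Points",
            "Outlier_Flags",
        ]
    )
    if predictions is not None:
        header.append("Predicted_Weight_g")

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for a in study.animals:
            by_day = {m.day: m.value for m in a.measurements}
            row = [a.animal_id, a.group] + [
                _fmt(by_day[d]) if d in by_day else "" for d in days
            ]
            fit = fits.get(a.animal_id)
            if fit is None:
                warnings.warn(
                    f"no valid fit for animal {a.animal_id!r}; "
                    "derived columns left empty",
                    stacklevel=2,
                )
                row += [""] * 7
            else:
                dt = fit.doubling_time
                row += [
                    _fmt(fit.N0),
                    _fmt(fit.rse_N0),
                    _fmt(fit.r),
                    _fmt(fit.rse_r),
                    _fmt(dt) if dt is not None else "",
                    _fmt(fit.r_squared),
                    str(fit.valid),
                ]
            row.append(str(fit.n_points) if fit is not None else "")
            aflags = flags_by_animal.get(a.animal_id, [])
            row.append(
                "; ".join(
                    f"{f.criterion.name}[{f.severity.name}]"
                    + (f"@d{_fmt(f.day)}" if f.day is not None else "")
                    for f in aflags
                )
            )
            if predictions is not None:
                pred = predictions.get(a.animal_id)
                row.append(_fmt(pred) if pred is not None else "")
            w.writerow(row)


def write_tgr_csv(matrices: Mapping[str, "TGRMatrix"], study: Study, path) -> None:
    """Write per-animal TGR matrices as a feature-vector CSV.

    Columns: ``Animal_ID``, ``Experimental_Group``, then one column per
    ordered day pair x<y named ``r_<x>_to_<y>``. Intervals an animal lacks
    are written empty.

    Raises
    ------
    ValidationError
        When the matrices do not share a single day grid.
    """
    grids = {tuple(m.days) for m in matrices.values()}
    if len(grids) > 1:
        raise ValidationError("TGR matrices have inconsistent day grids")
    days = list(grids.pop()) if grids else study.all_days()
    pairs = [(x, y) for i, x in enumerate(days) for y in days[i + 1:]]

    def _day_label(d: float) -> str:
        return _fmt(d) if d != int(d) else str(int(d))

    header = ["Animal_ID", "Experimental_Group"] + [
        f"r_{_day_label(x)}_to_{_day_label(y)}" for x, y in pairs
    ]
    group_of = {a.animal_id: a.group for a in study.animals}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for animal_id, matrix in matrices.items():
            row = [animal_id, group_of.get(animal_id, "")]
            for pair in pairs:
                r = matrix.rates.get(pair)
                row.append(_fmt(r) if r is not None else "")
            w.writerow(row)
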