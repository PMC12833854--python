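"""End-to-end analysis orchestration and static report rendering.

``run_full_analysis`` executes the full workflow — validation, pre-filter
homogeneity, outlier detection, filtering, exponential fits, group statistics,
TGR matrices with interval comparisons, optional power assessment and weight
standardization, post-filter homogeneity, exports — and returns a result
bundle. ``render_report`` turns a bundle into a single self-contained HTML
document (no recomputation at render time: every number shown is read from
the bundle). All randomness derives from the configured seed.
"""

from __future__ import annotations

import html
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from tgrkit.growth import FitConfig, GrowthFit, fit_exponential, predict_weight
from tgrkit.io import write_enhanced_csv, write_tgr_csv
from tgrkit.matrix import (
    TGRMatrix,
    aggregate_group_matrix,
    build_animal_matrix,
    classify_rate,
)
from tgrkit.model import InsufficientDataError, Study, Unit
from tgrkit.qc import (
    FilterLog,
    HomogeneityConfig,
    HomogeneityReport,
    OutlierFlag,
    SensitivityProfile,
    Severity,
    apply_filter,
    assess_homogeneity,
    detect_outliers,
    select_sensitivity,
)
from tgrkit.stats import (
    GroupComparison,
    IntervalComparison,
    PowerResult,
    assess_power,
    compare_all_intervals,
    compare_growth_rates,
    percent_reduction,
)

#: five-color display scheme for rate classes
CLASS_COLORS = {
    "high": "#d73027",
    "medium": "#fc8d59",
    "low": "#91cf60",
    "very_low": "#91bfdb",
    "minimal": "#e8e8e8",
}


@dataclass
class RunConfig:
    """Everything a full analysis run needs; mirrors the CLI flags."""

    input_path: str
    unit: Unit = Unit.volume_mm3
    r2_threshold: float = 0.8
    filter_mode: str = "point_level"  # complete | animal_level | point_level
    severities: set[Severity] = field(
        default_factory=lambda: {Severity.critical, Severity.high, Severity.medium}
    )
    sensitivity_override: Optional[SensitivityProfile] = None
    power_scenarios: list[tuple[int, int]] = field(default_factory=list)
    n_subsets: int = 20
    target_day: Optional[float] = None
    output_dir: str = "."
    seed: int = 0


@dataclass
class AnalysisBundle:
    """All results of one run, consumed by exports and the report."""

    config: RunConfig
    study: Study
    filtered_study: Study
    homogeneity_pre: dict[str, HomogeneityReport]
    homogeneity_post: dict[str, HomogeneityReport]
    profiles: dict[str, SensitivityProfile]
    flags: list[OutlierFlag]
    filter_log: FilterLog
    fits: dict[str, Optional[GrowthFit]]
    comparison: Optional[GroupComparison]
    reduction_pct: Optional[float]
    matrices: dict[str, TGRMatrix]
    group_matrices: dict[str, TGRMatrix]
    interval_comparisons: list[IntervalComparison]
    power_results: list[PowerResult]
    predictions: dict[str, float]


def run_full_analysis(config: RunConfig, study: Optional[Study] = None) -> AnalysisBundle:
    """Run the whole workflow on ``config.input_path`` (or a passed study)."""
    from tgrkit.io import read_study_csv

    if study is None:
        study = read_study_csv(config.input_path, config.unit)
    fit_config = FitConfig(r2_threshold=config.r2_threshold)
    hcfg = HomogeneityConfig()

    homog_pre = {
        g: assess_homogeneity(study.group(g), hcfg, stage="pre_filter")
        for g in study.group_names
    }

    profiles = {
        g: config.sensitivity_override or select_sensitivity(len(study.group(g)))
        for g in study.group_names
    }
    flags = detect_outliers(study, profiles)
    log = FilterLog(mode=config.filter_mode)
    filtered = apply_filter(study, flags, config.filter_mode, config.severities, log)

    homog_post = {
        g: assess_homogeneity(filtered.group(g), hcfg, stage="post_filter")
        for g in filtered.group_names
        if filtered.group(g)
    }

    fits: dict[str, Optional[GrowthFit]] = {}
    for animal in filtered.animals:
        try:
            fits[animal.animal_id] = fit_exponential(animal, fit_config)
        except InsufficientDataError:
            fits[animal.animal_id] = None

    comparison = None
    reduction = None
    interval_comparisons: list[IntervalComparison] = []
    grid = filtered.all_days()
    matrices = {
        a.animal_id: build_animal_matrix(a, days=grid) for a in filtered.animals
    }
    group_matrices = {}
    for g in filtered.group_names:
        mats = [matrices[a.animal_id] for a in filtered.group(g)]
        if mats:
            group_matrices[g] = aggregate_group_matrix(mats, "mean", owner=g)

    if len(filtered.group_names) >= 2:
        g_control, g_treated = filtered.group_names[0], filtered.group_names[1]
        fits_t = [fits[a.animal_id] for a in filtered.group(g_treated)
                  if fits.get(a.animal_id)]
        fits_c = [fits[a.animal_id] for a in filtered.group(g_control)
                  if fits.get(a.animal_id)]
        try:
            comparison = compare_growth_rates(fits_t, fits_c, fit_config)
            if comparison.mean_r_b != 0:
                reduction = percent_reduction(comparison.mean_r_a, comparison.mean_r_b)
        except InsufficientDataError:
            comparison = None
        mats_t = [matrices[a.animal_id] for a in filtered.group(g_treated)]
        mats_c = [matrices[a.animal_id] for a in filtered.group(g_control)]
        if mats_t and mats_c:
            interval_comparisons = compare_all_intervals(mats_t, mats_c, grid)

    power_results = []
    if config.power_scenarios and len(filtered.group_names) >= 2:
        g_a, g_b = filtered.group_names[0], filtered.group_names[1]
        for i, (n_a, n_b) in enumerate(config.power_scenarios):
            power_results.append(assess_power(
                filtered, g_a, g_b, n_a, n_b,
                n_subsets=config.n_subsets,
                seed=config.seed + i, config=fit_config,
            ))

    predictions: dict[str, float] = {}
    if config.target_day is not None:
        for animal in filtered.animals:
            fit = fits.get(animal.animal_id)
            if (
                fit is not None and fit.valid
                and animal.terminal_weight is not None
                and animal.euthanasia_day is not None
            ):
                predictions[animal.animal_id] = predict_weight(
                    animal.terminal_weight, animal.euthanasia_day,
                    fit.r, config.target_day,
                )

    return AnalysisBundle(
        config=config, study=study, filtered_study=filtered,
        homogeneity_pre=homog_pre, homogeneity_post=homog_post,
        profiles=profiles, flags=flags, filter_log=log, fits=fits,
        comparison=comparison, reduction_pct=reduction,
        matrices=matrices, group_matrices=group_matrices,
        interval_comparisons=interval_comparisons,
        power_results=power_results, predictions=predictions,
    )


def export_bundle(bundle: AnalysisBundle, output_dir: str | Path) -> dict[str, Path]:
    """Write enhanced CSV, TGR CSV and the HTML report; return their paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    enhanced = out / "enhanced_results.csv"
    tgr = out / "tgr_matrix.csv"
    report = out / "report.html"
    write_enhanced_csv(
        bundle.filtered_study, bundle.fits, bundle.flags,
        predictions=bundle.predictions if bundle.predictions else None,
        path=enhanced,
    )
    write_tgr_csv(bundle.matrices, bundle.filtered_study, tgr)
    report.write_text(render_report(bundle), encoding="utf-8")
    return {"enhanced_csv": enhanced, "tgr_csv": tgr, "report": report}


def _sig3(x: Optional[float]) -> str:
    """Round to 3 significant figures for display."""
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return "—" if x is None else f"{x}"
    if x == 0:
        return "0"
    return f"{x:.3g}"


def _heatmap_html(matrix: TGRMatrix) -> str:
    days = matrix.days
    rows = []
    header = "<tr><th></th>" + "".join(
        f"<th>d{d:g}</th>" for d in days[1:]
    ) + "</tr>"
    for i, x in enumerate(days[:-1]):
        cells = [f"<th>d{x:g}</th>"]
        for y in days[1:]:
            r = matrix.rates.get((x, y))
            if r is None or y <= x:
                cells.append("<td></td>")
            else:
                color = CLASS_COLORS[classify_rate(r)]
                cells.append(
                    f'<td style="background:{color}">{_sig3(r)}</td>'
                )
        rows.append("<tr>" + "".join(cells) + "</tr>")
    return f'<table class="heat">{header}{"".join(rows)}</table>'


def render_report(bundle: AnalysisBundle) -> str:
    """Render the bundle into one self-contained HTML document."""
    cfg = bundle.config
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>Tumor growth analysis report</title>",
        "<style>body{font-family:sans-serif;margin:2em}table{border-collapse:"
        "collapse}td,th{border:1px solid #999;padding:3px 7px;text-align:right}"
        "th{background:#f0f0f0}.heat td{min-width:3em}</style></head><body>",
        "<h1>Tumor growth analysis report</h1>",
    ]

    parts.append("<h2>Homogeneity assessment</h2><table><tr><th>Group</th>"
                 "<th>Stage</th><th>CV %</th><th>n</th><th>Base score</th>"
                 "<th>Factor</th><th>Score</th></tr>")
    for stage, reports in (("pre_filter", bundle.homogeneity_pre),
                           ("post_filter", bundle.homogeneity_post)):
        for g, rep in reports.items():
            parts.append(
                f"<tr><td>{html.escape(g)}</td><td>{stage}</td>"
                f"<td>{_sig3(rep.cv)}</td><td>{rep.n}</td>"
                f"<td>{_sig3(rep.base_score)}</td><td>{_sig3(rep.factor)}</td>"
                f"<td>{_sig3(rep.score)}</td></tr>")
    parts.append("</table>")

    parts.append("<h2>Outlier flags</h2>")
    if bundle.flags:
        parts.append("<table><tr><th>Animal</th><th>Day</th><th>Criterion</th>"
                     "<th>Severity</th><th>Detail</th></tr>")
        for f in bundle.flags:
            day = f"{f.day:g}" if f.day is not None else "—"
            parts.append(
                f"<tr><td>{html.escape(f.animal_id)}</td><td>{day}</td>"
                f"<td>{f.criterion.name}</td><td>{f.severity.name}</td>"
                f"<td>{html.escape(f.detail)}</td></tr>")
        parts.append("</table>")
    else:
        parts.append("<p>none detected</p>")

    parts.append(f"<h2>Exponential fits (R&sup2; threshold {cfg.r2_threshold})</h2>"
                 "<table><tr><th>Animal</th><th>Group</th><th>N0</th>"
                 "<th>RSE(N0) %</th><th>r /day</th><th>RSE(r) %</th>"
                 "<th>Doubling d</th><th>R&sup2;</th><th>Valid</th></tr>")
    for a in bundle.filtered_study.animals:
        fit = bundle.fits.get(a.animal_id)
        if fit is None:
            parts.append(f"<tr><td>{html.escape(a.animal_id)}</td>"
                         f"<td>{html.escape(a.group)}</td>"
                         "<td colspan='7'>invalid — insufficient data</td></tr>")
        else:
            parts.append(
                f"<tr><td>{html.escape(a.animal_id)}</td>"
                f"<td>{html.escape(a.group)}</td><td>{_sig3(fit.N0)}</td>"
                f"<td>{_sig3(fit.rse_N0)}</td><td>{_sig3(fit.r)}</td>"
                f"<td>{_sig3(fit.rse_r)}</td><td>{_sig3(fit.doubling_time)}</td>"
                f"<td>{_sig3(fit.r_squared)}</td><td>{fit.valid}</td></tr>")
    parts.append("</table>")

    if bundle.comparison is not None:
        c = bundle.comparison
        parts.append(
            "<h2>Growth-rate comparison (treated vs control)</h2>"
            f"<p>n valid: {c.n_valid_a} vs {c.n_valid_b}; "
            f"mean r: {_sig3(c.mean_r_a)} vs {_sig3(c.mean_r_b)} day&#8315;&sup1;; "
            f"U = {_sig3(c.U)}, p = {_sig3(c.p)}; "
            f"Cohen's d = {_sig3(c.d)} "
            f"[{_sig3(c.d_ci[0])}, {_sig3(c.d_ci[1])}] ({c.d_label})"
            + (f"; growth-rate reduction {_sig3(bundle.reduction_pct)}%"
               if bundle.reduction_pct is not None else "")
            + "</p>")

    parts.append("<h2>TGR matrices (group means, day&#8315;&sup1;)</h2>")
    for g, gm in bundle.group_matrices.items():
        parts.append(f"<h3>{html.escape(g)}</h3>")
        parts.append(_heatmap_html(gm))
    parts.append(
        "<p>Legend: "
        + " ".join(
            f'<span style="background:{CLASS_COLORS[label]};padding:2px 6px">'
            f"{label}</span>"
            for label, _, _ in
            [("high", 0, 0), ("medium", 0, 0), ("low", 0, 0),
             ("very_low", 0, 0), ("minimal", 0, 0)]
        )
        + " — high r&gt;0.25, medium 0.15–0.25, low 0.10–0.15, "
          "very_low 0.05–0.10, minimal r&lt;0.05 day&#8315;&sup1;</p>")

    if bundle.power_results:
        parts.append("<h2>Power assessment</h2><table><tr><th>n_a</th>"
                     "<th>n_b</th><th>Subsets</th><th>Valid</th>"
                     "<th>Conventional %</th><th>Exponential %</th></tr>")
        for p in bundle.power_results:
            parts.append(
                f"<tr><td>{p.n_a}</td><td>{p.n_b}</td><td>{p.n_subsets}</td>"
                f"<td>{p.n_valid}</td><td>{_sig3(p.power_conventional)}</td>"
                f"<td>{_sig3(p.power_exponential)}</td></tr>")
        parts.append("</table>")

    if bundle.predictions:
        parts.append(
            f"<h2>Standardized tumor weights (day {cfg.target_day:g})</h2>"
            "<table><tr><th>Animal</th><th>Predicted weight g</th></tr>")
        for aid, w in bundle.predictions.items():
            parts.append(f"<tr><td>{html.escape(aid)}</td><td>{_sig3(w)}</td></tr>")
        parts.append("</table>")

    profile_desc = "; ".join(
        f"{html.escape(g)}: {p.level} ({p.iqr_multiplier}× IQR, growth limit "
        f"{p.growth_limit_pct_per_day:g} %/day, decline limit "
        f"{p.decline_limit_pct_per_day:g} %/day)"
        for g, p in bundle.profiles.items())
    parts.append(
        "<hr><h2>Methodology</h2><p>"
        f"Filter mode: {cfg.filter_mode}; "
        f"R&sup2; validity threshold: {cfg.r2_threshold}; "
        f"minimum points per fit: 3; "
        f"sensitivity: {profile_desc}; "
        f"homogeneity thresholds &epsilon;=15, &pi;=30 with small-sample "
        f"factors 0.9 (n&lt;5) and 0.8 (n&lt;3); "
        f"Mann&ndash;Whitney two-sided, tie- and continuity-corrected normal "
        f"approximation; Bonferroni and Benjamini&ndash;Hochberg corrections "
        f"on diagonal intervals only; seed {cfg.seed}.</p>")
    parts.append("</body></html>")
    return "".join(parts)
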