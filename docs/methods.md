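# Methods

## Growth model

Each animal's tumor burden is modelled as exponential,
N(t) = N₀·e^{rt}, valid for the proliferation-dominated phase that typical
2–4-week preclinical studies occupy. Fitting is ordinary least squares on
(t, ln N): under multiplicative lognormal measurement error this is the
maximum-likelihood estimator, and it makes the rate r independent of the
measurement unit. Gompertz/logistic dynamics (late-stage plateaus) are out of
scope; the R² threshold is the guard against applying the model outside its
range.

Conventions and derived quantities:

- Natural logarithms throughout; doubling time = ln(2)/r, reported only for
  r > 0 (regressing tumors are retained with their negative rate, but a
  doubling time is undefined for them).
- R² is computed on the log scale, the scale the regression is performed on;
  a raw-scale option exists (`FitConfig(r2_scale="raw")`) for comparison with
  tools that report it on the original scale. A constant log-trajectory has
  zero total variance and zero residuals; its R² is defined as 1.
- RSE(N₀) = 100·se(ln N₀): for a lognormal intercept the standard error of
  ln N₀ is, to first order, the relative error of N₀. RSE(r) = 100·se(r)/|r|.
- Forward error propagation: RSE(N(t)) = sqrt(RSE²(N₀) + t²·(100·se_r)²).
  Dimensional analysis of ln N = ln N₀ + r·t forces the t²·var(r) form — the
  growth-rate term enters with the *absolute* standard error of r expressed
  in percent, not its relative error.
- A fit requires ≥ 3 positive, non-excluded points (below that the animal is
  reported invalid for insufficient data, not errored); validity additionally
  requires R² strictly above the threshold, default 0.8, configurable in
  [0, 1].

Caliper volumes use the ellipsoid formula V = L·W²/2; swapped axes are
corrected with a warning rather than silently accepted.

## TGR matrices

Localized rates r_{x→y} = ln(N_y/N_x)/(t_y−t_x) are computed for every
ordered pair of usable days — n(n−1)/2 intervals for n days. Matrices are
keyed by day values, not indices, so animals measured on a subset of the
study grid align correctly. On one animal's data the rates telescope exactly
(r_{x→z}·Δt_{xz} = r_{x→y}·Δt_{xy} + r_{y→z}·Δt_{yz}), which the tests
assert to 1e-12. Group-level matrices are entrywise means (median available)
and are display-only: all statistics run on per-animal rates.

Display bins (day⁻¹): high r > 0.25, medium 0.15–0.25, low 0.10–0.15,
very low 0.05–0.10, minimal < 0.05. Lower bounds are inclusive; "high" is
strictly above 0.25, so 0.25 itself is medium.

## Quality control

**Homogeneity.** For each group, the coefficient of variation of baseline
values (each animal's first positive recorded measurement; sample SD) feeds a
piecewise base score with thresholds ε = 15 (excellent) and π = 30 (poor):
100 for CV ≤ ε; 95 − (CV − ε) for ε < CV ≤ π; max(0, 100 − 2(CV − π))
above. The formula is implemented verbatim and is **discontinuous at
CV = π**: 80 at CV = 30 but ≈ 100 immediately above. This is a property of
the published scoring rule; it is documented here rather than silently
smoothed. Small-sample factors multiply the base score: ×0.9 when n < 5 and
additionally ×0.8 when n < 3 (both configurable; the defaults are this
package's choice — no canonical values exist). Assessment runs before and
after filtering so the effect of exclusions is visible.

**Outlier detection.** Six criteria with fixed severities, IQR fences on
log-transformed data:

| criterion | severity | rule |
|---|---|---|
| IMPOSSIBLE_VALUE | critical | value ≤ 0 |
| EXTREME_GROWTH | critical | per-day growth 100·(f−1) above the tier limit, f = (N_{i+1}/N_i)^{1/Δt} |
| EXTREME_DECLINE | critical | per-day decline 100·(1−f) above the tier limit |
| INTRA_OUTLIER | high | log residual from the animal's Theil–Sen trend outside median ± k·IQR of its residuals (≥ 4 points) |
| GROUP_OUTLIER | medium | ln value at a day outside the group's median ± k·IQR at that day (≥ 4 animals measured) |
| LAST_DAY_DROP | medium | final-interval decline > 50 %/day with no earlier declining interval |

Sensitivity tiers: n < 5 ultra-conservative (k = 4.0, growth limit
5000 %/day, decline limit 90 %/day, multiple indicators required for a
whole-animal exclusion recommendation), 5–10 conservative (3.0, 2500, 80),
n > 10 moderate (2.0, 1000, 67). Smaller groups get laxer limits
deliberately — each animal is a larger fraction of the evidence, so exclusion
must be harder. An alternative coarse tiering (n < 8 / 8–12 / > 12) is
available as `preset="coarse"`. The Theil–Sen median slope is used for the
within-animal trend because a single corrupt point must not drag the trend it
is judged against. Quartiles use linear interpolation (numpy default,
type 7); fence positions depend on this convention. Fences carry a 1e-9
absolute slack so exactly-collinear data (zero IQR) are not flagged for
floating-point rounding.

**Filtering** is non-destructive (points are marked, never deleted) with
three modes: complete (no exclusions), animal-level (whole animals with
selected-severity flags removed), point-level (flagged points excluded,
animals retained while ≥ 3 valid points remain). The detector is idempotent:
re-running it on a filtered study yields a subset of the original flags.

## Group statistics

Mann–Whitney U, two-sided, with the tie-corrected and continuity-corrected
normal approximation at every sample size; `method="exact"` (enumeration)
exists for verification. Against full enumeration the approximate p agrees
within 15% relative wherever the exact p ≥ 0.05 (measured maximum 9% over
random tie-free samples at n = 4–6); in the far tail the continuity-corrected
approximation is conservative (returns the larger p). One structural
consequence: at n = 3 per group the smallest achievable two-sided approximate
p is 0.081 (exact: 0.1), so no 3-vs-3 comparison can reach 0.05 — power at
that size is zero by construction under this p-value method, and nonzero
values would require dropping the continuity correction
(`mann_whitney_u(..., continuity=False)`).

Cohen's d uses the pooled SD with (n−1)-weighted variances and the
large-sample CI d ± 1.96·sqrt((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b−2))).
Orientation is treated − control: negative d and positive percent reduction
(100·(1 − r_treated/r_control)) both mean slower growth under treatment.

Multiplicity corrections (Bonferroni, capped at 1; Benjamini–Hochberg
step-up q-values) attach **only to diagonal intervals** — consecutive-day
rates, the single family of mutually data-disjoint comparisons. Off-diagonal
intervals share measurements, violating the independence assumptions, and are
reported uncorrected alongside effect sizes; interval comparisons are
exploratory by design.

## Power assessment

For each (n_a, n_b) scenario, 20 subsets (default) are drawn without
replacement within each group, independently across subsets (repeats
possible), all seeded. Conventional power: per-day Mann–Whitney tests at
every day where both subset groups have ≥ 2 available animals; a subset's
score is the fraction of tested days with p < 0.05, and power is the mean
score × 100. Exponential power: per-animal fits filtered at the R²
threshold; subsets with < 2 valid animals in either group are excluded; the
rest score significant/nonsignificant on the rate comparison, and power is
100 × significant/valid. The minimum of 2 valid animals per group is the
smallest testable sample.

Under a no-effect simulation the exponential procedure rejects ≈ 5% of
subsets at α = 0.05 (checked at 200 subsets), and power rises monotonically
with the planted effect size at every sample size tested.

## Weight standardization

With heterogeneous euthanasia days, terminal weights are not comparable.
Each animal's weight is carried along its own fitted burden rate:
w(target) = w·e^{r·(target − euthanasia_day)}, assuming weight is
proportional to burden over the extrapolation window. Accuracy degrades with
the extrapolation distance and with RSE(r) (the propagated uncertainty grows
linearly in Δt). Prediction error against a measured weight is reported as
100·|experimental − predicted|/experimental.

## Synthetic cohorts

The generator emits exactly the process the model assumes: per-animal true
rates r ~ Normal(mean, SD), baselines N₀ lognormal (geometric mean,
geometric CV), measurements N₀·e^{rt}·ε with ln ε ~ Normal(0, σ),
σ = sqrt(ln(1 + (cv/100)²)) so the measurement CV equals the requested
percentage. Optional right-censoring dropout emulates humane endpoints
(producing heterogeneous euthanasia days and terminal weights), and planted
single-point anomalies (10× spikes, 10× drops, non-positive values) exercise
the detector; all plantings are recorded in the returned truth table.

The bundled preset mirrors the public glioma-xenograft reference structure:
8 control + 10 treated animals, days 0, 3, 4, 5, 6, 7, 10, 11, 12, 13, 14,
17, 18 (78 intervals), group mean rates 0.257 vs 0.175 day⁻¹, 20%
measurement CV. Values not published anywhere — the between-animal rate SD
(0.04 day⁻¹, ≈ 16–23% of the group means, a moderate heterogeneity typical
of xenograft cohorts) and the baseline distribution (geometric mean 100 mm³,
30% geometric CV) — were fixed once as realistic study conditions.

What the generator does **not** emulate: growth deceleration near carrying
capacity, treatment effects that switch on/off mid-study, serially
correlated measurement errors, and cage or operator effects. Tests passing
on synthetic cohorts therefore validate the estimation and QC machinery
under the model's own assumptions; they do not certify behaviour on data
that violate exponential growth.

## Problem sizes and determinism

Simulation-based checks run at deliberately modest sizes — 200 resampling
subsets for the type-I and power-monotonicity checks, 1,000 random instances
for the least-squares oracle comparison, cohorts of ≤ 60 animals — chosen as
the point where Monte-Carlo error is small relative to the tolerances
asserted. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical seeds give bit-identical studies,
analyses and exports.

## Known limitations

- The exponential assumption restricts validity to early-stage growth;
  R² filtering flags, but cannot fix, model breakdown, and filtering itself
  can select against genuine non-exponential responders.
- The homogeneity base score's discontinuity at CV = π means scores for
  groups just above/below 30% CV are not comparable with each other.
- Weight standardization extrapolates a single-animal exponential; errors of
  tens of percent over week-long extrapolations are expected (the framework
  reports them rather than hiding them).
- With ≤ 4 animals per group, parameter estimates are fragile regardless of
  method; the adaptive QC tiers reduce, but cannot remove, that fragility.
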