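# Methods

## The problem

Dietary assessment instruments report energy intake with large and
systematic error, especially in people with obesity. The accepted way to
quantify that error is to compare reported total daily energy intake (TDEI)
against total daily energy expenditure (TDEE) measured by doubly labelled
water (DLW) in weight-stable participants, where energy balance makes TDEE
a physiological criterion for true intake. This package implements that
comparison end to end — isotope kinetics, energy-requirement norms,
misreporting classification, agreement statistics, and a nine-facet
validity scorecard — driven by a synthetic cohort generator that emulates
the data structure of a 7-day free-living validation week in n = 20 adult
females with obesity.

## DLW model

Two-point method in urine. Each tracer's excess enrichment above the
pre-dose baseline decays mono-exponentially; the elimination rate between
the post-dose plateau (arithmetic mean of the 4 h and 5 h samples) and the
final sample (~day 7) is `k = ln(E_plateau/E_final)/Δt`, with Δt measured
from the plateau midpoint (4.5 h). Dilution spaces follow from dose
bookkeeping, `N = n_water(dose)·(A_dose − A_natural)/E_plateau`, one pool
per tracer; the per-molecule atom-site count cancels between dose and body
water. CO₂ production uses

    rCO₂ = 0.4664 · N · (1.007·k_O − 1.043·k_d) · 22.26   [L/day]

and energy expenditure the Weir equation `TDEE = rCO₂·(1.106 + 3.94/RQ)` at
an assumed RQ of 0.85 (mixed diet).

Conventions the two-point literature leaves open, all configurable:

- **Pool size in rCO₂**: `N = (N_o + N_d/1.041)/2`, i.e. the ²H space is
  deflated by the reference dilution-space ratio before averaging with the
  ¹⁸O space.
- **Plateau** = arithmetic mean of the 4 h and 5 h excesses.
- **QC band** for N_d/N_o: [1.00, 1.07]; outside it the result carries a
  flag but is still returned, as are negative rCO₂ values.
- Excess units only need to be self-consistent between dose bookkeeping
  and samples (the sheets carry ppm of atom fraction; a δ-per-mil → ppm
  helper is provided).

One printed quantity deserves a note: published elimination-rate ratios for
this design are sometimes labelled k_d/k_O with a value near 1.32, although
a positive CO₂ production requires k_O > k_d. The engine reports both
k_d/k_O and k_O/k_d; the generator targets a water/CO₂ turnover ratio
k_O/k_d near 1.3207.

## Synthetic cohort

The generator is the analysis inverted. Anthropometrics are truncated
normals (lower bound 2 SD below the mean, no upper bound) at the study
moments: weight 108.4 ± 16.3 kg, height 1.66 ± 0.06 m, age 37.9 ± 13.4 y,
true TDEE 3004.2 ± 480.5 kcal/day. Body fat fraction is 0.48 ± 0.04 —
typical for BMI ≈ 39 adult females and consistent with the published
cohort BMR of 1449.6 kcal/day under Mifflin–St Jeor on adjusted body
weight — giving FFM, and total body water as TBW = 0.732·FFM (fixed
hydration of lean tissue, configurable).

Isotope series: doses follow the study protocol (1.8 g/kg TBW of 10 atom%
H₂¹⁸O, 0.12 g/kg TBW of 99.9 atom% ²H₂O); N_o is set from true TBW, N_d
from a draw of N_d/N_o ~ Normal(1.0398, 0.0067); elimination rates are
obtained by inverting the rCO₂ equation at the participant's true TDEE
under the engine's own pooling convention, with k_O/k_d = 1.3207. Plateau
samples are placed so their arithmetic mean equals the exact plateau
enrichment and the final sample decays from that mean, so the engine's
two-point estimate is exact at zero noise — the identity every recovery
test builds on.

Measurement noise is additive Gaussian on the excess enrichments, default
0.3 ppm. The two-point method amplifies rate errors roughly ninefold
through the small difference 1.007·k_O − 1.043·k_d, so 0.3 ppm yields a
per-participant TDEE uncertainty of ~4%, in line with the accepted
precision of DLW; substantially larger values would imply analytical
performance far worse than modern isotope spectrometry reports.

Reported intake: day-level TDEI = TDEE·(1 + bias)·B_i·W_id with lognormal
person-level (B_i) and day-level (W_id) factors of mean 1 — multiplicative
noise keeps intake positive and reproduces the right-skew typical of
app-reported intake. Defaults are the study conditions: bias −25% with
within-person CV 88.36% for the app-like tool (the study's printed
within-subject CV of reported intake), bias −50% for the recall-like tool.
The recall-like within-person CV (30%) and the between-person CVs (50%
app, 30% recall) are not published anywhere; they were chosen once so the
weekly-mean intake SDs land near the published 1400.8 and 554.1 kcal/day
and are exposed as parameters. The true (as opposed to reported)
day-to-day intake CV is likewise a free parameter with no published value.
Eating occasions are Poisson (means 5.1 and 3.0); macronutrient grams
follow a fixed 45/35/20 energy split at 4/9/4 kcal/g.

What the generator does **not** model: food recognition or portion-size
error mechanisms, food-composition database error, correlated day-to-day
reporting (each day is exchangeable), adherence decay over the week, or
any dependence of reporting bias on body size. Passing recovery tests
therefore show that the pipeline measures what the noise model puts in —
not that any real instrument has these error properties.

## Energy norms and Goldberg classification

IBW (Devine, female), ABW = IBW + 0.3·(W − IBW), and BMR on ABW via
Mifflin–St Jeor (default aBMR) or Harris–Benedict (revised classic female
coefficients 655.0955/9.5634/1.8496/4.6756; the coefficient table is
configurable because several variants circulate). Heights are stored in
metres and converted to cm exactly once at the formula boundary; energies
are kcal/day with kJ derived by ×4.184, never stored twice. Out-of-domain
inputs (weight below IBW, zero inputs) compute with a warning rather than
erroring, since the emulated cohort excludes them.

Goldberg bounds are individual-level log-scale intervals around a cohort
reference PAL. The variability factor composes within-person intake CV
over d days, within-person denominator CV, and between-person PAL CV in
quadrature. Study-specific CVs are estimated from the data (pooled
within-person variance over the grand mean; between-person CV of the PAL
series); the denominator CV keeps Black's literature value 8.5% since the
denominator is measured once per participant. The bound count n defaults
to the number classified, with an n−1 option (published intervals
reconstruct with n−1, suggesting one participant was dropped from that
computation). Ties at a bound classify as plausible — conservative toward
accurate reporting.

## Agreement statistics

Bland–Altman: bias = mean difference (reference subtracted), SD with
ddof 1, LoA = bias ± 1.96·SD exactly. Published tables of this design mix
divisor conventions — one row's standard errors reconstruct with m = n,
another's with m = n − 1 — so the divisor is an explicit per-call argument
(`se_bias = SD/√m`, `se_loa = SD·√(3/m)`) and the summary-reconstruction
helper carries the same m into the bias CI's t df (df = m − 1), which
reproduces both published CIs to print precision. Proportional-bias
regression of differences on means is deliberately not part of the main
output (the emulated analysis assessed it visually); the slope is available
from `pearson_assoc` on (means, differences) if wanted.

ICC is ICC(2,1): single-measure absolute agreement under a two-way random
effects model, computed from the ANOVA mean squares with the F-based
McGraw–Wong confidence interval (Satterthwaite df). The estimator is
validated against a brute-force variance-component computation and against
pingouin's ICC(A,1) in the test suite. Which ICC definition published
"two-way random effects" values used is rarely stated; absolute-agreement
single-measure is the default here and the natural reading for day-to-day
stability of a single instrument.

Paired comparisons run Shapiro–Wilk on the differences at α = 0.05 to
select paired t vs Wilcoxon signed-rank; p-values are Bonferroni-adjusted
with k = 3 (the three pairwise method comparisons) and capped at 1 — which
is why published scorecards of this design show p = 1.0 entries. The
adjustment family is configurable per call.

## Scorecard conventions

- Facet 3's percentage difference is the mean of per-participant
  percentages, not the ratio of cohort means: the two differ whenever
  intake error correlates with expenditure, and only per-participant
  averaging is consistent with published scorecards of this design
  (a −817.3 kcal/day bias at a 3004.2 kcal/day reference mean prints as
  −25.0%, not −27.2%).
- Facet 4 averages positive and negative differences over disjoint
  subsets; its percentages are subset means of the individual percentage
  differences. An empty side carries a "no overestimation/underestimation"
  sentinel.
- Facets 2 and 6–8 report signed r² = sign(r)·r², so inverse relationships
  are visible as negative entries.
- Facet 7's energy-storage regressor is Δ body weight × 7700 kcal/kg over
  the study days (energy density of tissue change, configurable); facet 8
  regresses (TDEI − TDEE) on Δ weight directly.
- Facet 1 carries the agreement module's results field-for-field, with no
  recomputation.
- Missing inputs drop a facet, never the report.

## Problem sizes and numerical choices

Recovery tests use the sizes at which their Monte-Carlo error is small
enough to be meaningful: moment and bias recovery at n = 200–400
participants, ICC recovery on 500 × 7 matrices, everything else at the
study size n = 20. The full suite runs in a few seconds. Degenerate inputs
are handled explicitly: zero SDs place all draws at the mean; constant
difference vectors short-circuit the paired test; exactly constant
correlation inputs return NaN with a flag rather than a warning; a
constant matrix yields ICC from the 0/0 limit convention of its formula.

## Known limitations

- The generator's between-person reporting CVs are calibrated to published
  dispersion summaries, not measured; conclusions about real instruments
  require real data.
- The DLW engine implements only the two-point plateau method — no
  multi-point regression variant, no spectrometer drift or memory
  correction, no intercept-method selection.
- The proprietary device REE regression and lifestyle-PAL algorithm are
  treated as input columns; they cannot be recomputed.
- Individual-level published results (per-participant Goldberg labels,
  real-cohort scorecard cells) are not reproducible from summary
  statistics alone and are out of scope; the pipeline's correctness on
  those paths is established by construction-recovery properties instead.
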