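# Methods

This note records the models, parameter choices and numerical conventions
behind `hairetg`, and what the synthetic-data generators do and do not
emulate.

## Signal model and peak processing

Simulated SRM traces are a constant baseline plus additive Gaussian peaks
plus i.i.d. Gaussian intensity noise, sampled on a regular grid
(`floor(duration/interval) + 1` points). A Gaussian (no tailing) is the
minimal shape sufficient for area and S/N arithmetic; i.i.d. Gaussian noise
matches the RMS noise definition used downstream. An optional interference
peak can be injected on one transition to reproduce the qualifier-channel
artefact that ball-mill pulverisation of hair induces on the m/z 405→331
trace; its signal-level consequence (an inflated qualifier/quantifier ratio
failing the identity check on that qualifier only) is the modelled
phenomenon, not its chemistry.

Peak integration uses caller-supplied retention windows — automatic peak
picking is deliberately out of scope so that no hidden heuristic sits inside
the quantitative surface. The local baseline is the straight line joining the
medians of the first and last `min(5, n/5)` window samples; height is the
maximum of the baseline-subtracted signal and area its trapezoidal integral,
floored at zero. Both are invariant under constant baseline offsets. For
windows whose edge sits on the peak itself (e.g. half-window checks) a known
constant baseline can be supplied instead. Baseline noise is the RMS of
residuals after removing a linear trend from a declared peak-free region
(≥ 20 samples); vendor "auto-RMS" readouts are proprietary, and detrended RMS
is the reproducible member of that family. S/N is peak height over this RMS.

Qualifier ion ratios are compared to reference ratios learned as the mean
qualifier/quantifier area ratio across calibration standards, with a default
acceptance window of ±20% relative — the conventional identification-point
tolerance; both are configurable because neither a numeric reference nor a
window is fixed by the assay description itself.

## Calibration

The response ratio (analyte area / internal-standard area) is regressed on
nominal concentration by **unweighted** OLS; weighted fitting is deliberately
not offered, because the workflow first checks homoscedasticity (variance-
ratio F-test between the replicate variances at the lowest and highest
levels, default α = 0.01) and adopts weights never. Default design: levels
6, 10, 20, 30, 60 pg/mg, three replicates each; a second curve spans
60–300 pg/mg, and estimates above 300 pg/mg are flagged for extract dilution
rather than extrapolated.

Linearity is accepted only if both tests pass at α = 0.05:

* **Lack-of-fit**: residual SS is split into pure error (within replicated
  levels, df n−k) and lack-of-fit (df k−2); F compared to the upper critical
  value.
* **Mandel**: F = (SSE_linear − SSE_quadratic)/(SSE_quadratic/(n−3)) against
  F(1, n−3).

When a fit is numerically exact, both SS terms consist of rounding dust
(~1e−32) and their ratio is meaningless; F is reported as 0 whenever the
relevant SSE falls below `n·eps²·Σy²`.

Back-calculation inverts the line with dilution-factor and sample-mass
scaling against a 50 mg reference aliquot (the standard washed-hair take;
configurable). Negative back-calculations are flagged `below_zero`, never
clamped — mapping to `<LOD` happens in the interpretation layer.

The LOQ rule is operational: the lowest level whose intra-assay CV% and
|bias|% are both ≤ 20%; with the default design this is the lowest calibrator
(6 pg/mg). RSD and bias are held unrounded in result objects; half-up
rounding to printed precision (integer RSD, one-decimal bias, magnitudes)
happens only at the report layer.

## Detection limits

Two routes, reported side by side:

* **S/N rule** — lowest *measured* concentration with S/N strictly above 3.
  No interpolation below the lowest qualifying measured level: the rule is a
  screen over what was actually measured.
* **Hubaux–Vos** — from the calibration line's one-sided prediction bands.
  With band half-width t·s_y/x·√(1 + 1/n + (x−x̄)²/Sₓₓ): the decision limit
  x_C converts the blank's upper (1−α) bound to concentration, and the
  detection limit x_D is the smallest x whose lower (1−β) bound clears it,
  found by bisection to 1e−6 pg/mg (no closed form once the x̄ and Sₓₓ terms
  are kept). Defaults α = β = 0.05; one-sided throughout, since detection is
  a one-sided decision. x_C is exactly proportional to s_y/x; x_D nearly so
  (the band width varies slowly with x), and x_D → 2·x_C in the flat-band
  limit.

## Factorial pretreatment analysis

Effects use the Montgomery convention: effect = mean(high) − mean(low) =
contrast/2^(k−1) (contrast/4 for the 2³ design), over block-averaged
responses in standard Yates run order (0, a, b, ab, c, ac, bc, abc); tables
whose rows arrive in another order are canonicalised on load, with run labels
authoritative and label/coded-level consistency enforced.

Three significance modes are provided because the packaged study's own
t-test construction ("n = 6") is not reconstructible from its printed
single-block data: the default reproduces its fixed 19.71 pg/mg threshold as
a given constant; `replicate_t` tests per-effect across-block variation when
≥ 2 blocks exist; `lenth` gives the standard pseudo-standard-error margin for
unreplicated designs. `FactorialModel` reports effects up to second order by
default — the conventional screening surface, with the three-factor
interaction as noise proxy — while `estimate_effects(max_order=None)` yields
all orders.

Yield deficits between run conditions are 100·(1 − num/den) on block-averaged
responses, rounded half-up to integer percent. On the packaged table the
cut+overnight vs pulverised+sonicated pairs give 28% and 8%; the aggregated
cut comparison (mean(0,a) vs mean(b,ab)) computes to 48%, which the package
reports as computed even though the accompanying narrative rounds it to a
different figure — arithmetic from the table is authoritative here.

## Validation report

Intra-day precision/trueness uses one day's ≥ 3 replicates; inter-day pools
all measurements (e.g. 3 days × 3 replicates = n 9) as a single sample rather
than decomposing day-level variance — matching how such panels are
conventionally summarised. The interference check back-calculates an
apparent concentration from each blank's quantifier window and passes only if
all stay below the LOD; qualifier-only signal is a warning, not a failure.
Overall validation passes iff linearity is accepted, the LOQ is defined,
every QC level is within the limits (defaults 15% RSD, 20% bias), and any
interference check passed.

The packaged validation summary table is internally consistent for its
inter-day rows (recomputed RSD 14/10/8%, bias 8.0/7.3/5.7% vs printed
8.2/7.3/5.6 — differences within rounding of the printed means), but its
intra-day bias at 30 pg/mg (printed 3.2%) does not follow from its printed
mean (31.8 vs 30 → 6.0%); the package always computes from the data and
documents rather than reproduces such inconsistencies.

## Cohort interpretation

Per-class concentrations are simulated log-normal — strictly positive and
right-skewed, as biomarker distributions are — with default medians/geometric
SDs graded across declared classes (Teetotal 1 pg/mg up to Heavy 120 pg/mg,
the observed class centres) and censoring at LOD 4 / LOQ 6 pg/mg. Censored
results are never imputed: summaries count them in n but exclude them from
order statistics. Classification against the 30 pg/mg SoHT cut-off treats
censored results as below it; abstinence assessment is always
`not_assessable` when the method LOQ exceeds 5 pg/mg, as with the 6 pg/mg
default. Subjects declaring Moderate-or-above consumption with censored
results are listed as anomalies, with no numeric adjustment — self-declared
consumption is unreliable, and the cosmetic-treatment flag is likewise
carried through reporting without correction.

## What the generators do not emulate

Synthetic traces have no peak tailing, retention drift or correlated noise;
calibration noise is Gaussian (constant-SD or proportional-CV) with no
outliers or carry-over; factorial responses have no block-by-factor
interactions beyond the specified effects; cohorts have no within-subject
segmental variation, cosmetic-treatment effects or misreported classes.
Passing tests on these generators therefore demonstrates correctness of the
estimators and decision rules under their stated assumptions, not robustness
to real-chromatography pathologies. Extraction chemistry is not modelled at
all: the factorial generator produces response values directly.

## Problem sizes and numerical conventions

Type-I-error checks for the linearity tests use 1000 null simulations of the
default 5×3 design (binomial-band assertion around α = 0.05); estimator
cross-checks use 500 random 2³ tables; sampling-statistics checks use
10³–10⁴ draws, sizes at which the asserted tolerances (e.g. CV within 0.5
points, medians within 10%) hold with comfortable margin. All randomness
flows through `numpy.random.default_rng(seed)`; identical specs and seeds
give bit-identical outputs. Rounding is half-up (decimal, not banker's) at
report layers only. CSV I/O is strict RFC-4180 with dot decimals; a
European-decimal source value ("19,71") is normalised once at fixture build
time, and decimal commas in user inputs are rejected with row/column
coordinates rather than silently parsed.

## Known limitations

No weighted or nonlinear calibration; no automatic peak picking or
retention alignment; no blank-population (mean + 3·SD) LOD; no measurement-
uncertainty budget; no pharmacokinetic dose–concentration modelling; no
segmental hair analysis. The fixed 19.71 pg/mg effect threshold is a
reproduced constant whose provenance is external to the computable data.
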