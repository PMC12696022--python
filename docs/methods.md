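# Methods

## Scope and data model

`vfaopt` analyzes batch acidogenic-fermentation experiments in which total
volatile fatty acids (VFA, mg COD/L) are measured on destructive replicate
samples over a grid of fermentation temperatures and retention days, for a
set of discrete treatments (sludge type, organic load in g VS/L, initial
pH). The reference design is a 48-combination factorial — {DS×{4,6},
PS×{10,14}} g VS/L × pH {9.5, 10.5, 11.5} × {25, 35, 45, 55} °C — sampled
in triplicate every 3 days to day 12, except day 9 at 55 °C where methane
onset ended the batches. Temperature and day are continuous covariates of
the response model; the 48 combinations therefore collapse to 12
treatments, each carrying its own surface.

Units are fixed in the schema (mg COD/L, g VS/L, °C, days) with no unit
inference: silent unit errors dominate this domain. Replicate indices are
explicit so duplicate detection is unambiguous. Whether day 0 was assayed
per reactor is left open in the source design; the schema accepts day ≥ 0
and the generator can include day 0 behind a flag (off by default, treating
inoculation VFA as baseline rather than forcing the cubic through it).

## Cubic response surface

Per treatment, VFA(t, d) is the full 10-term bivariate cubic fitted by
unweighted OLS on replicate-level rows (never cell means — with replicate
noise a perfect mean model cannot reach r² = 1, and reporting r² on
replicate points keeps that honest). Raw monomials reach t³ ≈ 1.7 × 10⁵,
so the solve runs on a column-normalized design matrix; coefficients and
standard errors are mapped back to the raw monomial scale, and t-values are
invariant under that scaling. Coefficient t-values use the classical
homoscedastic OLS covariance. The fit refuses designs with fewer than 11
rows (residual df ≥ 1) or a numerically rank-deficient basis (relative
singular-value cutoff 10⁻¹⁰), naming the dependent columns.

The degree comparison (2 vs 3 vs 4) reports r², adjusted r² and residual
df. A full quartic is *not identifiable* on a four-temperature design
(t⁴ is collinear with {1, t, t², t³} on four support levels), so the
comparison uses the minimum-norm least-squares projection with df taken
from the effective rank — the same behavior a generic least-squares
toolchain exhibits — rather than refusing. r² is non-decreasing in degree
by nesting; the cubic is justified when third-degree terms are significant
in the Pareto ranking and the quartic's adjusted gain is marginal.

The Pareto analysis ranks all 10 terms (intercept included) by |t| against
the two-sided critical t at the fit's residual df; at α = 0.05 and 27 df
that threshold is 2.052.

## Grid optimization

The production optimum is located by exhaustive sweep on a lattice with
0.05 °C and 0.05 day steps — far finer than experimental precision — over a
feasible domain censored by methane onset. The censor's shape between 45
and 55 °C is not observable from the design; the default is a step rule
(12 days for t ≤ 45 °C, 9 above), with a linear-interpolation option. Ties
break toward the lowest temperature, then the lowest day: the cheaper
operating condition. Halving the lattice step can only increase the
returned maximum because the grids nest.

The library's `study_domain()` spans the full [25, 55] °C × [0, 12] d
rectangle and both axis ranges are configurable. The pipeline, however,
clips the sweep domain to the span actually sampled in the data it is
given (`clip_domain_to_data=True` by default). The reason is structural:
with sampling starting at day 3, the cubic is pure extrapolation on
[0, 3), and at realistic replicate noise (SD ≈ 516 mg COD/L) the
extrapolated lobe dominates every sweep, producing boundary optima at
day 0 that no observation supports. An optimum should never be reported
where there is no data; users who want the full-horizon sweep can switch
the flag off.

## Synthetic data generator

The generator realizes exactly the statistical world the analysis assumes:
a known cubic truth surface per treatment plus i.i.d. homoscedastic
Gaussian replicate noise, truncated at zero (negligible bias at realistic
means of 3–7 g COD/L), on the factorial design skeleton with 55 °C
censoring. The default noise SD of 516 mg COD/L is the replicate SD
repeatedly reported for this assay class.

Truth surfaces are sampled as an interpretable peak — location, height,
quadratic curvature, mild cubic tilt — and converted to monomial
coefficients by exact interpolation on a 4 × 4 grid (16 values identify a
bivariate cubic exactly). Sampling raw β's almost never yields bounded,
realistic surfaces; the peak parameterization bounds the summed fractional
deviations below 1, guaranteeing non-negative VFA over the whole domain and
feasible maxima within [3000, 7500] mg COD/L. Two treatments are anchored
so pipeline output is comparable to real primary-sludge studies: (PS, 14,
10.5) peaks at ~7000 mg COD/L near 25 °C / 7.2 d and (PS, 14, 9.5) at
~6650 near 25 °C / 6 d; the other ten draw peaks from ranges strictly below
the anchored best. What a green test on this generator establishes is that
the *machinery* (fit → sweep → bootstrap → tests) is correct under its own
assumptions; it does not establish anything about heteroscedastic,
autocorrelated or non-Gaussian features real fermentation series may have
(triplicate error bars in real studies do suggest some heteroscedasticity).

## Bootstrap and between-treatment inference

The optimum is an arg-max functional with no convenient closed-form
sampling distribution, so uncertainty is propagated by parametric
bootstrap: B = 300 pseudo-datasets per treatment, each keeping the design
skeleton and redrawing every replicate from its cell's center plus
N(0, pooled within-cell SD). Centers are observed cell means by default
(fewest model assumptions); a flag centers on fitted values instead
(model-based variant). Each pseudo-dataset is refitted and re-swept; a
singular refit is retried with a fresh sub-seed up to 5 times (logged),
then raised. Sub-seed streams are salted by treatment so equal seeds never
share noise across groups. The bootstrap mean of the optimal VFA is biased
upward relative to the truth's maximum (the winner's curse of maximizing a
noisy surface); the test suite asserts the sign of this bias rather than
hiding it.

The ANOVA across treatments takes the per-group degrees of freedom as an
explicit parameter rather than using B − 1, reflecting the convention of
reducing df to those available in the polynomial regression. Each group is
treated as a pseudo-sample of size df + 1: the mean square within is the
pooled bootstrap variance, SS_between scales group-mean spread by the
pseudo-sample size, and F is referred to F(k − 1, k·df). With df = B − 1
this is exactly the classical one-way ANOVA (used for type-I calibration);
with two groups F equals the squared pooled t statistic. The published
convention of df = 28 per treatment reproduces the tabled critical value
F(0.05; 11, 336) = 1.817 — note the printed record of that workflow is
internally inconsistent (a t threshold of 2.052 implies 27 df while its
t-table prints 28; its ANOVA SS entries do not add up under any parsing),
which is precisely why df is a parameter here and the pipeline defaults to
the residual df of the fits it actually performed (35 on the default
design). The t-test between the two best treatments is pooled-variance by
default (equal variance is the bootstrap's own assumption), Welch optional.

## Numerical and degenerate-input choices

- Lattices are built as `lo + k·step` with a floor-based endpoint so
  halving the step yields a superset of points.
- Sweep evaluation uses the same design-matrix path as `predict`, so the
  reported optimum value equals `predict(model, t*, d*)` bit-for-bit.
- Zero pooled SD (e.g. noiseless data) degenerates gracefully: resamples
  equal cell means, all bootstrap optima collapse to the point estimate,
  and the ANOVA reports F = ∞ (p = 0) when between-group spread is positive
  with zero within-group variance.
- CSV export uses `%.17g` so floats round-trip exactly; the reader parses
  with Python's exact `float()` and raises named, row-numbered errors for
  missing columns, unparseable numbers, duplicate replicate keys and
  negative concentrations.
- Percent pilot difference is 100·(predicted − observed)/predicted, so
  symmetric inputs give 0 and the sign convention is fixed.

## Known limitations

- No mechanistic fermentation kinetics; the cubic is an empirical response
  surface and extrapolates poorly outside the sampled region (hence the
  domain clip).
- Homoscedastic noise only; no mixed effects, autocorrelation across
  retention days (destructive sampling justifies independence, but shared
  batch effects would violate it), or multiple-testing correction across
  the 12 treatments.
- Bootstrap summaries are mean/SD only — no BCa or percentile interval
  machinery.
- The VFA speciation chemistry (acetic/propionic/butyric fractions) is out
  of scope; only total VFA as COD is modeled.
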