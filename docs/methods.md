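# Methods

## Model and procedure

The pipeline targets the standard response-surface workflow for
optimizing a fermentation medium. A k-factor rotatable central
composite design (CCD) samples the factor space in dimensionless coded
units: a full 2ᵏ factorial core at ±1, 2k axis-aligned axial runs at
±(2ᵏ)^¼ (so every non-center run lies on the same coded sphere and the
prediction variance depends only on the distance from the center), and
replicated center runs that provide a model-free estimate of pure
error. Coded and actual scales are linked by `x = (amount − center)/Δ`
with a per-factor spacing Δ; the transformation is exact and invertible,
and fractional coded levels are legal everywhere since optimization
routinely lands off the design lattice.

The response surface is the full second-order polynomial

    y = b0 + Σ bi·xi + Σ bii·xi² + Σ_{i<j} bij·xi·xj

fit by ordinary least squares. The solve uses an orthogonal
decomposition of the model matrix (LAPACK lstsq), never the normal
equations; pure-quadratic columns are centered about their column means
while solving, which removes their strong collinearity with the
intercept on a CCD, and the coefficients are mapped back to the raw
polynomial parameterization afterwards. This is an exact
reparameterization: fitted values and all sums of squares are
unaffected.

The ANOVA reports per-term **partial (drop-one) sums of squares**
(residual SS of the model without the term minus the full model's), so
each term is adjusted for all others; per-term F is the partial SS over
the residual mean square, the per-term partial correlation is
`sign(b)·√(F/(F+df_res))`, and p-values come from the F distribution.
Pure error is pooled within replicate groups (runs with identical coded
vectors); the lack-of-fit F compares misfit mean square to pure-error
mean square at (df_misfit, df_pure) and the model is "adequate" when it
stays below the upper-α quantile. Model simplification retains the
intercept plus all terms with p ≤ α (default α = 0.10) **at their
full-model coefficient values** — no re-estimation — which is the
convention of the worked example this package reproduces.

Effect analysis reduces dimension by fixing all but one or two factors
at coded 0. The coefficients of these sub-models are read directly off
the parent model (a property-tested invariant). For one factor, the
analytic vertex −b/(2a) is reported when the curve is concave and the
vertex lies in the search domain (default [−2, 2], the design's coded
range); otherwise the better endpoint, flagged. For two factors the
gradient is linear, so the stationary point is the exact solution of a
2×2 system, classified maximum/minimum/saddle from the Hessian
determinant and leading element with a 1e-9 tolerance on the
determinant; a smaller determinant is treated as a degenerate ridge and
refused rather than solved unstably. Zone classification reports, for a
probe point, its quadrant relative to the stationary coordinates and
the sign of each partial derivative — i.e. whether raising each factor
alone raises or lowers the predicted response.

Optimization is an exhaustive lattice search over per-factor coded
level sets (default: the five design levels; arbitrary, including
asymmetric, lists are accepted). Exhaustive enumeration is the method:
it is exact on its lattice by construction, a wet lab can only realize
a handful of levels, and the search (625 schemes for 5 levels × 4
factors) is instantaneous. Ties break toward the lexicographically
smallest coded vector so the result is independent of enumeration
order. The analytic optimum of 2-D slices lives in the effect-analysis
module; no continuous optimizer is used on the headline path.

Assay metrics implement the field's scoring formulas (see README) with
validation at the record level: colony diameters below the plug, grades
outside the 0..6 scale and empty surveys are rejected; spore totals
below 300 warn (the usual counting recommendation is advisory, not
definitional). Duncan's multiple range test computes least significant
ranges from studentized-range quantiles at Duncan's protection level
(1−α)^(r−1) for span r, on the one-way-ANOVA error mean square
(harmonic-mean group size under imbalance), tests stretches of ordered
means largest span first with the usual containment protection, and
letters the maximal nonsignificant stretches; a zero error mean square
degenerates cleanly to "distinct means differ, tied means share".

## Worked example and its internal inconsistencies

The package embeds one published four-factor optimization as
`fermrsm.reference`: factor centers/spacings, the 31-run design with
responses, the fitted model, and the per-term p-values. The model is
shipped as a verbatim constant because the published design table and
the published coefficients are **not mutually consistent**: refitting
the 31 printed runs yields a peptone linear coefficient of −1.41 versus
the published +2.25, the published ANOVA claims 32 total df for 31
printed runs, and its pure-error SS (6.1951) does not match the printed
center replicates (4.405). The coefficient set together with the
published effect analysis and optimization results *is* internally
consistent, and that is what the package reproduces; `reproduce()`
carries a provenance note. Two further published values disagree with
their own inputs and are resolved in favor of exact arithmetic: the
sucrose stationary coordinate (exact 0.9417 vs printed 0.9517) and the
lattice optimum, which under the published model and level list is
(2.188, −2.132, −2.132, 2.188) at ≈91.8 mm rather than the reported
(2.188, −1.518, −1.066, 0) at 40 mm — the reported point (whose KNO₃
level is absent from the stated level list) is therefore carried as a
named reference point and evaluated separately. The peptone–sucrose
stationary point is likewise classified by its Hessian as a saddle.

## Synthetic data

`simulate_response_surface` draws a CCD response table as true-model
evaluation plus homoscedastic Gaussian noise — the standard RSM error
assumption. It emulates the magnitude structure of the worked example
(defaults: 7 center runs, unit noise sd, i.e. of the order of the
example's replicate scatter) but not features real fermentation data
can show: heteroscedasticity, run-order drift, batch effects, or
response truncation at zero. Passing recovery/bias tests therefore
demonstrates correctness of the estimator under its own assumptions,
not robustness to those violations. The assay generators use the
matching sampling models (normal diameters floored at the plug,
binomial germination counts per field, multinomial grade counts), so
their scoring-formula expectations are available in closed form. All
generators take an explicit seed and are bit-reproducible.

## Problem sizes and numerics

Tests run the statistical guarantees at desk scale: zero-noise recovery
on CCDs up to k = 6 (77 runs), Monte-Carlo calibration at 500 replicate
fits of the 31-run design (bias within 4 analytic SE/√500; empirical SE
within 10% of the analytic OLS covariance), lack-of-fit power at 20
replicates of a strongly cubic truth, and oracle agreement for the
lattice search and Duncan letters on batches of random models. ANOVA
additivity identities are asserted at 1e-9 relative tolerance,
stationary-point gradients at 1e-10, encode/decode round-trips at
1e-12. Reported table values use truncation (not rounding) to two or
three decimals where the worked example's printed values demand it;
full precision is kept internally.

## Known limitations

No Box–Behnken/Plackett–Burman/D-optimal designs, no stepwise or
penalized model selection, no response transformation, no full
k-dimensional canonical/ridge analysis, no desirability-based
multi-response optimization, no mixed models. The two-level letter
display sometimes seen in assay tables (e.g. "Bb") is obtained by
running Duncan grouping at α = 0.05 and α = 0.01 separately; the
package emits one letter set per call.
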