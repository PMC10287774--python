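# Methods

## The conversion problem

Loss-on-ignition (LOI) measures soil organic matter (SOM) as the mass
fraction lost when a dried sample is combusted at 550 °C.  Organic carbon
(OC) is a sub-component of that organic matter, so OC is predicted from SOM
by regression.  Three functional forms cover the published literature:
linear `OC = m·SOM + b`, quadratic `OC = a₂·SOM² + a₁·SOM + a₀`, and power
`OC = a·SOM^p`, with SOM and OC both in percent of dry mass (0–100).

A non-zero intercept is physically suspect: positive intercepts imply OC
without organic matter (incomplete carbonate removal before elemental
analysis), negative intercepts imply organic matter with no carbon (residual
water counted as SOM).  Dropping the intercept makes the slope the OC:SOM
ratio, the quantity used for group comparisons throughout the package.

### Unit conventions

All stored coefficients act on the percent scale.  The linear slope is
invariant under the percent/fraction convention, but the intercept is not:
an intercept of 10 on the percent scale is 0.10 on the fraction scale.
`convert_intercept_units` makes that conversion explicit, and the registry
refuses mixed conventions by construction.  The zero-intercept saltmarsh
quadratic in the literature registry is stored with its printed coefficients
acting on the percent scale — the reading consistent with its published
OC:SOM range (0.41–0.65 over 0–73% SOM).

## Outlier screening

Screening runs in two stages before any fitting:

1. **Physical bounds.**  Samples with OC:SOM ≥ 1 or ≤ 0 are removed
   (reasons `ratio_high` / `ratio_nonpositive`); a sample with SOM = 0 but
   measured OC has an undefined ratio and is removed too.
2. **Modified Thompson Tau**, per region, on the OC:SOM ratio.  With n
   retained points the threshold is τ·SD, where
   τ = t·(n−1) / (√n·√(n−2+t²)) and t is the two-sided Student-t critical
   value at α (default 0.05) with n−2 degrees of freedom.  The single most
   deviant point (first occurrence on ties, which is logged) is removed if it
   exceeds the threshold; the procedure repeats until no removal or n < 3.

The Tau variate and α are configurable because neither is uniquely
determined by convention; ratio space is the default because the screening
rationale (impossible ratios) lives there.  Note that the *iterated*
Thompson Tau is aggressive on large samples: on pure Gaussian data with
n in the hundreds it trims on the order of 10–15% before the stopping
condition is met.  This is a property of the test itself, not of the
implementation, and is worth keeping in mind when interpreting screened
sample counts.  Screening is idempotent: re-screening a screened dataset
removes nothing.

## Fitting

Linear and quadratic fits are ordinary least squares (statsmodels), with
coefficient standard errors from the usual σ²(XᵀX)⁻¹ and an option to force
the quadratic through the origin.  The power form is nonlinear least squares
(scipy `curve_fit`) initialized from the log–log OLS estimate, with relative
tolerance 1e-8 and a generous evaluation budget; if the solver fails, the
log–log estimate is returned with `converged=False` and a warning, with the
amplitude SE from the delta method.  R² is always 1 − SSE/SST on the
original scale so the three forms are comparable; for origin-forced models
this can in principle go negative and is floored at 0.

Degenerate inputs (zero predictor variance, n below the minimum, nonpositive
values for the power form) raise errors rather than returning NaNs.

The cross-regional **slope curve** fits `slope = a·(mean SOM)^p` across
regional summaries by the same power routine.  It rises steeply below ~10%
SOM and flattens toward high SOM; `predict_slope` turns a regional mean SOM
into a zero-intercept conversion slope (a last-resort tier — fitted regional
intercepts are rarely exactly zero), and `predict_slope_band` gives a ±1 SE
delta-method band (coefficient covariance is not retained, so the band is
approximate).

## Validation and group statistics

An equation is validated within a region by testing whether its residuals
(observed − modeled OC) center on zero.  Shapiro–Wilk at α = 0.05 gates the
choice: normal residuals go to a one-sample t-test (central tendency: mean),
non-normal residuals to the two-sided one-sample Wilcoxon signed-rank test
(central tendency: median; zero residuals dropped, scipy's exact
distribution for small untied samples and the continuity-corrected normal
approximation otherwise).  No transformation is attempted before the gate —
a configurable hook would be the place to add one — and no multiple-testing
correction is applied across regions.  Family quality is summarized by
AbsSum (Σ|central tendency| across regions) and AbsMean (AbsSum / number of
regions); the identity AbsMean × n = AbsSum holds exactly.

Group comparisons operate on the per-sample OC:SOM ratio: a pooled-variance
independent t-test for the two sedimentary settings, and a one-way ANOVA
with Tukey HSD post-hoc letters across coastal environmental settings (CES).
With exactly two groups the ANOVA F equals the squared t.  Compact letters
are assigned by an insert-absorb algorithm on the Tukey rejection set.

Latitude analyses: simple linear regressions of regional slope and regional
mean SOM on latitude over a chosen region subset, and a binned analysis that
isolates samples in fixed SOM increments (default 10%) to remove the
latitude–SOM confound, regresses regional mean OC:SOM on latitude within
each bin (bins with < 3 regions are skipped and reported), and averages the
per-degree slope over significant bins.

## Hierarchical estimation and stocks

Equation selection follows a fixed accuracy hierarchy: measured OC >
region-specific equation > CES equation > sedimentary-setting equation >
general mangrove equation > slope predicted from regional mean SOM.
Carbonate-lagoon contexts borrow the carbonate open coast equation (no
carbonate-lagoon calibration exists).  Selection is deterministic for a
fixed registry and context, and adding context never demotes the tier.

Predictions propagate linear coefficient SEs as
√(SOM²·SE_m² + SE_b²); the slope–intercept covariance is not recoverable
from published tables and is ignored (flagged in the output).  Negative
predictions — possible at low SOM under strongly negative regional
intercepts — are clamped to zero with both raw and clamped values retained.
Predictions outside an equation's calibration SOM range are flagged
`extrapolated`.

Stocks integrate over depth intervals:
`(OC/100) × bulk density (g cm⁻³) × thickness (cm)` gives g OC cm⁻², and
1 g cm⁻² = 100 Mg ha⁻¹.  The depth limit defaults to 100 cm; intervals
straddling it are pro-rated by in-limit length (a declared convention), and
the uncovered fraction of the profile is reported as `gap_fraction`.
Stocks are additive over disjoint partitions and homogeneous of degree one
in bulk density.  Paired stock estimates are compared with a two-sided
Wilcoxon signed-rank test reporting medians and interquartile ranges; an
all-zero difference vector is reported as statistic 0, p = 1.

## Synthetic data model

The generator emulates a 17-region mangrove compilation.  Each region draws
SOM from a truncated normal, applies a true linear relationship
`OC = slope·SOM + intercept` with Gaussian noise, and clips OC into
(0, SOM) so generated data satisfy the physical screening bounds by
construction.  Per region, the true slope, intercept, sample size and target
R² are the published regional-equation values; the noise scale is
`slope · SOM-SD · √(1/R² − 1)` so the expected regional R² matches the
published one.  Regional mean SOM is published for only three regions
(9.9%, 16.5%, 69.2%); the other fourteen means are synthetic defaults chosen
once to respect the published distribution of regional means (ten below 30%,
four in 30–50%, three above 50%) and the carbonate/terrigenous ordering —
they are labeled non-authoritative in the module.  Bulk density is an
independent truncated normal whose mean declines with organic content;
depth intervals tile 0–100 cm in 5-cm steps across cores.  An optional
latitudinal gradient on the true OC:SOM slope supports the binned-latitude
recovery studies.

A master seed spawns one independent substream per region
(`numpy.random.SeedSequence`), so datasets are exactly reproducible and
per-region draws are independent of list order.

What the generator does **not** emulate: spatial autocorrelation within
sites, downcore diagenetic trends, heteroscedastic analytical error,
non-Gaussian residuals, or carbonate-content structure.  Passing tests on
synthetic data therefore demonstrate the correctness and calibration of the
machinery under the stated model, not the field accuracy of any particular
conversion equation.

## Problem sizes used in tests

The test suite runs the full synthetic pipeline at the published scale
(1,246 samples, 17 regions), 500 generator replicates for slope/intercept
coverage of the ±3 SE band (checked per coefficient, whose nominal coverage
is ≈ 99.6%), 2,000 replicates for the type-I calibration of the gated
residual test, 1,000 random lists for the Thompson-Tau brute-force
cross-check, and 100 random datasets for the OLS/normal-equations
comparison at 1e-10 relative tolerance.

## Known limitations

- SE propagation ignores coefficient covariance everywhere it is not
  retained (published tables do not report it).
- The iterated Thompson Tau over-trims large clean samples (see above);
  regional fits on heavily screened data are mildly attenuated relative to
  the generating slope.
- The power-form R² can be compared with linear R² only on the original
  scale, which is how it is computed here; log-scale goodness-of-fit is not
  reported.
- No robust-regression alternative to outlier deletion, and no weighted or
  errors-in-variables fitting, is provided.
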