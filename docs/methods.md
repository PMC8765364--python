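# Methods

This note documents the models, parameter choices, and numerical decisions
behind `mangrove_nbudget`, and what the synthetic-data tests do and do not
demonstrate about real field data.

## Budget arithmetic and units

N stock of a slice is dry bulk density (g cm⁻³) × thickness (cm) × N mass
fraction, giving g N cm⁻², converted to Mg ha⁻¹ by the factor 100.  N
accumulation is SAR (mm y⁻¹) × bulk density × N fraction × 1000, in
g m⁻² y⁻¹ (100 g m⁻² y⁻¹ = 1 Mg ha⁻¹ y⁻¹).  %N and %C are held internally
as mass fractions and rendered as percent only at the tabular interfaces;
this costs one ulp on a write/read round trip (×100 then ÷100) but removes
the chance of silent factor-of-100 errors inside the arithmetic.  Molar C:N
uses atomic weights 12.011 and 14.007.

Slices are half-open depth intervals [top, bottom) in cm below the surface.
Thickness is `bottom − top`; no compaction correction is applied because
slice dates are apparent ages.  A slice dated exactly on a period boundary
belongs to the later period (half-open calendar intervals), so 1970 counts
as recent.  Temporal stock comparisons divide by the period duration
(46 y recent vs 40 y historic) to put both windows on a per-year scale.

### Depth extrapolation

To extend stocks below the cored depth, ln(N density per cm) is modelled
as linear in depth and the fitted exponential is integrated analytically
from the deepest observation to the target depth; the observed portion is a
trapezoidal integral with the shallowest density extended to the surface.
A non-decaying fit (slope ≥ 0) is allowed but raises a warning, since the
extrapolated tail then grows with depth.  Densities must be positive; the
choice of transform (density rather than accumulation rate) is a package
default, and callers can extrapolate either profile.

## Bootstrap engine

Per-parameter estimates use the percentile bootstrap: B = 1,000 replicates,
each the mean of a with-replacement resample of the same size; the estimate
is the replicate mean and the bounds the empirical 2.5th/97.5th percentiles
(linear interpolation between order statistics — the quantile rule is a
package choice).  Derived quantities (stock, accumulation) draw one SAR,
one bulk density, and one N fraction independently per replicate, so the
replicate statistic is a single derived value; this deliberately keeps the
full measurement-to-measurement spread in the bounds.  An alternative
(averaging m paired draws per replicate) is exposed via
`draws_per_replicate` and produces narrower intervals; it is not the
default.  Site-level estimates concatenate the replicate vectors of the
site's cores (2,000 values for two cores) before taking percentiles.

Significance is an interval-overlap rule on closed intervals; a shared
endpoint counts as overlap (conservative).  Randomness is keyed per core by
hashing (seed, core_id), so processing order cannot change results.

Percentile-bootstrap intervals at n ≈ 15 slices are approximate: measured
coverage of a known Gaussian mean is ~93%, inside the 90–98% band the test
suite enforces.

## Upscaling

Site values are interpolated onto a grid of mangrove cell centres by
inverse distance weighting with power 2 (unstated in the source design;
exposed as a config).  A cell within 1 nm of a site takes that site's value
exactly; IDW output is a convex combination of site values.  Stochastic
draws use a two-piece (Fernández–Steel) normal with shape ξ, re-centred and
rescaled so the population mean and sd match the requested moments; ξ = 1
reduces to the normal, ξ > 1 is right-skewed.  The default ξ is 1.5; when a
site contributes ≥ 5 values, ξ is estimated by inverting the two-piece
skewness relation on the sample skewness (clamped to the attainable range,
about ±0.995).  Draws are clipped at zero — negative stocks are unphysical
— and the analytic clipping bias (computed by quadrature of the density) is
logged; when it exceeds 1% of the mean the draws are re-centred by the bias.

One Monte-Carlo iteration draws one value per site, interpolates, and sums
per-cell masses; the estuary estimate is the mean and standard error
(sd/√n) of 100 iteration totals.  The (cells × sites) weight matrix is
precomputed once, making an iteration a single matrix-vector product; the
default synthetic mask (≈ 58,000 cells of 20 m) runs the full pipeline in
seconds.  Grid resolution is a config choice: halving the cell size changes
zero-variance areal means by well under 0.5%.

Aboveground stand N is biomass × the composition-weighted species N
content (A. germinans 0.26%, L. racemosa 0.157%, R. mangle 0.205%,
non-mangrove canopy 0.31%).  Aboveground accumulation rates are accepted as
site inputs (1.7–3.0 g m⁻² y⁻¹ in the default templates); how to derive
them from growth studies is out of scope.

## Food-nitrogen flow model

Annual food N = population × per-capita food demand × 2.45% N.  The
per-capita demand default, 286.1 kg y⁻¹ (≈ 7.0 kg N person⁻¹ y⁻¹), is
back-derived from the reference watershed budget (5,390 Mg over 769,000
people); the composted share of the municipal solid-waste stream, 5.96%,
is back-derived the same way (122 of 2,046 Mg).  Streams: 38% municipal
solid waste (landfill + compost), 44% ocean-bound treated wastewater, 18%
septic; flows balance the input exactly because human stock change is
taken as zero.  The post-hoc child check (20% of the population gaining
2.5 kg y⁻¹ at 2% N, i.e. 0.05 kg N each) quantifies that assumption:
7.7 Mg y⁻¹, under 0.5% of the wastewater flows.  Site-level budgets use a
circular 500 m buffer (78.54 ha).

## Porewater

DIN = NH₄⁺ + NOₓ with non-detected NOₓ set to 0 (default; the more
conservative variability estimate) or to the detection limit (0.05 μM
default); the two policies are verified to give identical significance
calls on the synthetic fixture.  Molar N:P = DIN/PO₄³⁻ (both μM), reported
to one decimal.  Site × season comparisons ln-transform values as
ln(x + dl) (the offset guards zeros; the source offset is unstated),
fit a two-factor OLS with interaction, report a Shapiro–Wilk residual
check, and test all site-within-season and season-within-site pairwise
contrasts with the pooled residual variance, Bonferroni-adjusted at
familywise 0.05.

## Isotope profiles

δ³⁴S depth profiles are fit by OLS as linear or quadratic polynomials in
the slice midpoint depth.  Under automatic selection the quadratic is kept
when its curvature term is significant at 0.05 (for numerically exact fits,
when the curvature is non-negligible) — the original "best fit" criterion
being unstated, this is the package's choice.  Site comparisons compute
per-term confidence bounds at level 1 − 0.05/m (Bonferroni), with m
defaulting to (site pairs) × (shared terms), so the familywise chance of a
false "different" call stays at 5%; terms differ when the closed intervals
are disjoint, and a quadratic term cannot be compared against a linear fit.
δ¹⁵N period means need no new machinery: they run through the bootstrap
engine on slice values and the overlap rule.

## Synthetic estuary

The generator emulates a five-site peri-urban estuary spanning an
urbanisation/flushing gradient: a dredged well-flushed canal end (high bulk
density ~0.85, low %N 0.49), a clogged sewage-influenced canal end (SAR
6.0 mm y⁻¹, %N 0.74), a low-density high-%N lagoon (ρ 0.16, %N 1.24), an
intermediate lagoon with a dredged inlet, and an isolated hypersaline
forest (SAR 5.5, %N 1.54, porewater NH₄⁺ ~1,057 μM wet season).  These
means put the deterministic per-site budgets inside the observed envelopes
(bulk density 0.14–1.02 g cm⁻³, SAR 1.3–6.2 mm y⁻¹, recent accumulation
~3.7–27.9 g m⁻² y⁻¹).  Within-site values are right-skewed (ξ = 1.8) with
coefficients of variation around 16%, and a global `noise_scale` multiplies
every sd (0 gives exact template means).

Cores are sliced 1 cm to 3 cm depth then 2 cm to the bottom (45 cm
default).  Dates follow a linear-within-period age-depth relation using
each site's own period SAR, so the recent/historic depth break varies by
site around the ~18 cm estuary-wide pattern rather than being imposed;
real cores have nonlinear apparent age models, and this linearity is a
deliberate simplification for testability.  δ³⁴S is generated from
site-specific quadratics (surface-enriched at poorly flushed sites,
surface-depleted at the dredged site; one linear site), δ¹⁵N from period
means plus noise, and porewater from seasonal cell means.  Each bundle
carries a `GroundTruth` record derived deterministically from the template
means and the (noise-independent) slice/date structure, including
deterministic IDW estuary totals.

What passing these tests shows: the arithmetic, resampling, interpolation,
and accounting machinery are correct and unbiased under the generator's
assumptions, at the study's design scale (5 sites × 2 cores, 100
iterations).  What they do not show: robustness to dating error,
compaction, non-stationary accretion, spatially structured heterogeneity
between sites, or mask misclassification — none of which the generator
simulates.

## Problem sizes and determinism

Default desk-scale settings — 1,000 bootstrap replicates, 100 Monte-Carlo
iterations on a ~58,000-cell 20 m mask, 500-repetition coverage studies —
were chosen so the full test suite and the acceptance script each complete
in well under a minute of compute while keeping Monte-Carlo error far
below the tolerances tested.  All randomness flows from a single seed
through named substreams, so identical configuration and seed reproduce
every numeric output byte for byte (the run manifest echoes both).
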