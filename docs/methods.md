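# Methods

This note records the modelling choices, default parameters and numerical
conventions behind each pipeline stage, and what the synthetic-data tests
do and do not demonstrate.

## Data model

Surveys are sites x metals concentration tables in mg/kg dry weight over a
closed metal set reported in a fixed order (Cd, Pb, As, Cr, Ni, Cu, Zn,
Fe). A `fraction` label distinguishes the aqua-regia total from the
extractable (DTPA; CaCl2 for Pb) fraction. Validation rejects negative or
missing cells and duplicated site ids; the availability screen reports
per-cell available/total ratios, flags division by a zero total as
undefined rather than failing, and ranks metals by mean ratio.

## Registry defaults and their provenance

The geochemical background (Cd 0.3, Pb 9.5, As 0.625, Cr 12, Ni 14.3,
Cu 3.5, Zn 26.5, Fe 6054.5 mg/kg) is the uncontaminated local reference
soil of the case study the package is benchmarked against; the Nemerow
standard is the WHO soil-quality guideline row (Pb 100, Cd 2, As 25,
Cr 150, Ni 50, Cu 100, Zn 300 mg/kg; none used for Fe).

Route-specific reference doses and cancer slope factors are not printed in
that study's main text. The shipped registry was reconstructed by solving
the study's printed intake -> hazard-quotient and intake -> cancer-risk
pairs cell by cell and cross-checking against standard USEPA/RAIS values;
every constant is verified in the test suite by regenerating the printed
cell it came from. The same applies to the exposure profiles (child IngR
200 mg/d, InhR 7.3 m3/d, SA 2800 cm2, AF 0.2 mg/cm2, EF 350 d/yr, ED 6 yr,
BW 15 kg; adult 100, 20, 5800, 0.07, 350, 24, 70; ABS 0.001, PEF 1.36e9
m3/kg for both). Two notable outcomes of that reconstruction:

- the adult skin area that reproduces the printed dermal intakes is
  5800 cm2 (5700 misses every adult dermal cell by ~1.7 %);
- the averaging time is AT = ED x 365 for both the non-carcinogenic and
  the carcinogenic pathway; the printed carcinogenic cells are only
  consistent with this choice, not with a 70-year lifetime AT. A
  consequence worth knowing: TCR here scales with ED through neither term
  (ED/AT cancels), so it is an annualised rather than lifetime-integrated
  quantity.

All registries are user-overridable from YAML; `show-defaults` prints the
shipped values for audit.

## Pollution indices

Summary statistics of per-site indices are always computed site-wise and
then aggregated. The distinction matters for log-based quantities: by
Jensen's inequality mean(Igeo) <= Igeo(mean concentration), so a mean
Igeo/EF quoted from per-site values cannot be reproduced from the mean
profile alone (the suite asserts the inequality direction instead).

Class gradings treat each printed bin as lower-exclusive/upper-inclusive,
so an exact boundary value falls in the lower class; printed inclusive
extremes (Igeo >= 5 extremely polluted, PERI >= 600 high risk) override
this at the top end. The Igeo lithogenic correction factor is fixed at
1.5.

One printed-rounding artifact is tolerated knowingly: the benchmark
study's "times background" series quotes Cr as 1.60 while 19.096/12 =
1.5913 rounds to 1.59; the suite accepts |difference| <= 0.011 for that
single entry and two-decimal equality for the other seven metals.

## Ecological risk

Eri = Tr x Cf with the standard Hakanson toxic-response factors; Fe has no
factor and is excluded from PERI. PERI is linear in concentration and
exactly the per-site sum of Eri; class shares and the fraction of sites
above any breakpoint are reported alongside.

## Deterministic health risk

The three intake equations, HQ/HI/THI and CR/TCR are linear in
concentration at a fixed profile. Printed-table regeneration tests compare
at 1.5 % relative tolerance because the printed inputs carry two decimals.
Cells excluded as internally inconsistent (with the inconsistency
documented in the tests): the child Pb-inhalation CR column (printed min >
max; mean ~10^3 times the slope-factor-consistent value), the totals
inheriting it, and the adult non-carcinogenic totals rows, whose printed
sums demonstrably omit As.

## Monte-Carlo risk and sensitivity

Inputs are independent marginals (no copula), matching common
Crystal-Ball practice. Defaults: per-metal concentrations lognormal,
moment-matched to the survey mean and CV; exposure frequency
triangular(180, 350, 365) d/yr; body weight normal (15 +/- 2 child,
70 +/- 10 adult, truncated at 0); duration and rate parameters point
values; AT derived as ED x 365 inside each draw. The risk model applied
per draw is exactly the deterministic pipeline, so degenerate (point-mass)
inputs reproduce the deterministic THI/TCR at every percentile to machine
precision. Percentiles use linear interpolation between order statistics.
Sensitivity is the signed normalised squared Spearman correlation
(contribution-to-variance); variance-based (Sobol) indices are out of
scope. The default run is 10^4 iterations, which stabilises the median to
well under 1 %.

Because the upstream study's input-distribution table is unavailable, the
probabilistic stage is validated by properties (degeneracy, symmetry,
convergence, sign structure), not by matching its printed percentiles.
With the defaults above, the sensitivity ordering nevertheless agrees
qualitatively with that study: exposure frequency is the dominant positive
contributor and body weight the dominant negative one.

## Weighted PMF

Uncertainties follow the EPA convention; the error fraction defaults to
0.1 (configurable) and the MDL to 0.001 mg/kg for all metals. The
below-MDL branch uses u = (5/6) MDL; the above-MDL branch reads the
quadrature form sqrt((ef.c)^2 + MDL^2).

The optimizer alternates exact row/column nonnegative least squares
(scipy `nnls`), which makes Q non-increasing per sweep — asserted in the
tests. Convergence: relative Q change < 1e-8 over a full sweep, at most
2000 sweeps; non-convergence is reported, never silent. Restarts: 20 by
default; the first start is the deterministic nonnegative double-SVD
(NNDSVD), the rest uniform random with seeds spawned from the master seed.
The plain-random starts alone fall into local minima on exactly low-rank
data in a majority of runs, which is why the SVD start is included. The
factor scale ambiguity is resolved by normalising each profile row to unit
sum; contributions absorb the scale. Per-metal r2 is the squared Pearson
correlation between observed and reconstructed columns; factor percent
contributions are column-normalised reconstructed mass.

## Multivariate statistics

Spearman correlations mid-rank ties and flag constant columns as NaN; the
two-variable case degenerates in scipy to a scalar and is re-expanded.
KMO uses partial correlations from the inverse correlation matrix (the
identity matrix yields an undefined, NaN, KMO — the p = 2 case is
identically 0.5). Bartlett uses the chi-square approximation
-(n - 1 - (2p+5)/6) ln|R| with p(p-1)/2 degrees of freedom. PCA is an
eigendecomposition of the correlation matrix; loadings are eigenvectors
scaled by sqrt(eigenvalue), each column sign-flipped so its
largest-magnitude entry is positive; components with eigenvalue > 1 are
retained for the summary. Varimax rotation is available behind a flag but
off by default, since the benchmark's reported eigenvalues sum like
unrotated ones. Hierarchical clustering is out of scope.

## Synthetic surveys

The generator emulates the benchmark's structure: 30 sites, three latent
sources. The landfill source (Cd/Pb/As-heavy) decays exponentially
(rate 3) along a fixed equally-spaced unit transect — a deterministic
sampling design, so its contribution pattern is identical across seeds;
the agricultural source (Cu/Ni/Cr/Zn-heavy) is lognormal across sites
(mean 1, CV 0.5); the geogenic source is constant and Fe-dominated.
Loadings are solved so that background + expected source mass equals the
survey's per-metal means, splitting each metal's anthropogenic excess
70/30 (Cd), 60/40 (Pb, As) between landfill and agriculture and 20/75/5
(landfill/agriculture/geogenic) for Cr, Ni, Cu, Zn, with Fe mostly
geogenic. Measurement/field noise is multiplicative lognormal per cell
(concentrations are positive and right-skewed, matching the benchmark's
non-normality finding); its per-metal CV is solved analytically so the
total CV hits the survey targets (Cd 77 % down to Fe 3.1 %), floored at
1 %. Availability is a Beta(2, 18) ratio per cell (mean 0.1, matching the
scale of observed extractable/total ratios), which guarantees available
<= total.

What the synthetic tests show: arithmetic correctness of every index and
risk formula, exact ground-truth recovery by the PMF under low noise, and
the qualitative structure (CV ordering, landfill gradient, factor
identities). What they do not show: real soils have spatially correlated
sources, correlated measurement errors, censored values below detection
limits and non-lognormal outliers; none of these is modelled, so passing
tests certify the implementation, not field validity. Note also that with
the full default noise the three-factor PMF explains weakly-sourced,
high-noise metals poorly (low r2 for Zn/Fe on some seeds) — the
recovery guarantees are stated for the low-noise regimes the tests pin
down (exact at zero noise; all r2 >= 0.75 at 5 % noise).

## Problem sizes and runtime

Default problem sizes are chosen to match the study design rather than
stress hardware: 30-site surveys, 10^4 Monte-Carlo iterations, 20 PMF
restarts on a 30 x 8 matrix. The whole test suite runs in well under a
minute; the acceptance script is instantaneous (its aggregates are
deterministic).

## Known limitations

No speciation/valence-state toxicity (total concentrations only), no
spatial statistics beyond the 1-D transect proxy, no below-detection
censoring in the generator (the uncertainty matrix supports the below-MDL
branch), no Fpeak rotation or bootstrap error estimation for PMF, no
age-adjusted (ADAF) or food-chain exposure pathways.
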