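# Methods

## Exposure model

The deterministic core is the US-EPA inhalation chain
ADD/LADD = c·IR·EF·ED·CF/(BW·AT), HQ = ADD/RfC_dose, LTCR = LADD·SF.
Default parameter values (adult occupational exposure):

| parameter | male | female | units |
|---|---|---|---|
| IR (inhalation rate) | 19.02 | 14.7 | m³/day |
| BW (body weight) | 62.7 | 54.4 | kg |
| EF (exposure frequency) | 261 | 261 | days/year |
| ED (exposure duration) | 24 | 24 | years |
| AT non-cancer | 8760 (= ED·365) | 8760 | days |
| AT cancer | 25550 (= 70·365) | 25550 | days |
| CF | 10⁻³ | 10⁻³ | mg/μg |

Toxicity: inhalation reference concentrations 0.05 (DMP), 2.8 (DEP),
0.02 (DBP), 0.07 (DEHP) mg/m³; DEHP is the only carcinogen, with slope
factor 0.014 (mg/kg-day)⁻¹.

Three numerical choices matter:

- **Unrounded RfC.**  RfC_dose = rfc_air·IR/BW is used at full precision;
  rounding it to the conventionally printed two significant figures
  changes HQ in the second decimal (DMP male: 6.95 unrounded vs 7.02 with
  RfC = 0.015).  A corollary is exact gender invariance of HQ: IR/BW
  cancels between the dose and the RfC conversion, so
  HQ = c·EF·ED·CF/(AT_nc·rfc_air) for either gender.  Published female HQ
  tables that differ from the male ones for some compounds are not
  algebraically reachable from this model; the package reports the
  consistent values.
- **Strict classification bounds.**  HQ = 1 exactly is acceptable
  ("exceeds 1" read strictly); LTCR = 10⁻⁴ exactly is "potential", not
  "severe".  The three cancer bands partition [0, ∞).
- **Loud failure for non-carcinogens.**  Requesting LTCR for a compound
  without a slope factor raises rather than returning 0, so a
  misconfigured toxicity table cannot silently produce zero risk.

HQ is reported from section-mean concentrations; the textual HQ *ranges*
use each compound's pooled min/max across both sections — the only
reading that reproduces all six published endpoints (0.4–22.6,
0.0046–0.55, 0.64–89.9).

## Descriptive statistics and correlation

Summaries use the sample SD (n−1).  The ΣPAEs pseudo-compound sums the
four compounds within each sample before summarizing, so its mean equals
the sum of compound means exactly whenever the panel is complete.  A
single-observation cell reports SD = 0 with a warning; an empty cell is
omitted with a warning.

Spearman correlations use average ranks for ties.  The two-tailed p-value
is exact — full enumeration of the n! rank permutations, counting
|ρ| ≥ |ρ_obs| — for tie-free columns with n ≤ 9, and the t-approximation
t = ρ√((n−2)/(1−ρ²)) otherwise.  At the study's n = 16 the printed
significance levels are approximation-based; at the administrative n = 6
the exact null is used.  A constant column has undefined ρ and is
reported as missing.

## Monte-Carlo LTCR

Input uncertainty is propagated by independent sampling of (c, IR, BW,
EF, ED) per trial.  The source study does not disclose its distributional
assumptions, so the default randomizes only the concentration, as a
lognormal moment-matched to the section mean and SD:

σ² = ln(1 + sd²/mean²),  μ = ln(mean²/√(mean² + sd²)),

with point masses for the exposure factors; alternative families (normal
truncated at 0, triangular, uniform) are selectable per variable.  Because
LTCR is linear in c and sampling is unbiased, the simulation mean equals
the deterministic point estimate up to Monte-Carlo error — and exactly,
bit for bit, when every input is a point mass (the degenerate case is
short-circuited to avoid last-ulp summation noise).  Default 100,000
trials; percentiles 15/25/50/75/90 by numpy's linear interpolation
between order statistics (percentile estimators differ in the third digit
at this n, so the rule is fixed here); results are reported both as LTCR
values and as multiples of the 10⁻⁶ acceptable-risk baseline, plus the
fraction of trials above it.  A seed is part of the result object;
identical seed and specs give bit-identical output.

The published percentile-to-baseline multipliers (58/449/1180/1910/2560)
depend on those undisclosed distributional assumptions and are treated as
qualitative context only; under the lognormal default the industrial
multipliers come out at roughly 370/510/910/1630/2760.

## Synthetic data generator

The raw per-sample measurements are unpublished, so the generator emulates
them: 16 industrial and 6 administrative samples.  Marginals are lognormal
— chosen because the published summaries show mean ≫ median with SD
comparable to the mean, i.e. strong right skew — moment-matched per
compound and section.  Cross-compound dependence is imposed by a Gaussian
copula: the target Spearman matrix (0.762 DMP–DBP, 0.606 DMP–DEHP, 0.471
DBP–DEHP; DEP pairs unreported and set to an invented 0.3) is converted to
a normal-score correlation via r = 2·sin(πρ_S/6), repaired to the nearest
positive semidefinite matrix by eigenvalue clipping if needed, and sampled
through Cholesky.  Draws are clipped to the published min/max envelope.

Clipping and n = 16 sampling noise mean a single generated table does not
reproduce the published moments exactly.  The fixture path
`moment_match_exact` therefore rescales each compound affinely (positive
slope, so rank correlations are untouched) to hit the target mean and SD
to 10⁻⁹; it never clips, and redraws from a deterministically derived
sub-seed in the rare case a rescaled value would go negative.  Exactness
tests run on this path; realism tests (moments within sampling error,
long-run rank-correlation calibration, KS distance of the marginal at
n = 10⁴) run on the stochastic path.

What the generator does *not* emulate: temporal autocorrelation,
seasonality, spatial layout of sampling points, measurement error and
censoring at the detection limit.  Tests passing on synthetic tables
therefore validate the arithmetic and the statistical machinery, not any
claim about new field data.

## Problem sizes

The test suite runs the Monte-Carlo engine at 10⁵ trials where the
convergence property is asserted and 10³–2·10⁴ elsewhere; generator
calibration uses 40–150 replicate seeds at the study sample sizes and one
n = 10⁴ draw for the marginal-distribution check.  The whole suite
completes in well under a minute.

## Known limitations

- Inhalation route only; dermal and ingestion routes are out of scope.
- Independence between Monte-Carlo inputs is assumed.
- The exact permutation p-value is limited to n ≤ 9 (n! growth).
- Section-mean HQ treats the mean as the exposure point estimate; no
  upper-confidence-limit exposure concentration is computed.
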