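# Methods

## The risk model

The package implements the USEPA quantitative scheme for inhalational
exposure. For the non-carcinogenic pathway the exposure concentration is

    EC = C · ET · EF · ED / AT        [mg/m³]

and the hazard quotient HQ = EC/RfC; HQ ≥ 1 is read as potential adverse
non-carcinogenic effect. For the carcinogenic pathway the chronic daily
intake is

    CDI = C · IR · ED · EF / (BW · AT)   [mg/kg-day]

and the lifetime cancer risk LCR = CDI · SF; the slope-factor route is used
throughout because inhalation unit risks are not available for all four
analytes (no SF exists for toluene and xylene, so their LCR is reported
*absent*, never zero). LCR bands are left-open/right-closed:
definite (> 10⁻⁴), probable (10⁻⁵, 10⁻⁴], possible (10⁻⁶, 10⁻⁵],
negligible (≤ 10⁻⁶), so each boundary belongs to the lower category.
Because the linear model can produce LCR > 1, values are clipped to 1 with
a warning.

### Averaging-time conventions

The symbol AT is the standing ambiguity of this model family: source
studies sometimes print a single number (e.g. 9000) without a unit and use
it in both pathways. The package therefore exposes two modes:

- **usepa** (default): AT for the non-cancer pathway is the exposure
  duration expressed in hours (ED·365·24), so EC reduces to
  C·(ET/24)·(EF/365) — a time-fraction discount with EC ≤ C, in which ED
  cancels exactly. AT for cancer is the 70-year lifetime, 25 550 days.
- **paper**: EC = C·ET·ED·EF/AT with AT taken verbatim (default 9000).
  This reproduces the literal printed equation; its output is not a
  physical concentration discount and can exceed C by orders of magnitude.

Every report records which mode produced it. Note the asymmetry under
"usepa": ED cancels in EC but not in CDI (whose AT is the fixed lifetime),
so duration uncertainty affects only the cancer endpoint.

Published mean HQ/LCR tables from studies using opaque software chains and
the unit-ambiguous AT cannot be recovered from summary statistics alone;
the package does not attempt to, and its validation instead rests on the
exactly reproducible constants plus the property suites described below.

## Exposure arithmetic

- TWA is the duration-weighted mean of shift samples; below-LOD samples
  are substituted before averaging (policy configurable: LOD/√2 default,
  LOD/2, 0, or LOD — the √2 convention is the usual low-censoring choice).
- ppm ↔ mg/m³ uses the molar volume 24.45 L/mol (25 °C, 1 atm, the ACGIH
  convention; 22.41 for 0 °C is provided). This constant reproduces the
  published BTEX limits: benzene 0.5 ppm → 1.60, ethylbenzene 20 ppm →
  86.84, xylene 100 ppm → 434.19 mg/m³.
- Brief & Scala: the daily form RF = (8/h)·(24−h)/16 and the weekly form
  RF = (40/H)·(168−H)/128 (H = weekly hours) are both implemented; the
  default takes the smaller (more protective) of the two and clips at 1.
  A 24-hour day is rejected (no recovery time).
- TLV exceedance is strict (>): a TWA exactly at the limit is not an
  exceedance.
- LOD = 3.3·SD(blanks)/slope, linear in the blank SD and inversely
  proportional to the calibration slope.
- An optional recovery correction (divide by the mean desorption recovery,
  e.g. 0.92) exists but is off by default, since published campaigns do
  not always state whether their figures are recovery-corrected.

## Stochastic input models

Concentrations are **lognormal** — positive and right-skewed, consistent
with stratum tables where the SD is of the same order as the mean — fitted
by moment matching on the natural scale:

    μ_log = ln(m²/√(m²+s²)),  σ²_log = ln(1 + s²/m²)

and truncated by rejection sampling to the stratum's observed [min, max].
The match targets the *untruncated* law, so the truncated distribution's
moments differ from (m, s); all recovery checks compare against the
truncated moments obtained by numerical integration, not the naive
targets. Degenerate inputs degrade gracefully: zero spread gives a
constant, fewer than three positive samples an empirical-resampling
fallback with a warning.

Questionnaire factors are **uniform** over their reported ranges — ET
[8, 12] h/day, EF [234, 270] d/yr, ED [21, 40] yr, BW [70, 97] kg — with
the inhalation rate fixed at the adult default 16 m³/day. Uniformity is
the least-informative choice given only a range; all specs are
overridable. All sampled inputs are independent.

## Monte-Carlo engine

Default 1000 iterations per stratum; summaries report mean, SD (n−1), the
full integer percentile grid 1…99 by linear interpolation between order
statistics, P95, and the 1%/99% "certainty band", plus the category at the
mean and at P95. Seeding is hierarchical: each (workstation, season,
analyte) stratum derives its own stream from the master seed and a CRC of
the stratum key, so identical seeds give bit-identical summaries and
adding strata never perturbs existing ones. Draw order within a stream is
fixed (C, ET, EF, ED, BW).

The paired seasonal comparison uses **common random numbers**: both
seasonal concentration models are evaluated by inverse-CDF transform of a
shared uniform stream and the factor draws are reused, so the
summer-minus-winter difference estimate carries far less Monte-Carlo noise
than independent streams would — the appropriate design when the quantity
of interest is the *difference* between two configurations.

## Seasonal statistics

The Friedman test is computed from the rank formulas with midranks and the
standard tie correction,

    χ²_F = (k−1) Σ_j (R_j − n(k+1)/2)² / (A − C),

A = Σ rᵢⱼ², C = nk(k+1)²/4, with p from the χ²(k−1) upper tail. At k = 2
without ties this is exactly the two-sided sign test, χ²_F = (2b−n)²/n
with b the number of blocks favouring season 2 — the test-suite exploits
this as a brute-force oracle, enumerating all 2ⁿ sign patterns for n ≤ 12.
The χ² tail is a continuous approximation to that discrete null; over
n ≤ 12 its absolute error can reach 0.44 (0.27 for n ≥ 8), shrinking with
n, which is why small-campaign p-values near a decision threshold should
be read with care. Fully tied blocks contribute no information; an
all-tied matrix returns statistic 0, p = 1.

The KS normality check compares the empirical CDF against a normal with
the sample's own mean and SD. Because the parameters are estimated (the
Lilliefors situation), the asymptotic Kolmogorov p-value returned is an
upper bound on the true one; the result object flags this. Small p
therefore remains decisive evidence against normality, while large p is
weaker evidence for it.

## Synthetic campaign generator

The generator emulates a paired two-season occupational campaign: each
subject receives a workstation (equal allocation by default, by
largest-remainder rounding — per-workstation counts are rarely published),
one set of uniform questionnaire factors, and per season and analyte a
fixed number of shift samples (default 3) from the stratum's truncated
lognormal, with sampling durations uniform on [80, 120] min. Defaults are
the study conditions: 84 subjects (hence 252 shift samples per
analyte-season) and 25 field blanks whose signal SD feeds the LOD formula.
Subjects are generated in both seasons so the Friedman design is complete.

What the generator does *not* emulate: within-subject correlation across
analytes or across seasons beyond the shared subject factors, day-to-day
autocorrelation of shift samples, censored (below-LOD) measurements
(generated campaigns mark all samples detected), meteorological
covariates, and any systematic sampling or analytical bias. Passing the
recovery and ordering tests therefore demonstrates that the pipeline's
arithmetic and propagation are correct under the stated model, not that
the model captures every feature of real campaign data.

## Numerical choices and problem sizes

- Truncated-lognormal moments are computed by adaptive quadrature of
  x·f(x) and x²·f(x) over the truncation interval.
- Rejection sampling retries out-of-bounds draws for up to 1000 rounds,
  then clips — with published ranges the inside mass is ≥ 0.91 per
  stratum, so clipping is never reached in practice; a truncation interval
  with essentially zero mass raises a named error instead of looping.
- Moment-recovery validation uses 2000-subject cohorts (≈1500 draws per
  stratum), at which the worst stratum error across all 32 strata is
  comfortably inside 10% of the integrated truncated moments.
- Closed-form oracle checks run at 10⁵ iterations with 3-standard-error
  bands; the seasonal CRN comparison uses 2·10⁴ iterations.
- Percentile estimation uses numpy's linear interpolation; with 1000
  iterations the extreme grid points (1%, 99%) carry the largest sampling
  noise, which the `mean_in_band` flag acknowledges rather than hides.

## Known limitations

- Inhalation route only; no dermal or oral pathways.
- Independence of all sampled inputs; no correlation structure between
  concentration and workload, or among exposure factors.
- The lognormal family is an assumption, not an inference from raw data;
  only stratum summaries (mean, SD, range) inform the fit.
- The paired-design assumption (every subject measured in both seasons) is
  structural in the generator and the Friedman reduction; campaigns with
  unpaired subjects would need a different test.
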