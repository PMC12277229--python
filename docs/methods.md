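# Methods

## Scope and data model

The package analyses per-well records from school tubewells: location
(WGS84), depth (feet), field physicochemistry (pH, EC in µS/cm, TDS in
mg/L, temperature in °C, salinity in practical units) and the two analytes
of health concern, iron and arsenic (mg/L). Concentrations come from field
kits with hard instrument ranges, enforced as record invariants: the iron
colorimeter reads 0.00–5.00 mg/L at 0.01 mg/L resolution; the arsenic test
kit's primary range is 0.00–0.5 mg/L. Arsenic readings in (0.5, 5] — the
kit's extended scale — are kept but flagged as suspect rather than
rejected, since the two ranges are documented inconsistently for the
instrument. Missing optional fields are explicit NaN, never zero: a zero
concentration is a legitimate non-detect here.

Union names are canonicalized through an alias map (Baguan→Bagoan,
Moahajanpur/Mahajanpur→Mohajanpur) because field records spell them
inconsistently.

## Guideline registry and exceedance accounting

The registry ships as YAML with one rule per (authority, parameter):
pH 6.5–8.5 for all three authorities (range rule), EC WHO 250 µS/cm,
TDS WHO 600–1000 / US EPA 500 / BDWS 1000 mg/L, Fe 0.3 mg/L (WHO, US EPA)
and 0.3–1.0 mg/L (BDWS), As 0.01 mg/L (WHO, US EPA) and 0.05 mg/L (BDWS).
Two semantics are explicit per rule: `above_upper` (value > upper) and
`outside_range` (outside [lower, upper]). The BDWS iron band counts an
exceedance only above its 1.0 mg/L upper bound — the reading that matches
the published per-authority counts. Percentages are rounded half-up to one
decimal.

Two deliberate fidelity choices, both overridable:

- The source accounting reports zero pH exceedances although its pH
  minimum (6.12) lies below 6.5. The default reproduces that accounting
  (pH never flags); `strict_ph=True` applies the range rule literally.
- The WHO TDS band (600–1000) counts only above the upper bound by
  default; the published TDS counts are internally inconsistent across
  authorities (a lower threshold cannot yield fewer exceedances than a
  higher one), so no golden value is built on them.

## Exposure model and the two parameter families

Risk follows the US EPA deterministic ingestion model (CDI = C·IR·EF·ED /
(BW·AT), HQ = CDI/RfD, HI = ΣHQ). The shipped parameter sets use IR = 1.0
L/day (school-time intake only), EF = 230 days/year, ED = 5 years and
AT = EF·ED = 1150 days, so CDI reduces to C·IR/BW.

The survey quotes body weights of 20 kg (girls) and 24.68 kg (boys) and an
iron RfD of 0.7 mg/kg/day, but those inputs do not reproduce its printed
per-union HQ ranges. Solving HQ·BW·RfD = C over the printed extreme pairs
shows the published table is consistent — across all four unions and both
analytes — with BW = 15 kg and RfD_Fe = 0.007 mg/kg/day (RfD_As = 0.0003
unchanged). All three sets ship (`stated-girls`, `stated-boys`,
`table-consistent`); the last is the default for golden comparisons, and
no claim is made about which the authors intended. Reported HQs round
half-up to two decimals with trailing zeros stripped (25.90 prints as
25.9), matching the published formatting.

## Safe-intake limits

FIR = BW·RfD·AT/(EF·ED·C) is the intake at which HQ = 1; the combined
limit solves HI = 1 and is the harmonic combination of the per-analyte
limits. The model is unit-aware with C in mg/L; a ×10³ factor applies only
when C is supplied in µg/L (dimensional analysis: kg · mg/kg/day ÷ mg/L =
L/day, and the benchmark value 0.06 L/day at C_As = 0.075 mg/L confirms
it). Zero concentration imposes no limit and is reported as an unbounded
sentinel (`inf`), optionally capped for presentation; caps are never
applied silently (a `capped` flag travels with the record).

## Synthetic cohort generator

The generator emulates the study design: n = 75 wells split 29/15/17/14
across the four unions, depth 100–560 ft, and the published marginal
moments (pH 6.85±0.24 on [6.12, 7.8], EC 900.27±290.48, TDS 460.50±144.30,
Fe 0.94±0.92, As 0.03±0.05, depth 311.20±126.14). Temperature (26.5±1.5 °C)
and salinity (0.45±0.15) have no published moments; the defaults are
realistic shallow-aquifer values chosen once.

Scheme: a latent multivariate Gaussian per sample, pushed through marginal
transforms — moment-matched truncated normals for pH, EC, TDS,
temperature, salinity and depth; left-censored ("tobit") normals for Fe
and As, whose point mass at zero reproduces non-detects, right skew, and
the published exceedance fractions far better than a lognormal while
keeping strong Pearson coupling attainable (a lognormal margin caps the
achievable |r| with depth below the 0.71 target). Arsenic is then snapped
to the kit's read-out grid {0, 0.005, 0.01, 0.025, 0.035, 0.05, 0.075,
0.1, 0.175, 0.25, 0.5} mg/L — a modelling choice consistent with the
printed per-union extrema, not a published fact — and iron is rounded to
the 0.01 mg/L colorimeter raster (exact midpoints snap downward, a
deterministic tie-break).

Because monotone transforms and quantization attenuate Pearson
correlation, the latent pairwise correlations are calibrated so the
*observed* correlations hit the five targets (TDS–EC 0.92, TDS–salinity
0.7, As–depth −0.71, Fe–depth −0.34, Fe–As 0.22) in expectation: the
observed correlation as a function of latent ρ is evaluated by bivariate
Gauss–Hermite quadrature (96 nodes) and inverted by Brent root-finding.
The calibration is deterministic and cached; an unattainable or jointly
infeasible target set raises an error naming the offending pair. The
untargeted EC–salinity entry is filled by conditional independence through
TDS to keep the latent matrix positive definite. Seeding: one master seed;
each union draws from a fixed-offset substream, so the same seed is
bit-identical and per-union draws are stable.

What the generator does **not** emulate: spatial autocorrelation
(coordinates are uniform in the study bounding box, for plumbing only),
seasonal variation, measurement error beyond quantization, and the
physically implausible EC/TDS minima in the source table (2.72 µS/cm and
1.37 mg/L; available behind `include_outliers`). Passing tests on this
cohort therefore demonstrate correctness of the accounting and modelling
machinery under the study's marginal/correlation structure, not claims
about any real aquifer.

## Association statistics

The Pearson matrix uses pairwise-complete observations; zero-variance
variables yield NaN entries with a warning. Depth regressions are ordinary
least squares of concentration on depth. PCA runs on the correlation (not
covariance) matrix because the indicators carry mixed units; variables are
log10-transformed with a zero offset of half the smallest positive
observed value (Fe = 0 and As = 0 occur), centered and unit-scaled, and
decomposed with `eigh`. Each loading row is oriented so its
largest-magnitude entry is positive — a deterministic sign convention so
results are reproducible run to run.

## Surrogate model

Features: union integer code (alphabetical codebook: Bagoan 0, Dariapur 1,
Mohajanpur 2, Monakhali 3), depth, Fe, As, pH, EC, TDS, plus four binary
exceedance flags (Fe>0.3 WHO, Fe>1.0 BDWS, As>0.01 WHO, As>0.05 BDWS) —
eleven features in a fixed, recorded order. Target: log combined FIR;
wells with unbounded limits (both analytes zero) are excluded before
training and the exclusion is logged. The log tames the heavy right tail.

Architecture: [16, 8] rectified hidden units by default — deliberately
small for a tabular problem of this size — with configurable activation.
Training is mini-batch SGD (batch 32, 400 epochs, η = 0.02 by default);
the update applies the L2 penalty gradient inside the step,
`w ← w − η(α·w + ∂Loss/∂w)`, with biases unpenalized. Features and target
are centered/unit-scaled using training-split statistics only (no
leakage). The 90/10 split is seeded and stratified by union; tenfold CV
assigns folds from the seed so every row validates exactly once per α in
the half-decade sweep {0.10, 0.3162, 1.0, 3.1623, 10.0}. A non-finite loss
aborts with a suggestion to lower η. A constant target short-circuits to
an exactly constant predictor with R² reported as undefined.

Shapley attribution is exact for ≤ 12 features: all 2^p coalition grids
are evaluated in one batch, with absent features drawn from the background
table (interventional convention), so the efficiency axiom (baseline +
Σφ = prediction) holds to machine precision and linear models recover the
closed form φ_i = w_i(x_i − mean background_i). Beyond 12 features a
seeded permutation-sampling estimator reports Monte-Carlo standard errors
alongside the values.

The α-sweep clustering diagnostic is a documented, reproducible analogue
of an under-specified step in the source analysis: per α, a seeded
two-means on standardized (prediction, residual) pairs, reporting group
sizes and co-assignment agreement with the smallest-α partition (maximized
over label swap). It is purely descriptive and makes no claim to reproduce
the source's cluster confidence figures, whose construction is not
recoverable. Similarly, the source's "87% accuracy" is treated only as a
qualitative band: the test suite requires held-out R² ≥ 0.85 and
correlation ≥ 0.92 against the analytic limit on 500-row synthetic
cohorts (10-seed median), which the default configuration exceeds.

## Numerical choices and degenerate inputs

- Reporting rounds are decimal half-up (never banker's rounding).
- Quantization ties snap downward; `-0.0` is normalized to `0.0`.
- Truncated-normal moment matching uses a root solve on (µ, log σ); if the
  requested moments are unattainable on the support, the generator falls
  back to plain truncation of the stated moments.
- The latent correlation matrix receives a 1e−12 diagonal jitter before
  Cholesky to tolerate exactly singular target sets.
- Empty datasets: descriptive statistics and compliance require n ≥ 1 and
  raise otherwise; validation returns an "empty" report instead.

## Problem sizes used in the checks

Golden hazard-quotient values are single closed-form evaluations.
Generator-recovery checks use n = 5000 over 10 seeds; surrogate-quality
checks use 500-row cohorts over 10 seeds; oracle-recount checks use 50
random datasets of up to 50 rows. These sizes make sampling error small
relative to the stated tolerances while keeping the full suite fast.

## Known limitations

- The pipeline is deterministic by design; no probabilistic (Monte-Carlo)
  exposure assessment is included.
- No carcinogenic (slope-factor) risk, and no water-quality index — the
  upstream analysis defines neither.
- GeoJSON export replaces map rendering; no shapefile/geodatabase support.
- The published safe-limit maxima (e.g. 8.27 L/day) are not reproducible
  from the intake equation under any shipped parameter set; the package
  reports what the equation yields and does not enforce those values.
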