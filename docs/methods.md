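# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and what the test suite does and does not establish.

## 1. Large-fire probability and flammability thresholds

**Model.** Conditional on an ignition having occurred, the probability
that it grows into a "large" fire is modelled per ecoregion *i* as a
product of logistic limitations over control factors *j* ∈ {VPD, fuel
availability (NPP proxy), suppression (population-density proxy)}:

    f(x_ij) = 1 / (1 + exp(-alpha_ij (x_ij - beta_ij)))
    F_i     = prod_j f(x_ij)
    Y_i     ~ Bernoulli(F_i)

`alpha` (steepness, 1/units of x) is constrained positive for VPD and
fuel and negative for suppression; `beta` is the midpoint (50%
limitation).  The model is conditional on ignition by construction: it is
fitted only to events that occurred, so it expresses fire-weather
limitation, not ignition likelihood.

**Event table.** "Large" fires are the largest `percentile` (default 10%,
with 15% and 20% as sensitivity settings) of events within each ecoregion
and ignition type; an equal count of the smallest events of the same type
serves as the "small" class, and everything else is dropped.  This
balanced extreme-contrast design reflects a small-to-large risk
transition rather than a model of all fire sizes.  Size ties break by
(size, event id), so labelling is deterministic.  The VPD covariate is
taken on the fire's discovery date at the ignition cell (most fires last
one day); a duration-mean convention is available as a config switch.
Fuel and suppression covariates are annual per-cell fields, standardized
per ecoregion before fitting so their priors are scale-free; VPD stays in
kPa so thresholds are physical.  Events with unknown ignition cause are
never modelled.

**Hierarchy and priors.** Per factor and ignition type, the
per-ecoregion parameters are partially pooled:

    log(alpha_i) ~ Normal(mu_a, sd_a),   c_i ~ Normal(mu_c, sd_c)

where `c = -alpha * beta` is the linear-predictor intercept (see §5 for
why slope/intercept coordinates are sampled).  Hyper-priors are
weakly-informative and data-scaled: `mu_a ~ N(log(2/sd_x), 1.5^2)`,
`sd_a ~ HalfNormal(1)` truncated below at 0.05, `mu_c` centred so the
implied midpoint sits at the covariate median, `sd_c ~ HalfNormal` at the
covariate scale with the same truncation.  Human- and lightning-ignited
fires are fitted as fully separate models.

**Threshold.** For each posterior draw, the VPD-only logistic is
inverted at probability level p (default 0.9):
`VPD_t = beta_VPD + ln(p/(1-p)) / alpha_VPD`.  The reported threshold is
the posterior median with the 5–95% interval; the lightning-minus-human
difference is summarized from paired draws with the posterior probability
of a positive difference.  The threshold deliberately uses only the VPD
factor even when the fit adjusted for fuel and suppression: it measures
the VPD limitation alone.

**Sampling.** The posterior is explored with an affine-invariant ensemble
sampler using differential-evolution moves, with the likelihood
vectorized across walkers.  Defaults mirror a four-chains-of-1,000-draws
budget: ≥32 walkers (at least 2×dim+2), 1,000 warm-up and 1,000 retained
steps; a `thin` option trades steps for memory so slow-mixing
multi-factor fits can run longer chains (the pipeline default is 1,500
warm-up + 5,000 steps thinned to 1,000).  Walkers start from a bounded
MAP + Laplace approximation computed with batched finite differences.
Diagnostics: split-R̂ and effective sample size with walkers treated as
chains (optimistic for coupled walkers, hence paired with an
acceptance-fraction floor); a fit with max R̂ above the configured limit
(1.1) or acceptance below 0.05 is flagged failed but still returned.

## 2. Flammable days and trends

A day is flammable when daily VPD **strictly** exceeds the ecoregion's
VPD_t for the given ignition type; equality days are excluded.  Annual
counts per cell form the F_hm / F_ltn panels; ecoregion-level thresholds
apply to every cell of the ecoregion.

Trends are Theil–Sen slopes (median of pairwise slopes, via
`scipy.stats.theilslopes`).  Significance uses the Mann–Kendall S with
tie-corrected variance and an effective-sample-size variance inflation:
the series is detrended with the Sen slope, rank autocorrelations are
computed, and only lags significant at 5% (|ρ| > z₀.₉₇₅/√n) enter the
correction factor

    n/n* = 1 + 2/(n(n-1)(n-2)) * sum_k (n-k)(n-k-1)(n-k-2) rho_s(k).

A non-positive factor (strong spurious negative autocorrelation) falls
back to 1.  The test requires ≥ 8 points and uses the continuity-corrected
normal approximation, two-sided.  Under AR(1) nulls with φ = 0.6 the
uncorrected test rejects ≈ 30% at nominal 5%; the correction roughly
halves that inflation — it improves but does not fully restore size, a
known property of this correction family, which is why the calibration
test asserts *closer to nominal*, not *equal to nominal*.  The correction
variant is isolated in one function and swappable.

Group comparisons use the two-sided Wilcoxon rank-sum test
(`scipy.stats.mannwhitneyu`: exact for small untied samples, tie-corrected
normal approximation otherwise; all-tied inputs return p = 1 by
convention).  Per-cell significance maps carry no multiple-testing
adjustment, matching the fraction-of-area-significant summary style; a
correlation helper computes Pearson r between annual anomaly series over
common years.

## 3. Regularized optimal fingerprinting

**Preprocessing.** Observations and forced responses are annual regional
means (cosine-latitude weights), converted to anomalies (baseline:
full analysis period unless configured otherwise) and reduced to
non-overlapping 2-year means — 42 years become a 21-dimensional vector.
Odd-length series are an error rather than a silent trim.

**Internal variability.** Control runs are cut into non-overlapping
42-year windows (10 per 420-year run); windows alternate between two
disjoint pools per run, the odd extra going to the first pool.  Each
window is biennially reduced and centred.  Pool 1 gives C1 for
prewhitening; pool 2 gives C2 for uncertainty.  Both are Ledoit–Wolf
linear-shrinkage estimates toward a scaled identity
(`sklearn.covariance.ledoit_wolf`, assume_centered), positive definite by
construction (a floor of 1e-3 on the shrinkage weight guards degenerate
pools); no EOF truncation is needed.

**Estimation.** All series are multiplied by C1^{-1/2} (symmetric inverse
square root).  Each whitened forced response is scaled by √n_i (n_i =
total members behind its multimodel mean) so its ensemble-mean sampling
noise is white like the observation noise; the scaling factors are the
total-least-squares solution from the right singular vector of the
smallest singular value of the augmented matrix, rescaled back.  A
numerically tied smallest singular pair raises a non-identifiability
error rather than returning an arbitrary vector.  OANT is derived as
ALL − NAT − GHG at the ensemble-mean level, so its effective member count
satisfies 1/n_OANT = 1/n_ALL + 1/n_GHG + 1/n_NAT.

**Uncertainty and decisions.** Monte-Carlo perturbation with C2: noise
with covariance C2 (expressed in whitened coordinates) is added to the
whitened observation and, scaled by 1/√n_i, to each forced response; the
TLS problem is re-solved per draw (default 1,000, minimum 100) and the
5th–95th percentiles form the interval.  A forcing is *detected* when the
interval lies above zero (a one-sided 5% decision); *consistent with
observations* when it contains 1.  Attributable trends are
β̂_i × (Theil–Sen trend of the forced-response ensemble mean), with
interval endpoints mapped monotonically (swapped for negative trends) and
an `undetectable` flag when the scaling interval covers zero.

## 4. The synthetic-data generator

The generator emulates the study's inputs at desk scale with known truth:

- **Climate**: daily temperature and relative humidity per cell on an
  abstract regular grid (default 6×8 cells, 31–49°N), per-ecoregion mean
  + mid-July-peaked seasonal cycle + linear trend + AR(1) noise, with
  small fixed cell offsets scaled to the noise level.  The trend advances
  in annual steps so calendar-year means are exactly linear in year.  RH
  is clipped to [1, 100] so VPD (Tetens form,
  0.611·e^(17.27T/(T+237.3))·(1−RH/100) kPa) stays defined and
  non-negative.  Defaults: +0.35 °C/decade, −0.5 %/decade, AR(1) 0.7 —
  western-US-like magnitudes.
- **Fire catalogs**: Poisson ignition counts per ecoregion-year-type;
  lightning ignition dates use summer-peaked von-Mises-like day-of-year
  weights (κ = 2, peak mid-July), human ignitions are uniform over the
  year; each ignition is labelled large with the truth probability F_i
  at its cell/date; 8.5% of records have the cause withheld; sizes are
  decorative lognormals (larger for truth-large events) used only by the
  size-percentile labelling path; durations are 1 day with probability
  0.79, else 1 + geometric.
- **Covariates**: static per-cell standard-normal bases plus small
  interannual noise — proxies on an approximately standardized scale, not
  mechanistic fields.
- **Pseudo-ESM ensembles**: regional-mean flammable-day trajectories —
  GHG a linear ramp (0.4 days yr⁻¹ per year), OANT a mid-record-peak hump
  (0.35t − 0.008t²; the aerosol-era shape, which also keeps it
  identifiable against GHG), NAT an 11-year sinusoid (amplitude 3 days),
  ALL their exact sum — plus AR(1)(φ = 0.3, sd = 2.5 days) member noise
  and 19 control runs of 420 years.  The internal-variability magnitude
  was chosen so the three-signal scaling-factor uncertainty matches the
  regime of published regional fire-weather attribution (sd(β̂_GHG) ≈
  0.2–0.3); ensembles are 9 models × 3 members, DAMIP-like.

Every dataset carries a truth manifest (JSON, round-trips losslessly)
including analytically derived true thresholds and the scaling factors
applied to pseudo-observations.  One master seed spawns fixed named
substreams per stage, so any stage reruns in isolation bit-identically.

**What the synthetic data does not emulate:** spatial covariance of
weather beyond shared ecoregion forcing, fire spread across cells,
reporting biases in cause attribution, regridding artifacts of real
model output, and non-AR(1) (e.g. ENSO-band) internal variability.
Passing recovery tests therefore demonstrates correctness and calibration
of the *estimators under their assumed data-generating process*, not
robustness to the full messiness of the observational record.

## 5. Numerical choices

- **Slope/intercept sampling coordinates.**  The likelihood constrains
  `alpha*x - alpha*beta` jointly; when a factor's midpoint lies outside
  the covariate range (typical for weakly-limiting covariates), (α, β)
  posteriors form a banana along `alpha*beta ≈ const`.  Sampling
  `(log alpha, c = -alpha*beta)` linearizes this; β = −c/α is recovered
  per draw.  The prior placed on `c` plays the role of a midpoint prior
  centred at the covariate median.
- **Truncated group scales.**  The joint mode of a centred hierarchy
  degenerates as a group sd → 0, and ensemble walkers get trapped in the
  funnel neck; truncating the scale priors below at 0.05 (on standardized
  covariates, effectively full pooling) removes the sink with no
  practical loss of pooling flexibility.
- **Overflow-safe likelihood**: log-sigmoids via `logaddexp`, the z-score
  clipped at +30 (f within 1e-13 of 1), `log(1−F)` via `log(-expm1)`.
- **Degenerate inputs**: empty factor lists, all-zero weights, odd-length
  biennial input, gap-filled time axes, sub-minimum Monte-Carlo draws and
  sub-minimum covariance pools all raise immediately; excluded strata and
  short control runs are dropped with logged warnings.
- **Determinism**: artifacts that carry results (threshold CSVs,
  attribution JSON) are written with fixed float formatting and sorted
  keys; timestamps appear only in the run report.

## 6. Study sizes used by tests and the acceptance script

Chosen to exercise each claim at meaningful statistical resolution:
threshold recovery uses 20 replicate catalogs × 2 ignition types
(~2,000 events per ecoregion-type stratum, 2 ecoregions, VPD factor only,
32 walkers × 800+800 steps); trend-test calibration uses 2,000 AR(1)
series of length 42; fingerprinting calibration uses 500 replicates with
500-draw Monte-Carlo intervals; the demo pipeline runs the full
three-factor model on a 4×4 grid at reduced ignition rates with a
thinned 6,400-step chain.  The recovery study's coverage check pools the
80 resulting credible intervals and applies a 3σ binomial band around the
nominal 90%.

## 7. Known limitations

- The fingerprinting intervals are percentile Monte-Carlo around the
  observed fit; they are first-order calibrated (verified empirically)
  but can drift from nominal coverage at very low signal-to-noise, where
  TLS itself is heavy-tailed.
- R̂ across coupled ensemble walkers understates non-convergence relative
  to independent chains; the acceptance-fraction floor partially
  compensates.
- The variance-corrected Mann–Kendall test reduces, but does not
  eliminate, size inflation under strong autocorrelation.
- The binary large/small contrast does not model intermediate fire sizes,
  and case–control balancing means the fitted curves estimate the
  size-contrast limitation, not an absolute large-fire probability.
- Ecoregions are latitude bands on an abstract lattice; no projection or
  shapefile handling is included.
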