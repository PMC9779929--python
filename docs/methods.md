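# Methods

`stressgain` estimates annual genetic gain in grain yield from unbalanced
multi-environment maize hybrid trials conducted under managed drought
stress (MDS), a well-watered control (WW), artificial *Striga
hermonthica* infestation (STRIN), its non-infested control (STRNO) and a
large series of rainfed multi-environment trials (MET).  This note
describes the statistical machinery, the synthetic-data generator that
stands in for the (non-bundled) field data, the numerical choices, and
the limits of what the simulation studies demonstrate.

## The two-stage gain analysis

**Per-trial QC.**  Every location-year environment is first analysed on
its own with hybrids random (replicates and incomplete blocks random
where informative).  Generalized repeatability is computed on the
BLUP-difference basis

    h2 = 1 − v̄_Δ / (2 σ̂g²),

where v̄_Δ is the mean pairwise prediction-error variance of hybrid BLUP
differences from the mixed-model equations; h2 is defined as 0 at
σ̂g² = 0.  Trials with h2 below 0.2 (strict inequality) are discarded.
This generalized form is preferred to the classical
σg²/(σg² + σe²/r) because entries are not required to reach every
replicate; on balanced trials the two agree closely (the suite checks
within 0.02).

**Stage 1 — combined model per condition.**  Over the retained
environments of one condition, plot yields are modelled with hybrids and
years *fixed* (a random genotype main effect would shrink the very trend
being estimated, and year effects absorb the non-genetic trend),
replicates within environment, blocks within replicate, hybrid-by-year
interaction and (for multi-location conditions) location-within-year
random, and a separate residual variance per environment (per year for
the single-station MDS/WW series).  The hybrid adjusted means are the
BLUEs of intercept + hybrid effect, averaged equally over years, with
standard errors from the fixed-effect covariance.

**Stage 2 — weighted trend regression.**  The adjusted means are
regressed on each hybrid's year of first testing, weighted by the
inverse squared standard errors; inference is two-sided on n−2 df.  The
slope (kg/ha per year) is also expressed relative to the predicted mean
of the first testing year:

    percent gain = 100 · slope / (intercept + slope · first_year),

reported as undefined when that baseline is non-positive.  "Year of
origin" is operationalized as the year of first testing, the information
a trial series actually carries.  Check entries (the commercial and
local checks) are excluded from stage 2 by default because their origin
predates the program; a pooled mode is available.

**Known calibration property.**  Stage 2 weights by stage-1 precision
only, while the dominant scatter around the trend line is the genetic
deviation of hybrids (σG², identical for every hybrid).  When stage-1
SEs are small or heterogeneous relative to σG, the usual
scale-estimated WLS standard errors are mildly anticonservative.  Under
the recovery-study conditions below the empirical sd of the slope is
about 6% above its mean reported SE, 95% CI coverage is ≈0.93 and the
nominal 5% test rejects a true zero trend in ≈7–8% of replicates.  The
slope itself is unbiased.  This is a property of the two-stage weighting
scheme, not of its implementation; it is measured and asserted at that
level in the suite.

## REML core

All mixed models are fitted by a single REML engine supporting arbitrary
crossed/nested categorical random terms (one variance each) and
group-wise heterogeneous residual variances.  The restricted likelihood
is evaluated through the mixed-model equations: with W = [X Z] and
C = W′R⁻¹W + blockdiag(0, G⁻¹),

    −2 l_R = (n−p) log 2π + log|R| + log|G| + log|C| + y′Py,

and all score terms reduce to the diagonal of C⁻¹, so one Cholesky
factorisation and one inverse per evaluation yield the criterion and the
full analytic gradient.  Optimisation is quasi-Newton (L-BFGS-B) on
log-variances — iterates stay positive and boundary components decay
smoothly toward zero — with a Nelder-Mead fallback; components finishing
below 1e-7 of the response variance are reported as 0 with a boundary
flag.  Starting values put every component at half the response
variance; convergence is declared at machine-level relative change of
the criterion (well inside 1e-8).  The response is standardized
internally so tolerances are unit-free; estimates are returned on the
original scale.  Fixed factors use sum-to-zero contrasts, making the
intercept the equally weighted grand mean and adjusted means simple
contrasts.  Residual groups with fewer than 5 plots are pooled with the
group of nearest mean response (configurable), since per-environment
variances are otherwise unstable.  The suite verifies the MME-based
criterion against a dense marginal-covariance oracle and the optimum
against a surrounding parameter grid.

A note on prediction-error variances: the PEV reported for a BLUP is the
diagonal of the C⁻¹ random-effect block, i.e. Var(û − u) including the
fixed-effect estimation uncertainty (Monte-Carlo verified); the
known-mean shrinkage variance σg²(1−h) is smaller.  The uncertainty of
the overall mean cancels in BLUP differences, so repeatability is
unaffected by the distinction.

## Genetic correlations

**Between conditions.**  Hybrid adjusted means are modelled as
y_ip = μ + G_i + E_p + e_ip with a single genetic variance, fixed
condition effects (five levels) and one residual variance per condition;
the correlation between conditions p and p′ is

    r = σ̂G² / sqrt((σ̂G² + σ̂²_ep)(σ̂G² + σ̂²_ep′)),

with delta-method SEs from the observed information of the REML
criterion.  Two properties to keep in mind: the estimator interprets all
cross-condition covariance as genetic, so noisy adjusted means attenuate
r toward the plain Pearson correlation of the means; and the single-σG²
assumption makes the estimate a compromise when genetic variances differ
between conditions.  Both are documented behaviours, exercised but not
"corrected" — they are what the variance-ratio formula delivers.
Location shifts of any condition and common rescaling leave r invariant;
a per-condition rescale does not, precisely because of the single-σG²
structure.

**Between traits.**  A bivariate model with an unstructured 2×2 genetic
covariance is fitted to the per-hybrid adjusted means of two traits.
With one mean per hybrid and trait, genetic and residual covariance are
not jointly identifiable, so the stage-1 SEs enter as known residual
variances (residual covariance zero) and only the genetic covariance is
estimated, by REML over per-hybrid 2×2 marginals with the correlation
parameterized as tanh(z) (hence |r| ≤ 1 by construction; |r| > 0.9999 is
reported as ±1 with a boundary flag).  The plot-level entry point
computes per-trait adjusted means with the stage-1 model first.

## Trait structure

PCA uses the correlation matrix of the per-hybrid trait BLUPs
(complete-case; constant columns dropped with a warning), via a
symmetric eigendecomposition.  Eigenvector signs are fixed by making
each axis's largest-magnitude loading positive, so directional
statements ("higher PC1 goes with higher yield") are reproducible.
Trait-axis Pearson correlations equal loading × sqrt(eigenvalue) for
correlation-matrix PCA; both routes are computed and cross-checked.
Yield BLUPs are regressed on PC1 scores by OLS.

## The synthetic program generator

The generator emulates the structure of an eight-year (2012–2019)
regional testing program; since the real plot data are not bundled, it
is the source of every analysis input and the truth-maker for recovery
tests.

**Entry structure.**  112 DTSTR test hybrids with testing tenures
42/26/15/12/6/3/5/3 for 1..8 years, 30 commercial checks (12/8/2/3/2/1/1/1;
the 8-year and 6-year entries are the two Striga-resistant commercial
hybrids), one local check present throughout.  Entries are packed
deterministically: within class and tenure, first years cycle over the
feasible range, so every year receives new entries and multi-year
entries connect the series.  The field layout (entry order within
replicates, hence blocks of 6 plots) comes from a fixed stream, so
different noise seeds share the design skeleton exactly.

**Design per condition.**  MDS/WW: one station, 3 replicates.
STRIN/STRNO: two locations, 2 replicates.  MET: 174 location-year
environments over 8 years (22/22/22/22/22/22/21/21), 3 replicates.

**Plot model.**  yield = condition mean + s_env · (class offset +
trend·first-year + g_ic + hybrid×year) + year + location-in-year +
replicate + block + N(0, σ²_e(env)).  Genetic deviations g_ic are
equicorrelated across conditions through a shared factor (default
correlation 0.6, inside the 0.37–0.76 range such programs report).
Default trends are the per-condition annual gains the program realized
(11.89 / 62.65 / 86.60 / 102.44 / 53.11 kg/ha/yr for
MDS/WW/STRIN/STRNO/MET), carried by the DTSTR class only — checks are
static cultivars.  Default variances (σG² = 200 000, σGY² = 60 000,
σS² = 400 000, σY² = 150 000, σR² = 20 000, σB² = 15 000 kg²/ha², and
per-condition residual bases 550/440/450/450/680 ×10³ with lognormal
per-environment jitter, sd 0.25) were chosen once so that per-trial
repeatabilities land in the reported 0.5–0.9 ranges and trial means
match the reported levels; condition means 1900/4400/3900/4500/5600
kg/ha.  Negative plot yields are truncated at zero by default (physical
realism); the recovery studies disable the truncation because it
attenuates planted trends under severe stress means — recovery tests the
estimator under its model.

A configurable fraction of environments (defaults 40/174 for MET, 2/16
for STRNO — the discard counts of the real program) is generated with
the entry-level signal scaled by 0.05, emulating trials without usable
genetic signal; these are what the repeatability filter should remove.
Secondary traits are linear in the standardized yield genetic deviation
at configurable genetic correlations (negative for flowering dates, ASI,
ear aspect and the Striga damage/emergence traits; positive for heights
and ears per plant), with rating-scale traits rounded and clipped to
1–9 and emerged-parasite counts Poisson on a log link.

**What the generator does not emulate:** parasite population dynamics,
weather and soil-water processes, spatial field trends within trials,
selection-driven (non-random) entry and exit, and genetic-variance
erosion over cycles.  Passing recovery tests therefore demonstrate that
the estimation chain recovers the truth of *this* generating model at
these problem sizes — not that the field estimates carry the same
precision.

## Simulation studies and problem sizes

* **Trend recovery** uses the single-station MDS design (8 years, 3
  replicates) with a reduced entry list (28 DTSTR hybrids, ~10 per
  trial) so that hundreds of full pipeline replicates run in minutes:
  300 seeded replicates per planted trend (0, 12, 60, 100 kg/ha/yr) for
  bias and coverage, 200 for the type-I rate.  Bias is asserted as
  negligible relative to a single estimate's SE (0.15·SE plus a 2σ
  Monte-Carlo allowance), coverage against the 0.90–0.98 band.
* **Filter recovery** plants 10 no-signal environments among 50.  The
  null spread of per-trial h2 is ≈ sqrt(2/(k−1)) for k entries —
  at realistic 30–46-entry trials a null environment crosses the 0.2
  threshold with probability ≈0.13, so exact-set recovery is only a
  large-trial property; the study uses 420-entry unblocked 2-replicate
  trials (null crossing ≈0.2%) and requires exact recovery in ≥95% of
  20 seeds.  At field-realistic sizes the filter's ranking (all planted
  environments below all regular ones) is the property that holds, and
  is what the unit suite asserts there.
* **Correlation recovery** draws 150 hybrids' adjusted means per
  condition with known genetic correlation 0.5 and SEs of 60–120 kg/ha
  (the precision of means from a large MET series); the mean estimate
  over 50 seeds is required within ±0.05.  With noisier means the
  estimator attenuates, as described above.

## Degenerate inputs and edge conventions

Constant responses return all-zero components with the BLUE equal to the
constant.  Noise-free tables are fitted at the variance floor and
reproduce generating values exactly; stage-1 SEs of zero are floored at
1e-8 before weighting.  A trial with a single replicate is a QC error; a
stage-2 set with fewer than 3 hybrids or a single first-testing year is
a degenerate-design error.  h2 is clamped to [0, 1]; correlations are
clamped to [−1, 1] with boundary flags.  The repeatability filter keeps
a trial exactly at the 0.2 threshold.

## Analysis scripts

The numbered scripts under `analysis/` run the study end to end on a
generated program: 01 simulation (full default footprint for structural
summaries; a reduced 24-environment MET footprint for the model-fitting
scripts, keeping the combined MET fit affordable), 02 per-trial QC and
the filter, 03 the two-stage gain analysis with trend plots, 04 genetic
correlations (between conditions and yield-trait), 05 PCA and
yield-on-PC1, 06 check-relative comparisons and drought yield-reduction
percentages.  Each writes CSV tables (and plots) under `results/`.
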