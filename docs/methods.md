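# Methods

This note documents the models, numerical conventions, and design choices
behind the package, and what the synthetic-data tests do and do not
demonstrate about field data.

## Exposure model

**Travel time.** Transport between the two gages follows the empirical
power law *T* = *c* · *Q*<sup>−*e*</sup> hours with defaults *c* = 29.35,
*e* = 0.62. The coefficients come from dye-tracer calibration and are valid
only in the flow unit they were fitted in; the configuration therefore
declares a flow unit (`cfs` by default) and `travel_time` rejects inputs
declared in any other unit rather than converting. The law is singular at
zero flow, so non-positive flow is a domain error. *Q* is taken as the
downstream-gage observation nearest the event midpoint; on an exact
distance tie the earlier observation wins (documented, tested).

**Event propagation.** Each weekly flow-composite event at the source gage
is shifted rigidly by the travel time, its water volume at each downstream
site is integrated (trapezoidal) from the gage flow record — drainage-area
scaled at the ungaged site as the mean per-area yield of the two bracketing
gages times the target drainage area — and the downstream event-mean
concentration is source load divided by downstream volume. Mass is
conserved exactly by construction. Whether the interval should be shifted
before or after integrating the downstream volume is not determined by the
study design; both orders are exposed via `ScenarioConfig.shift_before_volume`
with shift-first as the default (the lag describes when the water mass
arrives, so the arrival-window volume is the physically coherent divisor).

**Antecedent windows.** Events contribute to a look-back window if and only
if their midpoint lies in `(visit − w, visit]`; no partial-volume proration
is done for straddling intervals, because the entire chain is keyed to
midpoints. Windows whose event coverage (summed event-interval overlap over
window length) is below a completeness threshold (default 0.5) yield
missing features rather than biased means. Empty windows are flagged
missing, never zero. Left-censored concentrations enter at their reporting
level everywhere (composites, grabs, regressions, correlations).

## Temperature

Ungaged sites carry paired thermocouples averaged upstream of fitting (a
helper averages two records, tolerating single-sensor dropout). The
gap-fill relation is plain OLS of ungaged on gaged over exactly
contemporaneous non-missing pairs (≥ 10 required); a constant gaged series
is a degenerate-fit error. Filled values carry an `estimated` provenance
flag, and antecedent statistics report the estimated fraction per window.
Window statistics use gap-filled data by default. The SD convention is
sample (n−1). Record QA is modeled as a simple despiking filter (physical
bounds −1…35 °C plus a 5 °C maximum step from the last retained value) —
a stand-in for agency processing, clearly flagged as such.

## Biofilm volumes

Per class, *V* = (*F* · 50 m²) · *T̃* with *F* the fraction of all surveyed
points in the class (bare points count in the denominator) and *T̃* the
median thickness in mm; the median of an even count is the mean of the two
central values. With mm × m², the volume unit is liters per standardized
50 m² reach, recorded in output metadata. *F* = 0 gives *V* = 0 exactly.
For log transformation, zeros are replaced by half the minimum non-zero
volume computed **over the whole analysis set** (not per site), since a
single substitution value applies to a given regression; an all-zero set is
an error. The deicer-season contrast (December–May vs June–November) is a
two-group Kruskal–Wallis test with the chi-square approximation, verified
against an exact permutation oracle on small groups in the test suite.

## Regression models

Stepwise OLS alternates a forward step (add the single candidate whose
inclusion most lowers BIC) with a backward sweep (repeatedly remove the
term whose exclusion most lowers BIC) until no single move improves the
criterion. BIC is *n* ln(RSS/*n*) + *k* ln *n* with *k* counting the
intercept; variants differ by additive constants that cannot change the
ordering, but the convention is fixed so reported values are comparable.
Ties break toward the smaller model: adds must strictly lower BIC, drops
are taken when BIC does not rise. The returned model is locally BIC-optimal
in its one-term neighborhood (asserted in tests, which also check agreement
with an exhaustive all-subsets oracle on small candidate sets). Candidate
pairs with |r| ≥ 0.98 are reduced deterministically to the earlier-listed
member, with a warning. The default biofilm-volume candidate suite is the
flow-weighted COD means for all seven windows, 2-week temperature max and
mean, nutrients, specific conductance, pH, and downstream site indicators;
this suite is a reconstruction (the original predictor inventory is not
fully printed) and is entirely configuration-driven. DO is excluded from
the biofilm-volume candidates by construction, because biofilms themselves
depress DO.

## qPCR

The *sthA* primers amplify four products (melt classes 80/86/88/90 °C), of
which only 80 and 90 °C are on-target. The published processing adjusts
copy numbers "for the proportion of on-target amplicons" without printing a
formula; the minimal interpretation — multiply raw copies by the on-target
signal fraction — is used, which is linear in raw copies and bounded by
them. 16S copies receive no analogous correction (its assay is standard).
Spearman correlations use average ranks with the standard tie correction;
p-values from the t-approximation are reported for context only and drive
no screening decision.

## Synthetic study generator

The generator emulates the study conditions: two deicing seasons (December
2009–June 2010, November 2010–June 2011), four sites with drainage areas
2.1–30.6 km² (per-site defaults 2.1/18.3/24.9/30.6, configurable since the
individual areas are not printed), monthly site visits December–June plus a
November pre-deicing visit and twice-monthly visits in May, weekly
flow-composite COD at the source gage with a seasonal lognormal
concentration (geometric means 120 mg/L in deicer months vs 14 mg/L
off-season; reporting level 8 mg/L), and 15-minute temperature with an
annual cycle (mean 10 °C, amplitude 9.5 °C), diurnal cycle, synoptic
wander, and ~8 % sensor gaps at the ungaged sites.

**Noise calibration.** Printed relations come with R² values, not residual
SDs. Every generator calibrates its noise as
sd = sd(signal) · √((1−R²)/R²), where sd(signal) is the realized SD of the
deterministic part over the generated sample — making the population R²
equal the target. A target of 1 forces zero noise; targets outside (0, 1]
are rejected.

**Ground-truth coefficient sets** default to the study's fitted relations:
temperature pairs (1.13, −1.71, R² 0.85) and (1.01, 0.16, R² 0.98);
log₁₀(total deicer) = 1.03 log₁₀(COD) − 0.47 (R² 0.93);
log₁₀(grab COD) = 0.97 log₁₀(composite COD) + 0.04 (R² 0.86);
log₁₀ *V* = 0.79 log₁₀(COD₂wk) + 1.1·DS1 + 0.61·DS2 − 3.9 (R² 0.62);
DO = −2.2 log₁₀ *V* − 0.35·maxT₂wk − 4.4 log₁₀(COD₈wk) + 20 (R² 0.74).

**Survey discretization.** Survey points realizing a true volume share one
thickness recorded to 0.01 mm, chosen with a point count ∝ √V, so the
standard aggregation returns the true volume up to 0.005 mm × count. The
generating model yields sub-liter volumes over realistic exposure ranges,
so a survey detection floor of 0.005 L is applied: thinner or patchier
growth is recorded as absent (*F* = 0), which downstream becomes a zero
subject to the half-minimum substitution — mirroring how minimal growth
enters a field survey. This truncation attenuates coefficients recovered
from the survey-reconstructed volumes (visible in the demo run); the
parameter-recovery experiments therefore draw volumes directly from the
model (`simulate_biofilm_dataset`), which is also how the recovery targets
are defined. The upstream reference site has no composite-event exposure
and is generated at the zero floor, consistent with its role as an
unimpacted control.

**Rank coupling.** The *sthA*:16S ratio is coupled to heterotroph volume
(target Spearman ρ = +0.73) and DO (−0.77) via a Gaussian copula: both
variables are mapped to normal scores of their ranks, a latent normal for
the ratio is a linear combination of the two scores plus independent noise,
with weights solved so its correlation with each score equals the
sine-transformed target r = 2 sin(πρ/6) given the realized volume–DO score
correlation; infeasible coupling pairs are rejected. The ratio is a
lognormal monotone map of the latent, so the rank structure carries
through; the marginal is arbitrary by design.

**Determinism.** Each generator stage draws from an independent stream
derived from the scenario seed via `SeedSequence`, so a fixed configuration
reproduces byte-identical CSVs (tested), and changing one stage's logic
does not perturb another's draws.

## What the synthetic tests show — and do not

Passing recovery tests show the analysis chain is *internally correct*: it
recovers known generating parameters at the configured noise levels, sample
sizes, and couplings. They do not validate the generating models against
real streams: the generator assumes exact affine temperature relations,
lognormal concentration marginals, independent Gaussian residuals,
midpoint-aligned weekly composites, and a clean site hierarchy — real
records have serially correlated residuals, storm-event chemistry dynamics,
rating-curve errors, and survey observer effects, none of which are
emulated. Field thresholds reported for the original system (e.g. minimal
growth below ~48 mg/L antecedent COD) are properties of that dataset, not
outputs of this package.

## Problem sizes and numerical conventions

Recovery experiments use 20 seeds throughout, with 500 site-visits for the
regression recoveries, 2000 15-minute pairs for the temperature slopes, and
250 samples for the rank-coupling check — sizes at which Monte-Carlo error
is a small fraction of each target. Stochastic assertions use tolerances of
2 × the Monte-Carlo standard error of the seed-mean (plus a vanishing
epsilon for degenerate SEs). OLS uses `numpy.linalg.lstsq` /
`scipy.stats.linregress`; perfect fits clamp RSS at 1e−300 inside the BIC
log. The whole default pipeline runs in ~10 s; the acceptance script in a
few seconds.

## Known limitations

- The stepwise search is greedy; it is locally BIC-optimal and matches the
  all-subsets optimum with high probability at these problem sizes, but is
  not guaranteed globally optimal.
- `merge_features` joins per site with a nearest-timestamp tolerance; it is
  O(visits × features) and intended for survey-scale tables, not continuous
  records.
- Censored values substituted at the reporting level bias low-concentration
  statistics high; no maximum-likelihood censoring treatment is attempted,
  matching the published convention.
- The despiking filter is order-dependent (a spike shadowing rule) and is
  not a reconstruction of agency QA.
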