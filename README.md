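# deicer-biofilm

Quantitative analysis of heterotrophic biofilm response to organic deicer
runoff in airport receiving streams — with a synthetic study generator that
carries known, recoverable ground truth.

## The problem

Airfield pavement deicers and aircraft anti-icers are low-molecular-weight
organic compounds (propylene glycol, acetate) that are readily consumed by
heterotrophic bacteria. Streams draining airports therefore grow thick
heterotrophic biofilms — typically dominated by sheathed bacteria of the
*Sphaerotilus*–*Leptothrix* group — and suffer dissolved-oxygen (DO)
depletion. Because biofilm growth integrates exposure over time, the
relevant predictor is not the concurrent concentration but the *antecedent*
exposure: flow-weighted mean chemical oxygen demand (COD, the standard
surrogate for total deicer concentration) over look-back windows of 2–20
weeks before each biofilm observation.

This package implements that full analysis chain for a four-site study
design (one upstream reference site `US1`, three downstream sites
`DS1`–`DS3`, with stream gages near `DS1` and `DS3`):

1. **Exposure estimation** (`hydro`). Composite COD chemistry is measured
   only at the upstream gage. Each weekly flow-composite event is lagged by
   the flow-dependent travel time between the gages,

   *T* = 29.35 · *Q*<sup>−0.62</sup> (hours),

   its water volume at each downstream site is integrated from the gage
   records (drainage-area scaled at the ungaged site,
   *x*<sub>target</sub> = ½(*x*<sub>up</sub>/DA<sub>up</sub> + *x*<sub>down</sub>/DA<sub>down</sub>) · DA<sub>target</sub>),
   and the downstream event-mean concentration follows by mass conservation
   (source load / downstream volume). Antecedent exposure at a site visit is
   then the flow-weighted mean Σ*V<sub>i</sub>C<sub>i</sub>* / Σ*V<sub>i</sub>*
   over events whose midpoints fall in the look-back window.
2. **Temperature** (`temperature`). Ungaged 15-minute records are gap-filled
   from OLS affine relations against the nearby gage and summarized as
   antecedent statistics (mean, max, min, median, SD) over 0.5–20-week
   windows.
3. **Biofilm volumes** (`survey`). Point-transect field surveys (5 transects
   × 10 points) are aggregated per operational class (soft algae,
   transition, heterotrophs, diatoms) to a standardized volume
   *V* = (*F* · 50 m²) · *T̃*, where *F* is the fraction of survey points in
   the class and *T̃* the median thickness (mm); zeros are replaced by half
   the minimum non-zero volume before log transformation.
4. **Regression models** (`models`). Stepwise OLS with forward/backward
   moves minimizing BIC (= *n* ln(RSS/*n*) + *k* ln *n*) selects predictors
   for log₁₀ biofilm volume and for DO from the antecedent exposure,
   temperature, nutrient and site-indicator candidates; left-censored
   values enter at their reporting level.
5. **qPCR relative abundance** (`qpcr`). Raw *sthA* (a *Sphaerotilus*
   sheath-biosynthesis marker gene) copy numbers are corrected by the
   proportion of on-target amplicons (melt classes 80/90 °C), ratioed to
   16S rDNA copies, and screened against environmental measures by
   tie-corrected Spearman rank correlation.

The `synthetic` module generates every pipeline input — hydrographs,
gappy temperature records, composite and grab chemistry with censoring,
survey points, DO, and qPCR records — from configurable ground-truth
coefficient sets, so every stage is testable by parameter recovery without
any field data.

## Worked example

Run the whole pipeline on the default two-season scenario:

```sh
deicer-biofilm all --out runs/demo --seed 1
```

or equivalently from Python:

```python
from deicer_biofilm.config import ScenarioConfig
from deicer_biofilm.pipeline import run_pipeline

run_pipeline(ScenarioConfig(seed=1), "runs/demo")
```

`runs/demo/model_biofilm_volume.txt` then contains:

```
model: biofilm_volume
n = 45
R2 = 0.643
BIC = -78.05
residual SD = 0.372
intercept = -3.351
  log10(cod_fwmc_2wk): 0.6742
  is_DS1: 0.6926
  is_DS2: 0.3241
```

The stepwise search has selected exactly the generating model structure —
the 2-week flow-weighted mean COD plus both site indicators — from sixteen
candidates, with R² 0.64 against the configured population value 0.62; the
coefficients are attenuated relative to the generating values (0.79, 1.1,
0.61) because the survey discretization truncates the smallest volumes, as
the field protocol would. The Spearman screen
(`runs/demo/spearman_screen.csv`) ranks DO (ρ = −0.80) and heterotroph
volume (ρ = +0.61) as the strongest correlates of the *sthA*:16S ratio,
matching the signs and approximate magnitudes of the configured couplings
(−0.77, +0.73).

Each stage is also available as its own subcommand (`generate`, `exposure`,
`temperature`, `survey`, `merge`, `model`, `correlate`) over documented CSV
schemas, with a YAML configuration file for non-default scenarios.

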