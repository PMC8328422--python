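# scalechron

Growth biochronologies from sea trout scale increments: a reusable pipeline
for sclerochronology analyses of wild vs. hatchery-reared anadromous brown
trout (*Salmo trutta* L.).

Annual growth zones on fish scales proxy somatic growth: the distance
between consecutive annuli records how much the fish grew in one calendar
year, in freshwater before smolting (FW zones) and at sea afterwards (SW
zones). Given a table of increment widths from a spawning-run sample, the
package

1. validates, filters and calendar-anchors the records (marginal
   "plus-growth" zones and spawning-eroded zones are removed; rare life
   histories excluded),
2. fits a Bayesian Gaussian mixed model of log increment width with crossed
   random intercepts,

   log w_i = x_i'β + u_fish[f(i)] + u_year[g(i), e(i), t(i)] + ε_i,

   with age class × group fixed effects, a per-fish intercept
   u_fish ~ N(0, σ²_fish), a per group:environment:year intercept
   u_year ~ N(0, σ²_year), and ε ~ N(0, σ²_obs), under penalized-complexity
   priors on the random-effect SDs (half-Cauchy and classical
   gamma-on-precision defaults available for sensitivity checks), with DIC
   (ΔDIC > 2) for term selection,
3. extracts **growth biochronologies** — the posterior of the year random
   effects per group × environment — partitions variance across the three
   components, and compares individual growth plasticity between groups with
   a variance-ratio F test on the fish intercepts,
4. runs **posterior-propagating Monte Carlo correlation tests** between the
   chronologies and yearly temperature series (sea: Jul–Dec mean;
   freshwater: annual mean): each posterior draw of the year-effect series
   is correlated with temperature, so the secondary test carries the
   chronology's uncertainty instead of treating point estimates as data.

A synthetic-cohort generator reproduces the statistical structure of a
2007–2016 southern-Baltic spawning-run sample (1,596 fish, ~3,800 retained
increments spanning growth years 2003–2015, ~90/10 FW1/FW2 smolt ages,
63/35/2 % SW1/SW2/SW3 sea ages, temperature-coupled year effects), so every
stage is testable without any data download.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort and write tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_scale_calibration.py
python analysis/03_fit_growth_model.py --seed 1
python analysis/04_chronology_and_plasticity.py
python analysis/05_climate_correlations.py --seed 1
```

Step 01 prints the filtering arithmetic:

```
simulated 1603 fish / 5615 growth zones
rare life histories excluded: 7 fish -> 1596 retained
marginal zones removed: 1596 (28.6%)
spawning zones removed: 169 (3.0%)
3818 increments retained, growth years 2003-2015
```

Step 03 fits the growth model (the generative truth has intercept 6.70,
Age[SW1] 0.61, Group[Wild] −0.39 on the log-μm scale; σ_obs = 0.155):

```
fitted 3818 increments / 1596 fish / 47 year cells; DIC = -3073.1 (pD = 423.1)
coefficient   mean    sd   q2.5  q97.5
  Intercept  6.691 0.024  6.643  6.739
        SW1  0.614 0.034  0.547  0.681
       Wild -0.381 0.035 -0.447 -0.309
  ...
  component   mean     sd   q2.5  q97.5
observation 0.1531 0.0024 0.1488 0.1579
       fish 0.0553 0.0051 0.0446 0.0638
       year 0.0791 0.0101 0.0619 0.1014
```

so the baseline hatchery FW1 increment is exp(6.69) ≈ 806 μm and a wild
first sea year is exp(6.69 + 0.61 − 0.38 + 0.55) ≈ 1,740 μm. Step 04
partitions variance (year effects ~19 %, fish ~9 % in this realisation) and
runs the plasticity F test; step 05 correlates the chronologies with
temperature, printing the Monte Carlo mean r with its 95 % interval per
stratum next to the realised correlation of the planted year effects.

The same pipeline is available as a CLI (`scalechron simulate / fit /
chronology / climate / calibrate / run`) driven by a YAML config; library
functions live in `scalechron.*` and are what the scripts, CLI and tests
all call.

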