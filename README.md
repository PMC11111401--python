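# paleoresil

Resistance and resilience of past human populations, measured on
radiocarbon summed probability distributions (SPDs).

Archaeological radiocarbon compilations are a standard proxy for
relative population or activity levels through prehistory. `paleoresil`
implements a complete analysis pipeline for asking how populations
responded to disturbances: it calibrates conventional radiocarbon ages
against a calibration curve, pools same-site dates into bins, sums the
bin-averaged densities into a regional SPD, fits a bounded exponential
growth model to the dated events by MCMC, flags *downturns* — runs of
calendar years where the observed SPD falls below the 90%
posterior-predictive envelope of the fitted model — and extracts
per-downturn response metrics that can be compared across regions with
linear mixed-effects models. It is aimed at archaeologists and
palaeodemographers who work with regional `lab_id / site_id / CRA /
error` tables and IntCal-style calibration curves.

## The model and the metrics

Within fixed calendar bounds `a` (older) and `b` (younger, cal BP), the
null demographic model is exponential growth toward the present:

    f(t) = r · exp(r·(a − t)) / (exp(r·(a − b)) − 1),   b ≤ t ≤ a,

with the uniform density as the r → 0 limit. Only the annual growth
rate `r` is estimated (random-walk Metropolis, exponential prior with
mean 4·10⁻⁴ per year); the bounds are fixed per region. The marginal
likelihood of each binned date integrates over calendar age and the
combined lab/curve measurement error. Posterior-predictive replicates —
simulate as many events as the data have bins, back-calibrate, calibrate,
sum — give pointwise 5th/95th percentile envelopes; maximal runs of years
with SPD strictly below the lower bound, longer than 10 years, are the
downturns.

For each downturn with baseline SPD value `b`, minimum `x`, and end
value `e`:

* **resistance** = 1 − 2·|b−x| / (|b| + |b−x|)  ∈ [0, 1] — depth of the
  downturn (1 = no change, 0 = total collapse);
* **resilience** = 2·|b−x| / (|b−x| + |b−e|) − 1  ∈ [−1, 1] — recovery
  by the downturn's end (1 = full recovery, 0 = none, negative =
  overshoot of the baseline);
* **pace** = time-to-minimum / duration  ∈ [0, 1] — relative speed of
  decline;
* **frequency** = cumulative downturn count / elapsed record years ×
  1000 — events per millennium, computed per downturn.

The downturn-level table, joined with expert annotations (disturbance
category and type, dominant land use, evidence of change), feeds
random-intercept mixed models (`response ~ fixed effects + (1|region)`,
REML) with forward stepwise AIC selection of fixed effects.

## Worked example

Fit a growth rate to 500 synthetic dates generated at r = 0.002 between
6000 and 1000 cal BP, then check convergence:

```python
import numpy as np
from paleoresil.calcurves import synth_curve
from paleoresil.calibration import C14Date, bin_dates
from paleoresil.growth_model import MCMCConfig, bin_members, diagnostics, fit_mcmc
from paleoresil.synthetic_data import Scenario, generate_region

curve = synth_curve((8000, 0), sigma=0.0)
scenario = Scenario(region="demo", a=6000, b=1000, r=0.002,
                    n_dates=500, n_sites=500, curve=curve, seed=20240514)
dates_df, _ = generate_region(scenario)
dates = [C14Date(r.lab_id, r.site_id, r.cra, r.error, "demo")
         for r in dates_df.itertuples()]
binned = bin_members(dates, bin_dates(dates))
post = fit_mcmc(binned, (6000, 1000), curve,
                MCMCConfig(n_chains=3, n_iter=5000, burn_in=1000, seed=11))
s = post.summary()
print(f"posterior mean r = {s['mean']:.5f}, "
      f"95% CI ({s['ci95'][0]:.5f}, {s['ci95'][1]:.5f})")
print(f"rhat = {diagnostics(post).rhat:.3f}")
```

Output:

```
posterior mean r = 0.00206, 95% CI (0.00188, 0.00226)
rhat = 1.002
```

The generating rate 0.002 sits inside the 95% credible interval, and
the split R-hat near 1 indicates the three chains mixed. The same
workflow on real data replaces `generate_region` with a dates CSV and a
real curve; the `paleoresil` CLI (`calibrate`, `fit`, `simulate`, `run`)
wraps these stages, and `paleoresil run --config study.yaml` executes a
whole multi-region study (see `docs/methods.md`).

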