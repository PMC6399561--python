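# colocea

**Cost-effectiveness of follow-up colonoscopy from a partially observed
Markov cohort model of colorectal neoplasia.**

Screening colonoscopy prevents colorectal cancer (CRC) by removing
precursor adenomas, and guidelines schedule *follow-up* (surveillance)
colonoscopies by interval and prior findings. But each follow-up exam
prevents less than the screening exam did — the colon was just cleared —
while costing the same. `colocea` is for health-economics and screening
modellers who want to quantify that trade-off: it computes, for a cohort
screened at a given age and stratified by the screening finding, which
follow-up intervals are cost-effective at a willingness-to-pay threshold
and which interval maximizes the quality-adjusted life years (QALYs)
gained.

## The model

The colon state is `x = (N_d, N_m, N_l, stage, symptomatic)` — adenoma
counts by size class (diminutive/medium/large, capped at 3 each) plus CRC
stage and symptom status. The cohort distribution evolves monthly as a
Markov chain

```
P(t + Δt) = K(t) P(t)
```

with published annual per-lesion transition probabilities (appearance is
age-dependent, 0–0.0971/yr), independent lesions, stage progression
local → regional → distant, and stage-specific symptom onset that triggers
immediate diagnosis. Colonoscopy *partially observes* this state: each
lesion is seen with a size-dependent sensitivity (39% diminutive, 95.8%
large), detected adenomas are removed, detected cancer is diagnosed — so
the clinical finding category is a noisy function of the truth, and missed
lesions carry forward.

Survival after diagnosis is piecewise-exponential per stage with a single
breakpoint, `S(t) = exp(-k₁·min(t,b) - k₂·max(0, t-b))`; the
population curve is the stage-prevalence-weighted mixture
`(0.44·S_loc + 0.34·S_reg + 0.18·S_dis + 0.05·S_unk)/1.01`. All-cause
mortality is a sixth-order polynomial fit to a period life table (a
bundled synthetic Gompertz–Makeham table with life expectancy ≈79 years by
default). Costs (colonoscopy + adverse events; phase-based CRC treatment)
and utilities (healthy 0.91; diagnosed CRC 0.74/0.70/0.25; dead 0) accrue
annually, discounted continuously at 3% from the screening age, to age
100. Follow-up schedules are compared with a screening-only control via
the incremental cost-effectiveness ratio ICER = ΔCost/ΔQALY; the
recommended interval is the quadratic-interpolated QALY maximum inside the
cost-effective window. An individual-level microsimulation with identical
rules validates the cohort model's expectations.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Optimal follow-up after screening at age 50, all findings combined, at the
$100,000/QALY threshold:

```bash
colocea optimize --screen-age 50 --threshold 100000
```

prints

```json
{
  "screen_age": 50,
  "finding": "all findings",
  "threshold_usd_per_qaly": 100000.0,
  "cost_effective": true,
  "window_years": [4.838232492892946, 20.0],
  "recommended_interval_years": 8.845098336042575,
  "qalys_gained_per_10k": 99.31968379952387
}
```

Read: every single follow-up between ~4.8 and 20 years after the age-50
screen costs at most $100,000 per QALY gained versus screening only; the
QALY-maximizing interval within that window is ≈8.8 years, which yields
≈99 QALYs per 10,000 screened persons. At $50,000/QALY no follow-up
interval qualifies, and screening at 60 or later admits no cost-effective
follow-up at any of the three standard thresholds.

The same analysis is available from Python:

```python
from colocea import Pipeline, default_config, recommend

pipe = Pipeline(default_config())
outcome = recommend(pipe, screen_age=50.0, threshold=100_000.0)
print(outcome.window, outcome.recommended)
```

Other entry points: `colocea run` (one scenario with its per-year
cost/QALY ledger), `colocea sensitivity` (one-way sensitivity axes:
colonoscopy cost bounds, cancer cost bounds, 0% discounting),
`colocea validate` (cohort model vs microsimulation), and
`colocea write-config` to emit the full default parameter file (YAML/JSON,
with the clinical table row names) for editing.

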