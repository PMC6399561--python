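# Methods

`colocea` estimates the cost-effectiveness of follow-up (surveillance)
colonoscopy after a screening colonoscopy, using a partially observed
Markov cohort model of colorectal neoplasia coupled to survival, cost and
utility models. This note records the model, its assumptions, the numerical
choices, and what the synthetic validation machinery does and does not
establish.

## Natural history

The colon is a joint state `x = (N_d, N_m, N_l, stage, symptomatic)`:
counts of diminutive (<5 mm), medium (6–9 mm) and large (≥10 mm) adenomas,
each capped at 3 per class, an invasive-cancer stage (none, local,
regional, distant), and a symptom flag. The cohort distribution `P(t)`
evolves as a Markov chain, `P(t+Δt) = K P(t)`, starting lesion-free at
birth.

Per-lesion annual transition probabilities (appearance, regression, growth,
malignant transformation; cancer stage progression; stage-specific symptom
onset) are the published point estimates. Annual probabilities `p` are
converted to monthly ones via the constant-rate identity
`1-(1-p_m)^12 = p`, and the model steps monthly; the yearly kernel is
defined as the 12-fold composition of the monthly kernel. Within a step,

* each lesion independently draws one outcome from its class's competing
  set (stay / regress / grow / transform), combined across lesions of a
  class by multinomial convolution;
* the cancer sub-state independently draws stay / progress / become
  symptomatic;
* at most one new diminutive adenoma arrives (the monthly arrival
  probability is <0.01, so multi-arrival mass is <1e-4);
* counts that would exceed the cap are redirected to the cap.

A transforming lesion starts a local cancer if none exists; with an
existing cancer it simply leaves the adenoma pool (one cancer per patient).
All-cause death is applied first within each step as `1-exp(-h·Δt)`; at
monthly resolution the ordering effect is below 1e-5.

**Adenoma appearance by age.** Only the range of the age-dependent
appearance probability (0 to 0.0971/year) is published. The default profile
is a linear ramp: 0 before age 20, rising to 0.0971 at age 70, constant
after. It is a swappable function in the configuration. This is the single
most influential unpinned input: it sets the scale of preventable disease
and hence of the QALY gain of a follow-up (see *Calibration limits*).

**Count cap.** The cap of 3 per size class keeps the state space at 448
states. Raising it to 5 (1,512 states) moves 50-year cumulative cancer
probability by <0.2% relative (tested), so the cap is immaterial for
cohort-level results. It does matter for one conditional quantity — see
*Finding strata*.

## Observation and intervention

Colonoscopy detects each lesion independently with a size-dependent
sensitivity: 0.39 for diminutive and 0.958 for large adenomas (published);
0.70 for medium lesions and 0.958 for an asymptomatic cancer (not
published; defaults chosen between/equal to the printed anchors, both
configurable). Findings are grouped into the eight clinical categories (no
adenomas; 1–2 / 3+ nonadvanced; 1–2 / 3+ with some advanced; local /
regional / distant cancer), computed from *detected* lesions only, with
"advanced" operationalized as any detected large adenoma. Detected adenomas
are removed; a detected cancer moves to the diagnosed compartment at its
true stage; missed lesions persist.

Symptomatic cancer triggers an immediate, perfectly sensitive diagnostic
colonoscopy. Before the screening age the cohort is propagated with
symptom-triggered diagnosis active, and at screening the cohort is
conditioned on being alive, asymptomatic and undiagnosed (mass removed and
renormalized): every screened patient is healthy as far as anyone knows.
Diagnosed patients leave the screening/follow-up schedule.

## Mortality

*After diagnosis*: a two-piece constant hazard per stage ("breakpoint"
model), `S(t) = exp(-k1·min(t,b) - k2·max(0,t-b))`, with published
stage-specific `(k1, b, k2)`. The population curve is the
prevalence-weighted mixture (weights 0.44/0.34/0.18/0.05, normalizer 1.01).
Undiagnosed cancer carries no excess mortality; death competes with
diagnosis only through the symptom process.

*Fitting*: `fit_breakpoint_model` jointly fits all four stages to four
5-year survival points plus an 11-point overall curve by unweighted least
squares. The objective is a sum of piecewise exponentials and has many
shallow local minima, so the optimizer multi-starts deterministically over
the per-stage breakpoint grid {2, 5, 8}⁴ with rates seeded from the 5-year
points (`k = -ln S5 / 5`), screens each start with a cheap bounded
trust-region solve, and polishes the best three tightly (early exit when an
exact interpolant is found). On noise-free data generated from the default
hazards this recovers the generating parameters to machine precision. With
2% Gaussian noise on the survival values the rates remain well determined
but breakpoints of slowly-decaying stages are weakly identified (median
absolute breakpoint error on the order of 1–2 years); the binding guarantee
is optimizer adequacy — the fitted objective never exceeds the objective at
the generating parameters. A `constant_rate=True` variant (k1=k2)
quantifies the lack of fit of a single exponential.

*All-cause*: a banded period life table is summarized by a sixth-order
polynomial in the band midpoints; negative fitted values clamp to zero and
ages beyond the last band (90+) use the polynomial extrapolation, which is
increasing under the default table. The bundled default table is synthetic:
Gompertz–Makeham `h(x) = 4.5e-4 + 2.65e-5·exp(0.0945·x)`, calibrated so
life expectancy is ≈79 years (the published anchor). A user CSV
(`age_lo, age_hi, annual_death_rate`) overrides it. The synthetic table has
no infant-mortality hump and no period shocks; absolute mortality levels
therefore differ from any specific national table, which shifts the
economics slightly (more below).

## Economics

Costs: each colonoscopy costs $1,068.59 plus $92.06 expected adverse-event
cost, times the probability the colonoscopy happens (1 at scheduled exams
for alive undiagnosed patients; the symptomatic-diagnosis mass otherwise).
Cancer treatment follows phases by time since diagnosis: a stage-specific
initial cost in year 1, surveillance costs in years 2–5, nothing after, and
a single terminal cost ($23,002.35) added in the year of a cancer death.
Utilities: healthy 0.91 (including undiagnosed neoplasia), diagnosed cancer
by stage at diagnosis (0.74/0.70/0.25) from diagnosis onward, death 0.

Accounting is annual over the monthly dynamics: monthly state masses are
averaged within each year of age, costs/QALYs accrue per year, and each
year is discounted by `exp(-r·(t-τ))` at its starting age `t`, anchored at
the screening age `τ` (the printed discount formula reduces algebraically
to this continuous multiplier). Accumulation runs from `τ` to age 100.
Pre-screening flows are identical across compared scenarios and are not
accounted.

## Cost-effectiveness analysis

For a screening age (50–75) and optional finding stratum, every single
follow-up interval on the 2–20-year grid (step 2) is compared with the
screening-only control via the ICER `ΔCost/ΔQALY`. At a willingness-to-pay
threshold ($50k/$75k/$100k per QALY):

* the *cost-effective window* is the maximal contiguous run of grid
  intervals with ICER ≤ threshold and ΔQALY > 0, endpoints refined by
  linear interpolation of the ICER curve at the threshold crossing (runs
  touching the grid edge keep the edge);
* the *recommended interval* is the vertex of the parabola through the
  largest in-window ΔQALY grid point and its two grid neighbours
  (ties to the longer interval; boundary maxima and collinear triples
  return the grid point flagged; a vertex outside the window clamps to the
  window endpoint), with the QALY gain read off the same parabola and
  reported per 10,000 persons.

"All findings" uses the unconditional post-screening distribution, which
equals the probability-weighted mixture over the strata. One-way
sensitivity axes re-run the pipeline with the colonoscopy cost or all
cancer costs at their published low/high bounds, or with a 0% discount
rate; at 0% discount multi-colonoscopy schedules are searched greedily,
accepting each next interpolated-optimal follow-up while its marginal ICER
against the current schedule stays at or below the threshold (the greedy
rule is an approximation; the exact search used for the published
multi-exam schedules is not described).

## Validation machinery

`oracle.simulate_patients` is an individual-level Monte-Carlo twin of the
cohort model: same parameter objects, same monthly probabilities, same
within-month order of operations (all-cause death; cancer death and
diagnosis-clock advance; lesion/cancer transitions drawn from the pre-step
state; arrival; symptom-triggered diagnosis) and the same annual economic
accounting. Its expectations therefore coincide with the cohort model's
per step, not just asymptotically, and the test suite checks totals and
finding shares at n = 200,000 within 3 standard errors, plus state
marginals at ages 40–80. The simulation is vectorized across patients with
a single seeded PCG64 stream: runs are bit-reproducible for a given
(seed, n), but changing n reshuffles the stream. Ages before the
appearance ramp are collapsed into one exact survival draw (the only
active process there is all-cause death, whose monthly survival factors
multiply exactly).

What passing these tests shows: the deterministic cohort propagation,
observation layer and economic accounting are mutually consistent and
correctly implemented. What they do not show: fidelity to real screening
populations — the generator emulates the model's own assumptions
(independent lesions, no risk heterogeneity beyond age, no serrated
pathway, no prep-quality or complication effects), so agreement says
nothing about those assumptions.

## Calibration limits

Two inputs of the published analysis are not printed: the adenoma
appearance age profile (only its range) and the all-cause life table. Under
the defaults above, the headline optimum is reproduced within its
documented tolerance (recommended follow-up after screening at 50, $100k
threshold: 8.85 years vs 8.5; QALY gain 99.3 vs 84.0 per 10k, within
±30%), and the ICER-vs-interval curve has the published shape. But its
level sits ~15–20% lower at long intervals, so the $100k window opens at
4.8 years rather than 7.7, the minimum ICER across strata is ≈$68k rather
than ≥$80k, and the $75k window is not empty. Stratified recommendations
also spread more than the published ≤0.5 years: conditioning jointly on
the finding makes the "3+ nonadvanced" stratum nearly lesion-free after
polypectomy under a count cap of 3 (9% residual adenoma mass vs 35% for
"no adenomas"), pushing its window to ~14 years. These conditional results
are confirmed against the microsimulation, i.e. they are properties of
this model under its defaults, not implementation artifacts.

## Degenerate inputs and tie-breaks

* `yearly_to_monthly` rejects probabilities outside [0,1); all parameter
  tables validate ranges, monotonicity and bound ordering on construction.
* An all-unit-survival fit input is flagged (`flat_objective`) and returns
  the boundary solution; a constant-hazard stage fits with k1≈k2 and an
  arbitrary (unidentifiable) breakpoint.
* A finding stratum with zero probability is absent from the
  stratification and scenario runs on it raise.
* Empty cost-effective windows are legal outcomes (`Window.empty`);
  `optimal_interval` requires a non-empty window.
* Conditioning on a cohort with no surviving asymptomatic mass raises.

## Problem sizes used

State space 448 (cap 3); monthly steps to age 100 (1,200 steps); diagnosed
compartments tracked at monthly resolution (3 stages × 1,212 months).
A full scenario runs in ~0.1 s, the 10-interval grid in ~2.5 s, and the
microsimulation at 200,000 patients in ~10 s, so the full test suite
(≈150 tests) completes in about 70 s and the headline-results script in
about 15 s on one CPU.
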