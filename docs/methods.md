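# Methods

`melanosim` is a continuous-time, individual-level microsimulation of
cutaneous melanoma natural history, detection and management, built to
evaluate the benefits, harms and cost-effectiveness of organised,
risk-tailored skin-screening strategies against the opportunistic-detection
status quo. This note documents the model, its assumptions, the synthetic
parameterisation, and the numerical choices.

## Model structure

Individuals enter at exact age 15 in a *well* state with fixed attributes:
sex, birth year, and a lifetime relative-risk group (group membership is
immutable; risk acts purely as a multiplier on the melanoma emergence
hazard, and also raises skin-check uptake). Simulation ends at the first
absorbing event: other-cause death, melanoma-specific death, or the age cap
at 85.

All waiting times are drawn from piecewise-constant hazards over age by
exact inversion of the cumulative hazard at a unit-exponential deviate
(`hazards.PiecewiseHazard`), so there is no cycle-length discretisation.
Competing events are resolved by taking the earliest sampled time; exact
ties follow a fixed priority in which death outranks diagnosis (a
same-instant diagnosis can never post-date death), followed by the age cap,
diagnosis, emergence, and the check channels. After any state-changing
event, hazards that the change invalidated are re-drawn from their own
random channels — exact for the memoryless piecewise-exponential structure.

### Natural history

First-primary emergence is `baseline(age, sex) × cohort(birth_year) ×
relative_risk`. The baseline is a 5-year-age-band table shaped like
Australian registry incidence (rising steeply with age, male excess at older
ages). The birth-cohort multiplier is 1 for cohorts born up to 1972,
declines linearly to 0.6 at 1992, and is constant thereafter — the
sun-protection-campaign plateau; the post-1992 level is held constant
because no endpoint beyond "campaign impact reached" is defined.

A tumour, once emerged (i.e. detectable), has a histology drawn from an
age-indexed mix over four codes (superficial spreading, lentigo maligna,
nodular, other; identical for both sexes, constant in calendar time) and a
body site drawn once from a categorical distribution over ICD-O-3 C44.0–C44.9.
Undiagnosed tumours have **no explicit stage states**: the stage recorded at
diagnosis is a pure function of histology and dwell time (years detectable
but undiagnosed) through per-histology dwell thresholds. The defaults make a
nodular melanoma reach stage IV after 0.5 years of dwell and a lentigo
maligna after 20 years, with superficial spreading (10 y) and other (8 y) in
between. Breslow thickness is categorical (≤1 mm, 1–4 mm, >4 mm), assigned
from dwell cutpoints within stages I–II; dwell 0 is in situ (ICD-O-3
behaviour 2), anything past the first threshold invasive (behaviour 3).

Subsequent primaries occur sequentially: after each diagnosis the next
emergence is clocked from that diagnosis with hazard `first-primary form ×
risk multiplier(number of previous primaries) × histology factor × scale`.
The multipliers (20, 25, 28 for 1, 2, ≥3 previous primaries) are
non-decreasing and >1. The next primary keeps the first primary's histology
with probability 0.6 (concordance), else draws from the marginal mix. There
is no cap on the number of primaries. The global `scale = 0.79` was
calibrated so that, under the packaged defaults, the simulated proportion of
first-primary patients diagnosed with a second primary within 10 years is
≈16% (pooled estimate 15.9%, SE 0.6 pp, over 200,000 simulated lives) — the
nationally reported figure for Australia.

### Detection

Diagnosis factorises into *attendance* (getting in front of a clinician)
and *detection* (the clinician finding the lesion). Four channels exist.
Before the first diagnosis: opportunistic clinician visits, routine skin
checks (an uptake event whose hazard rises with calendar year, followed by
annual checks thinned by exponentially decaying compliance), and organised
screening rounds at fixed calendar times (eligibility by age band and
optionally risk group, attendance by a participation probability). After the
first diagnosis only surveillance remains — population screening refers to
first cancers, so routine checks and organised rounds are gated off for
life; opportunistic visits continue and can find subsequent primaries.

The per-check detection probability is the product of a histology-specific
dwell curve (rising for superficial spreading and lentigo maligna, flat for
nodular, reflecting its early vertical growth), a two-level body-site
visibility factor, and a diagnostic-technology period factor (a linear ramp
over 1980–2010 standing in for the dermoscopy era), times the programme's
test sensitivity for organised rounds; the product is capped at 1. A check
on a melanoma-free attendee yields a cost-bearing false positive with
probability 1 − specificity (programme specificity for organised rounds,
clinical specificity 0.97 elsewhere); false positives change no state and,
absent any quantified evidence, do not alter later behaviour.

Symptom-prompted presentation adds an extra clinician-visit hazard while an
undiagnosed tumour is present. This extra rate follows the tumour's
*current implicit stage* (0 for in situ, up to +1.6/yr at stage IV), not raw
time since emergence: a design choice made because a histology-blind dwell
ramp presents a stage-IV nodular and an in-situ lentigo maligna equally and
therefore produces no length-time bias. With stage-driven presentation,
fast-growing tumours are clinically diagnosed at short dwell while
slow-growing ones linger in the detectable pool, and screening over-samples
them — the classic mechanism, now observable in the simulator (the lentigo
maligna share among screen-detected tumours roughly doubles relative to
opportunistically detected ones under the default programme).

Surveillance after a first diagnosis is 6-monthly for stage III–IV or
high-risk individuals and annual otherwise, to age 85, with per-visit
attendance decaying in time since diagnosis and modified by histology and
stage factors. In situ first diagnoses trigger the same schedule as invasive
ones (guidelines draw no distinction).

### Mortality

Other-cause mortality comes from a life table (synthetic Gompertz–Makeham
shape, male excess ~1.5×, 5-year bands 15–90). Melanoma-specific death
requires prior diagnosis; the hazard of an individual is the **sum over
diagnosed invasive tumours** of stage-specific rates, piecewise-constant in
time-since-diagnosis bands (0–1, 1–5, 5+ years, mimicking relative-survival
curves), with Breslow multipliers (0.6/1.0/1.8) inside stages I–II. Tumour
count itself carries no penalty, and in situ tumours none at all. Histology
affects survival only through stage and thickness. The undiagnosed-to-death
pathway is honoured indirectly: an undiagnosed tumour keeps progressing, so
late diagnosis lands in a high-stage, high-hazard state.

## Reproducibility and common random numbers

Every (individual, channel) pair gets an independent PCG64 substream keyed
by `(root seed, individual id, channel)`. Cohorts are therefore
reproducible bit-for-bit and invariant to execution order, and the
*natural-history* channels (attributes, other-cause death, one exponential
per tumour index for emergence, histology, body site) consume draws in an
order no policy can perturb. Two runs of the same seed under different
policies share other-cause death ages and the emergence age, histology and
site of the first primary exactly; this pairing is what the overdiagnosis
estimator and policy comparisons rely on. Emergence of subsequent primaries
is clocked from the previous diagnosis, which is policy-dependent, so exact
invariance cannot extend past the first primary; the per-index draws are
still shared.

## Calibration

The likelihood of the simulator is intractable, so calibration is ABC-SMC:
priors (uniform, log-uniform, normal, beta) over dotted parameter paths;
a weighted squared *relative* error between simulated and target summaries
(incidence and melanoma mortality per 100,000 person-years by age band and
sex, the 10-year second-primary proportion, the stage distribution at
diagnosis); generation 0 sampled from the prior, later generations
resampling survivors under the previous generation's median-distance
threshold with a Gaussian kernel of twice the weighted variance and standard
importance weights. Posterior intervals are weight-aware. An exhausted
simulation budget raises an explicit error rather than returning a partial
population. Probabilistic sensitivity analysis re-simulates policy and
comparator under common random numbers for each posterior draw and reports
per-draw incremental cost, QALYs, net monetary benefit and the
cost-effectiveness acceptability fraction.

## Economics

Health-system perspective, lifetime horizon, continuous discounting at an
annual 5% base (`x/(1+r)^t`, reference = cohort entry); willingness to pay
50,000 AUD/QALY. Costs attach to events at their exact ages: check costs by
channel plus a keratinocyte/benign-lesion adjunct (45 AUD) at *every* skin
check (these cancers are not simulated explicitly; their expected downstream
cost rides along with each check), false-positive work-ups, excision plus
stage-specific initial treatment at diagnosis, a continuing-treatment
annual stream for five years post-diagnosis (integrated analytically under
discounting), and per-invitee programme costs at each screening round.
QALYs integrate utility weights over state occupancy: well until first
diagnosis, then the worst diagnosed stage's weight, with a terminal weight
in the final six months before melanoma death. Budget impact is
undiscounted, per calendar year over a five-year horizon, scaled from
per-capita cohort costs to a target population; the programme's *fixed*
annual cost is excluded from those rows (it does not scale with population)
and is reported separately in the CLI decision summary.

A screen-detected tumour is counted overdiagnosed when the paired
unscreened history exits — by other-cause death, the age cap, or melanoma
death from a different tumour — without that tumour (matched by index) ever
being diagnosed.

## Synthetic data: what it does and does not emulate

No restricted registry, claims or survey data are used anywhere. The
packaged `australia_like` fixture reproduces the *shape* of Australian
melanoma epidemiology (age/sex gradients, birth-cohort decline, histology
mix, second-primary excess, stage-dependent survival) with round synthetic
numbers; absolute incidence and survival levels are plausible but not fitted
to any registry table, so passing tests demonstrate internal consistency and
mechanism — not agreement with Australian data, except for the explicitly
calibrated 10-year second-primary proportion. Fixture bundles are
self-consistent: their calibration targets are computed by simulating the
bundled parameters, so recovery exercises have a known truth. The
`calibration_demo` scenario (one risk group, flat hazard, near-certain
detection, 40-year horizon) exists for fast identifiability tests and
targets incidence rates only, because near-zero mortality and rare-stage
statistics at demo sample sizes contribute only heavy-tailed relative noise.
`stress_multiprimary` inflates hazards so multi-primary logic is exercised.

## Problem sizes and numerical choices

Statistical checks follow fixed problem sizes chosen to separate signal from
Monte-Carlo noise at 3 standard errors: 10⁵ lives for the epidemiological
anchor, survival ordering and length-time checks; 2×10⁴ for closed-form
exponential comparisons; 10⁵ draws for sampler oracles; 20 repetitions at
reduced budget (population 24, 2 generations, 300 lives per draw) for ABC
coverage. Ages are exact reals internally; summary tables use completed
years and calendar year = floor(birth year + age). Serialisation is YAML
(config) and CSV/JSON (tables, manifests), all versioned; round-trips are
exact to 1e-12 relative on reals. Degenerate inputs are contracts: empty
candidate lists, negative hazards, dwell or times below zero, and
post-diagnosis queries with zero previous primaries raise errors rather
than returning defaults.

## Known limitations

Tumour growth is not modelled biologically (no continuous Breslow process,
no regression); melanoma of unknown primary, keratinocyte cancers (beyond
the cost adjunct), treatment effects, emigration/censoring before 85, and
capacity constraints are out of scope. Risk stratification uses three
placeholder groups; a real risk-tailored programme would plug in an external
risk-prediction tool's strata. The overdiagnosis definition is one of
several defensible counterfactual definitions. Calendar effects enter only
through uptake and the period detection ramp.
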