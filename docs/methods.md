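# Methods

## Model overview

`crcscreen` implements an annual-cycle Markov cohort (state-transition)
model of colorectal neoplasia and superimposes population screening
programmes on it. A closed cohort enters at age 30 with no adenomas or
preclinical cancer and is followed to age 100, by which point almost all
members are absorbed into a death state. The model has three interlinked
components:

1. **Natural history.** Normal epithelium → low-risk adenoma (<10 mm) →
   intermediate/high-risk adenoma (≥10 mm) → preclinical cancer (AJCC
   stage I→II→III→IV) → clinically diagnosed cancer → death. A fraction
   `p_direct` (base case 14%) of cancers arises directly from normal
   epithelium without a prior adenoma (flat/serrated lesions, IBD-related
   cancers), modelled as a normal → preclinical-stage-I flow. New adenomas
   and direct cancers split 70:30 between distal and proximal colon so that
   a distal-reach test (flexible sigmoidoscopy) can be represented.
   Preclinical cancers progress between stages and present clinically with
   stage-specific annual probabilities; diagnosed cancers face
   stage-specific annual cancer-death probabilities, non-decreasing in
   stage, applied for the rest of life (no cure point).
2. **Screening and surveillance.** Strategies redistribute cohort occupancy
   at screening time points in expectation; there is no Monte Carlo at the
   cohort level. The diagnostic cascade is: positive screening test (after
   reflex testing where configured) → colonoscopy referral at the stated
   compliance, with a configurable fraction routed to CT colonography →
   lesion-class-specific colonoscopy sensitivity → polypectomy
   (adenomas) or stage-specific clinical management (cancers). People with
   intermediate/high-risk adenomas removed enter colonoscopic surveillance;
   low-risk adenomas return to routine screening.
3. **Mortality.** Death from colorectal cancer, from endoscopic
   perforation (applied per procedure, including screening FSIG), or from
   other causes via an age-dependent life-table probability applied
   competitively to every live state.

### Cycle order and competing risks

Within each annual cycle the order is: (1) surveillance exams and any
scheduled screening round, (2) natural-history progression, (3) other-cause
death. Other-cause death is folded into the transition matrix by scaling
all live destinations of live states by `1 − q_other(age)`; transitions
already bound for a death state (cancer death) are not scaled. Rows
therefore sum to one exactly (checked to 1e-12), and at age 100
(`q_other = 1`) all live states exit to a death state. No half-cycle
correction is applied by default; `simulate_strategy(half_cycle=True)`
averages start- and end-of-cycle occupancy for the QALY stream.

### State space

The canonical enumeration has 22 states (1 normal, 2×2 adenoma risk ×
location, 4×2 preclinical stage × location, 4 clinical stages, 2 lumped
surveillance compartments, 3 absorbing death states). The simulator works
on two extended spaces: a 28-state natural-history space that additionally
splits preclinical states by provenance (via-adenoma vs direct), so the
share of cancers arising without an adenoma can be tracked exactly, and a
196-cell overlay space for screening runs. The overlay space holds a
routine attender pool and a never-attender block (21 pre-diagnosis lesion
states each), seven surveillance tunnel cells × 21 lesion states, 4
clinical states, and 3 death states.

### Direct-pathway constraint

`p_direct` is enforced as a flow ratio at parameterisation time, not by
per-cycle renormalisation: a preliminary run with the direct pathway off
records the via-adenoma flow into preclinical stage I and the normal-state
occupancy at each age, and the age-specific direct rate is set to
`p_direct/(1−p_direct) × via_flow(age)/normal(age)`. Because adding the
direct flow perturbs the occupancies slightly, the realised lifetime direct
share is approximate (observed ≈ 13.9% against the 14% base case, within
the ±0.01 tolerance the enumeration tests assert).

### Surveillance tunnel encoding

Surveillance follows the guideline rule: annual colonoscopy for high-risk
findings, 3-yearly for intermediate-risk, exit after two clear exams
3 years apart. Encoding: one high-risk cell (examined every cycle) and six
intermediate cells — clears banked (0 or 1) × years-since-exam (0/1/2).
A clear exam in the high tier banks one clear and moves the member to the
intermediate tier; a second clear exam three years later returns the member
to the routine pool (with any lesion the exam missed carried along).
Detected adenomas are removed and re-enter surveillance with the clear
count reset (29% of intermediate/high-risk findings to the high tier);
detected cancers become surveillance-detected clinical cases. Non-compliant
members (per-exam compliance 86%) have the exam deferred by one full
interval. Between exams, lesions inside surveillance progress under the
same natural-history rates as everyone else, so interval (symptomatic)
cancers can arise.

### Attendance model

The population is partitioned once into never-attenders (13%) and potential
attenders, who attend each offered round independently with probability
`uptake / 0.87` (0.53/0.87 ≈ 0.609 for the faecal programmes), so the
overall per-round uptake matches 53% while "ever screened" never exceeds
87%. Once-only sigmoidoscopy applies its 39% uptake directly. For
gFOBT-based screening everyone positive on the guaiac test completes a
reflex FIT with independent performance; referral requires both positive.
Kit dispatch costs accrue per invitee, processing costs per participant;
the reflex FIT carries processing cost only.

### Economics

QALYs weight each year lived by 0.94 (cancer-free, including undiagnosed
preclinical cancer and surveillance) or 0.80 (diagnosed cancer, all
stages). Lifetime stage-specific cancer-management costs are charged once
at the diagnosis cycle, using screen-detected prices for screening- and
surveillance-detected cases and symptomatic prices otherwise; per-event
costs cover kits, processing, procedures, pathology (65 € × 1.9 adenomas
per polypectomy episode), perforation treatment and bleeding admissions.
All flows are in 2008 euro, discounted at 4%/year from age 55; flows before
the reference age are carried undiscounted, which cancels in incremental
comparisons because screening starts at or after 55. The efficiency
frontier removes strictly dominated strategies and then iteratively removes
extended-dominated ones; the survivors form the lower convex hull of the
(QALY, cost) cloud, which the tests verify against an exhaustive
net-monetary-benefit support oracle.

### Calibration

The 18 natural-history probabilities (5 age-band adenoma-onset rates plus
progression, presentation and fatality parameters) are estimated by
random-walk Metropolis–Hastings against targets for stage-specific
incidence, cancer mortality (annual rates per 100,000 alive in 5-year bands
50–84) and adenoma / preclinical-cancer prevalence (ages 55/60/65), under
an independent normal likelihood and flat Beta(1,1) priors. The proposal is
a per-coordinate Gaussian random walk in probability space; proposals
outside [0,1] or violating structural constraints (fatality monotone in
stage, stage exits ≤ 1) have zero prior mass and are rejected. Scales adapt
toward 20–40% acceptance during burn-in. Three chains run by default; the
highest-likelihood sampled vector (MAP set) drives base-case analyses and
the pooled post-burn-in samples feed the PSA as whole vectors, preserving
between-parameter correlation. Single chains are sticky (lag-50
autocorrelation near 1), so interval estimates should always pool chains.

### Uncertainty analysis

Each uncertain parameter carries a beta, uniform or scaled-beta PSA
distribution; parameters judged inter-dependent (each test's sensitivities
for adenomas and cancer) form perfectly correlated groups sharing one
uniform quantile per draw. Each PSA iteration draws one joint parameter
set — including one natural-history vector from the calibration
posterior — and re-simulates every strategy on it (common random
parameters). Outputs: incremental cost/QALY clouds, bivariate-normal 95%
confidence ellipses from the sample moments, and cost-effectiveness
acceptability curves over a willingness-to-pay grid of €0–50,000 in €500
steps. One-way sensitivity analyses vary one parameter to each end of its
stated range, everything else at base case; the tornado table orders
parameters by ICER range width.

The distribution printed for FIT cancer sensitivity, Beta(35.29, 143.08),
has mean ≈ 0.198, inconsistent with its 71% base case and 67–75% range. By
default the package re-parameterises this row by moment matching (mean
0.71, the range read as a 95% interval); `default_parameter_registry(
reparameterise_fit_crc_beta=False)` restores the verbatim shape.

## Synthetic data

No deposited registry or life-table data accompany this analysis, so the
`synthetic` module generates every input. The life table is Gompertz,
`q(age) = 1 − exp(−a·e^{b·age})` with defaults a = 3×10⁻⁵, b = 0.095
(adult annual mortality ≈ 5×10⁻⁴ at 30, ≈ 2.3% at 70, ≈ 10% at 85),
absorbing at 100. Calibration targets are produced by running the model
forward under a reference ("true") parameter set and adding
N(0, (CV·value)²) noise with the sd column set to CV·value (default CV 5%).

The reference parameter set is synthetic and labelled as such. It was fixed
once, before any screening analyses, by least-squares fitting to the
intended no-screening epidemiology: lifetime clinical incidence in
5,000–5,500 and cancer mortality in 2,200–2,400 per 100,000 cohort members,
stage distribution at diagnosis near 12/25/35/29%, adenoma prevalence
rising through roughly 15–22% over ages 55–65, preclinical-cancer
prevalence ≈ 0.4%, and clinically plausible shape constraints (symptomatic
presentation rates increasing in stage, monotone fatality). It reproduces
that epidemiology well, but it is *not* a published calibrated transition
set: in particular its preclinical sojourn is short (≈ 1.5 years in stage
I) and its adenoma dwell times long, so screening in this synthetic world
works more through adenoma removal (FIT lifetime incidence reduction ≈ 26%)
than through stage shift, and the faecal strategies come out cost-saving
rather than at small positive ICERs. Passing tests therefore demonstrate
the correctness and internal consistency of the machinery, not
transferability of ICER levels to any real population.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script scale the stochastic components to
what a desk run needs: parameter-recovery uses 20 replicate target sets,
each calibrated with 3 chains × (1,000 burn-in + 1,667 retained) iterations
over a 6-parameter free subset (the remaining parameters held at their true
values); the conjugate-posterior cross-check uses 20,000 MH draws; the
acceptance script calibrates with 3 × 1,200 iterations and runs a 150-
iteration PSA over the four core strategies. The full-size settings
(burn-in 2,000; 1,200 PSA iterations) remain the library defaults.

## Known limitations

- Cohort-level expectation only; no individual-level microsimulation, so
  no variance in event counts and no history-dependent test behaviour
  beyond the never-attender split and surveillance tunnels.
- The index-lesion representation carries one lesion per person; missed
  synchronous lesions and their pathology costs are not modelled beyond
  the mean 1.9 adenomas per polypectomy episode.
- Colonoscopy imperfect specificity has no behavioural consequence for
  truly normal referrals (a false-positive colonoscopy is costed as a
  clear exam; no pathology is charged when no adenoma exists).
- CT colonography acts as a pre-filter: positives proceed to colonoscopy,
  negatives return to routine screening; CTC-specific complications are
  not modelled.
- Quality-of-life decrements of screening episodes, programme set-up and
  administration costs, and participant/societal costs are out of scope.
- Surveillance-detected cancers are costed at screen-detected prices.
- FSIG polypectomies for low-risk distal adenomas happen within the
  screening visit (no extra procedure fee); their pathology is charged.
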