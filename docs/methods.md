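# Methods

## Model structure

The simulator represents one individual's COPD natural history as a strictly
feed-forward cascade of four stages. Nothing feeds back: exposure drives
activity, activity drives the rate of lung-function loss, and the resulting
deficit drives perceived impact. This is a deliberate idealization — real
disease includes adaptation, rehabilitation and treatment effects that the
cascade cannot express (see Limitations).

**Exposure.** Daily smoking dose is a closed-form product of two logistics
in time: a rising one for initiation and, for quitters, a mirrored falling
one for cessation. Each logistic is parameterized by its 5%→95% span: "time
to maximal exposure" of 5 years means the dose passes 5% of maximum at the
onset age and 95% five years later, centred mid-window. Cumulative dose
(pack-years) is accumulated by a left-endpoint Euler sum, 1 pack/day for one
year ≡ 1 pack-year. Never-smokers have exposure identically zero.

**Activity.** Inflammatory activity relaxes toward a steady-state target
with time constant τ_A (default 1 year):

    dA/dt = (A*(E) − A) / τ_A,
    A*(E) = max( g(E − E_trig; k_A),  π · A_peak ),

where `g(d; k) = 1 − exp(−k·d)` for d > 0 and 0 otherwise — a *gated*
saturating dose-response that is exactly zero at and below the trigger, so a
never-smoker mounts no inflammatory response at all. `π` is the persistence
fraction and `A_peak` the running maximum of A: after cessation, activity
decays not to zero but to π·A_peak (hysteresis). A is clamped to [0, 1]
after each step, being a fraction of maximal response by construction.

**Severity.** FEV1 obeys a first-order linear decline law,

    dFEV1/dt = −ρ(A) · FEV1,    ρ(A) = r(A) / FEV1(20),
    r(A) = r_normal + (r_max − r_normal) · g(A − A_trig; k_S),

so the tabulated ml/yr rates are *initial-slope* rates at the individual's
age-20 volume and sustained activity produces an exponential volume decay.
The constant-rate (linear-in-time) reading was rejected because it drives
the continuous-smoker scenario's FEV1 negative before age 80, whereas the
exponential reading lands on both published anchors (45% of reference at 80;
~50 ml/yr cohort mean decline). The activity→rate coupling is gated for the
same reason the exposure→activity one is: a fully quiescent lung (A = 0)
must decline at exactly the normal rate, otherwise a never-smoker would
drift off the reference trajectory.

No decline of any kind occurs before the plateau end age (default 25,
configurable), the conventional end of the lung-function plateau; FEV1
before age 20 is held at the age-20 value (the growth phase is not
modelled — an early-life deficit is imposed as the age-20 initial
condition).

**Reference trajectory and "% ref".** The reference lung holds 4.0 L to the
plateau end and then follows the same first-order law with A ≡ 0 at
30 ml/yr initial slope, in closed form. "% ref" is the individual's FEV1 as
a percentage of this *age-matched* reference — not of the individual's own
age-20 value — which is what makes a 45%-at-80 endpoint consistent with a
~50 ml/yr mean decline and with clinical convention.

**Impact.** Perceived symptom burden relaxes (τ_I, default 1 year) toward a
*decreasing, ungated* logistic of % ref with midpoint at the impact trigger
(default 80% ref, fractional scale). Triggers above 1.0 are legal
(hyper-perceivers). The ungated form implies a nonzero resting impact even
at 100% ref (≈0.40 at the default trigger/slope); this "perception floor" is
the price of reproducing the 68%-of-maximal-impact endpoint with a single
logistic, and it also means a young healthy individual's impact drifts up to
its resting level early in the simulation rather than staying at zero.

## Choice of activation forms

The gated form `1 − exp(−k·d)` was selected over two alternatives — a
logistic rescaled to vanish at the trigger, and a tanh — by requiring the
default parameter tables to reproduce three quantitative anchors
simultaneously: the continuous smoker's 45%-of-reference FEV1 at 80, his 68%
of maximal impact at 80, and a ~50 ml/yr cohort mean decline. The rescaled
logistic overshoots the FEV1 endpoint (≈55% ref at 80); the tanh undershoots
it (≈40%). The selected form gives 46.1% ref, 66.0% impact and ≈50 ml/yr
with the unmodified published parameter values. The impact stage keeps the
plain logistic, whose closed form 1/(1+e^(−0.7)) = 0.668 matches its anchor
directly.

## Integration

All stages advance together with an explicit Euler step, Δt = 0.2 years
(configurable), over ages 10–90. Each step is feed-forward *within* the
step: the activity update reads the current exposure, the FEV1 update the
current activity, the impact update the current % ref. Halving Δt moves the
scenario FEV1 at 80 by under 2 ml in all six scenarios. At Δt = 0.2 and
τ = 1 yr the discrete relaxation (1 − Δt/τ)ⁿ deviates from the continuous
exponential by up to ~4% of the initial gap mid-transient; both agree with
each other and with the steady-state target to better than 1% once five
relaxation times have elapsed, which is the regime the tests check.

A single trajectory and a population ensemble share one vectorized kernel
(`simulate` is the batch-of-one case), so an ensemble of one with zero
dispersion reproduces the single-run trajectory to machine precision.

## Population layer

A cohort is described by per-parameter truncated-normal distributions
(center, CV, truncation bounds). Defaults: centers at the
continuous-smoker values, CV 0.15, truncation at ±3 SD intersected with hard
validity bounds; the quitting block is not varied (the default cohort is a
persistent-smoker population), and non-smoker cohorts zero the exposure
block. The published distributions are shown only graphically in the
source material, so these defaults are configuration, not constants. Each
draw's generator derives from (seed, draw index), making draws independent
of cohort size and ensembles bitwise reproducible.

Cohort statistics use population (ddof = 0) standard deviations so a
degenerate cohort reports exactly zero spread. The per-individual "mean
adult decline" is the chord slope of FEV1 between the plateau end and age
80. The lower limit of normality is a configurable fraction of the internal
reference trajectory (default 0.80) — a synthetic stand-in for published
spirometric reference equations, which are deliberately out of scope.

**Calibration** is a seeded, derivative-free random search over the
per-parameter CVs (optionally also centers): log-normal multiplicative
proposals with a step size annealed from 0.5 to 0.1 over the budget, each
candidate scored on a reduced ensemble with a fixed evaluation seed so the
loss surface is deterministic. The loss is the summed squared error of the
cohort mean (and SD, when given) FEV1 at the target ages plus a weighted
squared error on the mean decline. If no candidate improves on the input
spec, the input spec is returned with a diagnostic. Correctness is checked
by parameter recovery: targets generated from a known cohort are matched
within Monte Carlo error when the search starts from a mis-dispersed cohort.

## Problem sizes

Default runs integrate 401 steps per individual. The shipped test suite
uses cohorts of 20–150 models and calibration budgets of 20–25 evaluations
at 100–120 models each; the headline ensemble quantity is computed on the
full 1,000-model cohort, which the vectorized kernel simulates in well under
a second.

## Known limitations

- No exacerbations, comorbidities, treatment effects, feedback loops or
  genetic effect-modifiers; the cascade is deterministic given parameters.
- The exposure stage models cigarette smoking only.
- The reference trajectory and LLN are internal constructs, not published
  reference equations; absolute liters should not be compared against real
  spirometry.
- The synthetic cohorts emulate dispersion by independent truncated normals;
  real populations have correlated parameters (e.g. dose and onset age), so
  passing cohort-level tests demonstrates internal consistency, not fidelity
  to any real cohort.
- Impact has a nonzero resting level at full lung function (see above);
  treat impact as a relative, not absolute, scale.
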