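# Methods

`boldnvc` tests mechanistic hypotheses of the neurovascular coupling — the
chain linking neuronal activity to cerebral blood flow and blood oxygenation —
against event-related BOLD fMRI time courses. This note records the models,
the numerical and statistical choices, and what the synthetic data do and do
not establish.

## The modeling problem

A brief visual stimulus (a 0.5 s flash) elicits a BOLD response lasting
roughly 15–18 s with up to three characteristic features: a shallow *initial
dip* in the first couple of seconds, a large *peak* near 6 s, and a
*post-peak undershoot* before the return to baseline. Competing hypotheses
attribute these features to different mechanisms:

- **metabolic feedback** — activity consumes glucose and oxygen; the glucose
  deficit feeds back onto cerebral blood flow, which restores supply;
- **neurotransmitter feed-forward** — glutamate signaling in neurons and
  astrocytes releases vasoactive agents (NO→cGMP, and the arachidonic-acid
  metabolites EET, prostaglandins, 20-HETE) that dilate or constrict vessels
  in anticipation of demand, with no metabolic component;
- **feed-forward + metabolism** — the feed-forward flow control combined with
  oxygen/glucose metabolism; metabolism is driven directly by the input and
  there is no metabolic feedback on the flow.

Each hypothesis is written as a small ODE system (a *model structure*); a
structure plus a parameter vector is a *model*. Structures are fit to a
group-mean single-trial BOLD time course by weighted least squares, tested
statistically, screened for qualitative features and biological plausibility,
minimized, and finally asked to predict held-out stimulation conditions.

## Model structures

All structures follow interaction-graph conventions: non-regulated rates are
mass action, and each state equation is the signed sum of its in- and
out-going reactions. The blood flow `v` is a *variable*, not a state; it
transports the four vascular species (glucose G, free oxygen O2,
oxyhemoglobin oHb, deoxyhemoglobin dHb) in and out of the studied volume.
Basal concentrations are normalized to 1 au; signaling species are deviations
from basal (basal value 0). Inflow concentrations are derived from the rate
constants so that the basal state is an exact steady state — this removes a
family of non-identifiable scale parameters and makes `f(x0, p, 0) = 0` hold
by construction rather than by numerical root finding.

The hemoglobin pool obeys `d(oHb+dHb)/dt = v((oHb+dHb)_basal − (oHb+dHb))`,
so total hemoglobin relaxes exponentially to its basal total — a useful
numerical invariant. Consumption terms are first order in the consumed
species (`(k_bas + k_stim·m)·G`, and analogously for O2 with the
stoichiometries `n_b`, `n_s`), which keeps every concentration non-negative
along trajectories. The two stoichiometries encode how aerobic basal
(`n_b`) versus stimulated (`n_s`) metabolism is; their ratio decides whether
the simulated response shows a dip, a peak, or both (see below).

Delay chains are first-order cascades of length 3 (`dS1/dt = k(src − S1)`,
`dSi/dt = k(S_{i−1} − S_i)`), the standard linear representation of
unmodelled lag such as smooth-muscle action. The minimized feed-forward
structure `Mn2` gives each arm per-stage rates rather than one shared rate;
this is the smallest structure that can make a constricting arm rise early,
saturate low and decay slowly while the dilating arm rises later, higher and
decays faster — the balance required for dip + peak + undershoot from flow
alone.

The flow is floored at `1e-6·v0`; it can never reverse. Measurement maps:
the pure feed-forward family reports `y = y_scale·(v − v0)` (no metabolism,
so flow is a direct output proxy); all families with hemoglobin report
`y = y_scale·(oHb/dHb − ratio_basal)`. Because ratio deviations are a few
percent while the data peak is ~23.5 au, `y_scale` gets a wider bound
([1e-3, 1e5]) than the default [1e-3, 1e3] used for every other parameter.

### Reference parameter sets

`REFERENCE_PARAMS` documents hand-chosen sets realizing each qualitative
regime; they were found by forward simulation (no fitting to any data):

- `Mm2_aerobic` / `Mm2_anaerobic` / `Mm2_mixed` — identical except for
  `n_s`: fully aerobic stimulation (n_s = n_b) produces an initial dip and no
  peak; fully anaerobic (n_s = 0) a peak and no dip; partly anaerobic both.
- `Mm3_depleting` — glucose collapses below 5 % of basal within a second:
  the behavior that renders the delayed-feedback variant implausible.
- `Mn2_canonical` — dip + peak + undershoot from the constriction/dilation
  balance; the dip is vasoconstrictive (flow falls >2 % below basal early).
- `Mnm2_reference` — all three features with a *metabolic* dip: oxygen falls
  ~1 s after the stimulus while the flow stays within 2 % of basal, glucose
  dips ~16 % and recovers, and the late undershoot comes from the
  slowly-decaying constrictor arm.

## Simulation

LSODA (via `scipy.integrate.odeint`) with the boxcar pulse edges passed as
critical points so 0.5 s stimuli are never stepped over. Default tolerances
rtol 1e-8 / atol 1e-10; fitting uses rtol 1e-6 / atol 1e-8 with the step
budget capped (mxstep 2000) so pathological parameter proposals fail fast.
Convergence was checked by tolerance tightening (halving tolerances changes
the sampled output by < 1e-4 au on reference runs). Output is sampled on the
acquisition grid, TR = 0.5 s over −1 … 17.5 s (38 samples; 36 post-onset).

## Feature detection and dip attribution

The dip is the most negative excursion before the peak below a threshold;
the undershoot the most negative excursion after the peak; doublets are
counted as local maxima above the peak threshold separated by ≥ 1 s.
Defaults: dip threshold 2 % and peak threshold 10 % of the estimation data's
peak amplitude — the initial dip is reported to be only 1–2 % of the baseline
signal, so a detector threshold well below the peak scale but above solver
noise is needed; both are configurable.

A dip is attributed to *vasoconstriction* if the flow falls more than 2 %
below basal before the dip minimum, and to *oxygen metabolism* if free oxygen
drops more than 1 % below basal while the flow stays within 2 % of basal
during the oxygen fall. The "while" is evaluated up to the oxygen minimum,
not the (later) ratio minimum: the flow legitimately begins rising between
the two, and the mechanistic question is what initiates the dip.

## Fitting

The cost is the chi-square sum of SE-normalized residuals over the 36-point
estimation window. Optional penalties enforce qualitative requirements: each
missing feature adds `w·(shortfall/threshold)²` (w = 100 by default), a term
that decays continuously to zero as the feature emerges, so the penalty does
not create cliffs in the search landscape. Failed integrations yield a large
sentinel cost (1e12) instead of raising, so rugged regions do not abort a
search.

The optimizer is a seeded, bounded, derivative-free global search over log10
parameters: 5 restart legs of Metropolis annealing (temperature decays ×0.98
every 50 evaluations) preceded by a short random screening phase, followed by
derivative-free simplex polish of the best leg incumbents within the
remaining budget. Two optimizer details matter:

- half the screening starts are drawn log-normally around 1/s rather than
  log-uniformly over all six decades, because biological rate constants
  cluster near unit timescales for a ~15 s response;
- the linear measurement scale `y_scale` is profiled out at every evaluation
  (a separable least-squares step — the output is linear in it, so its
  conditional optimum is closed-form). One ODE solve still backs every
  evaluation.

Every evaluated parameter vector whose cost passes the chi-square cutoff is
archived (cap 5000, thinned by cost-stratified subsampling); the archive is
the raw material for prediction envelopes. Runs are deterministic given the
seed.

## Statistical evaluation

The chi-square test compares the optimized cost with the (1 − α) quantile at
df = N − 1 (49.8 for N = 36, α = 0.05). Minimized structures are compared
with the full structure by a likelihood-ratio test: the cost increase of the
reduced model (costs are already chi-square scaled) against the chi-square
quantile at df equal to the number of removed parameters (33.9 at df = 22).
A verdict combines three criteria: statistical acceptance, presence of all
three response features, and biological plausibility (no glucose depletion
below 5 % of basal, no glucose minimum coinciding with the BOLD peak within
0.5 s, and a dip caused by metabolism rather than vasoconstriction).

## Core predictions

Predictions are computed for *every* archived acceptable parameter set, not
just the optimum; the pointwise min/max across the archive forms an
uncertainty envelope around the best trace. This is a representative
selection of acceptable parameters, not a formal confidence band — no
coverage statement is implied. Validation reports the fraction of held-out
data points whose ±1 SE interval intersects the envelope (pass threshold
80 %, configurable) plus peak-count agreement.

## Synthetic data

The generator emulates the study conditions: 12 subjects, TR = 0.5 s,
window −1 … 17.5 s, ground truth either a fitted model or a canonical
double-gamma response scaled to the measured group peaks (23.5 au intensity,
19.8 au frequency), and i.i.d. Gaussian per-subject noise with SD 8 au so the
group SE is ~10 % of the peak. Each subject trace is baseline-normalized
(its last pre-stimulus sample subtracted) *before* averaging, exactly as the
acquired responses were processed; this matters statistically, because the
inter-subject SE then includes the baseline-subtraction noise and the
chi-square calibration of the cost is preserved. A SE floor of 1e-6 au keeps
noise-free fixtures usable.

What the synthetic data do not emulate: temporal autocorrelation of fMRI
noise, physiological (cardiac/respiratory) components, drift, motion, or
trial-to-trial adaptation. Passing recovery tests therefore demonstrate
correctness of the pipeline under the stated Gaussian model, not performance
on real scanner noise.

## Problem sizes

Default budgets were chosen as the smallest that make the stochastic studies
reproducible across seeds: 20 000 evaluations for the metabolic-model fit,
8 000 per run for the 20-run recovery study, 1 500 for warm-started
prediction fits. All are configurable; the acceptance script and test suite
use these defaults.

## Known limitations

- The structures omit blood volume entirely, so the output is the oHb/dHb
  ratio rather than a volume-weighted BOLD signal equation; predictions of
  undershoot depth are correspondingly coarse.
- Delay chains are linear; receptor kinetics and smooth-muscle mechanics are
  not represented beyond lag.
- The likelihood-ratio comparison assumes nested structures and chi-square
  calibrated costs; it is not an information criterion and should not be
  used across non-nested families.
- Archive envelopes under-cover where the optimizer never visited; they
  widen monotonically with archive size but carry no probability statement.
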