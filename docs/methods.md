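# Methods

## The inference problem

A two-option foraging puzzle (slide a door left or right for a food
reward) spreads through breeding populations of great tits monitored with
RFID.  Juveniles fledge into a social environment containing knowledgeable
adults and, increasingly, knowledgeable siblings and peers.  The package
reconstructs *how* the behaviour spreads: through which social pathway
each juvenile most plausibly learned (from parents, from non-parental
adults, from siblings, from unrelated peers, or asocially), and which
decision rule governs the left/right choice once a bird solves.

## Event model

Streams are delimited tables of RFID registrations.  Derived quantities:

* **Scrounges** — a visit by a different bird at the same site within
  (0, 2] s of a solve, while the sliding door is still open.  A scrounge
  attaches to the most recent qualifying solve.
* **Knowledge states** — a bird is *knowledgeable* once it has produced at
  least 10 solves over the study (a conservative threshold because the
  perch antenna occasionally misattributes solver identity when several
  birds perch at once), while its *acquisition time* is the time of its
  3rd solve.  Adults acquiring before the diffusion start are
  *demonstrators*; adults acquiring during it are *filtered* — excluded as
  learners but retained as transmitters.  Windows are half-open intervals
  (start, end] so boundary events are never double-counted, and solves
  with identical (bird, time, site) are de-duplicated as RFID double-reads.

## Association networks

Feeder detections are clustered per site and day into gathering events by
1-D Gaussian mixtures over timestamps, with the number of components
chosen by BIC (K = 1..10, three restarts, fixed seed).  Component
variances are floored at (30 s)² — without the floor, BIC favours
near-singular components that split sub-minute visit bursts into
singletons; with it, bursts on the scale of a feeding visit stay together
while bouts separated by tens of minutes split.  Under the gambit of the
group, dyadic association is the simple-ratio index
SRI = n_joint / (n_joint + n_a + n_b) ∈ [0, 1].

Each dyad belongs to at most one pathway layer determined by the
pedigree: juvenile × own parent → *vertical*; juvenile × other adult →
*oblique*; same-brood juveniles → *sibling*; different-brood juveniles →
*peer*; adult dyads carry no layer.  Networks are recomputed in a ±7-day
window around each acquisition event (associations change rapidly as
broods reach independence), birds with fewer than 10 feeder registrations
over the whole study are excluded as transients, and a presence matrix
(any registration at the event's site within the preceding 7 days) gates
who can learn or transmit at each event.

## The multinetwork TADA model

Acquisition times are survival data.  A naive, present individual i has
hazard

    λ_i(t) = λ0(t) · [ exp(β_A·x_i(t)) + Σ_k s_k exp(β_S·x_i(t)) · T_i^{(k)}(t) ],
    T_i^{(k)}(t) = Σ_j a_ij^{(k)} w_j(t) z_j(t) π_j(t),

with baseline λ0(t) = 1/θ (constant) or (κ/θ)(t/θ)^{κ−1} (Weibull; κ = 1
recovers the constant family), per-layer social transmission rates
s_k ≥ 0 expressed relative to the asocial rate, knowledgeable indicators
z_j, presence π_j, and transmission weights w_j — the transmitter's solves
per day since its own acquisition, so prolific solvers transmit more.
Two time-varying individual-level variables x_i (parental solves since
fledging; own scrounges to date) may multiply the asocial rate, the
social rate, or both.  Networks, weights, presence and ILVs are held
piecewise-constant between acquisition events, which makes the
log-likelihood closed-form: one log-hazard term per event plus the
negative integrated hazard over every interval in which an individual is
naive and present, with non-learners censored at the site end time.
The multi-site likelihood is the sum of per-site likelihoods with shared
parameters; sites with fewer than 3 acquisition events are dropped as
uninformative.

Numerical choices: tied acquisition times are separated by 1 s in
recorded order (the event-history likelihood needs a strict order); the
TADA time axis is days since diffusion start; ILVs are centred across the
learner pool within each interval and scaled to unit variance (raw
parental-solve counts reach hundreds, and exp(β·x) on that scale
destroys the optimisation — centring cross-sectionally per interval keeps
the "average individual" interpretation of the baseline at every event
time); linear predictors are clipped at ±300 inside the likelihood as an
overflow guard far outside the plausible region.  Fitting is
box-constrained L-BFGS-B (s ≥ 0; θ, κ on the log scale, κ ∈ [0.05, 20])
from five starts: social rates at 0.1, 1 and 10 plus two seeded jitters;
the baseline scale starts at the exponential MLE that ignores networks.

## Model set, support, and uncertainty

For each baseline family, all 2⁴ network subsets × 4² ILV placements
({absent, asocial-only, social-only, both} per ILV) give 256 models.
Models are ranked by AICc with n = total acquisition events; support for a
network or ILV is the summed Akaike weight of models containing it, and
the two baseline families are compared by summed weight over the pooled
set.  Model-averaged effect sizes are Akaike-weight-weighted medians
across the models containing the parameter (weights renormalised) — one
specific reading of a model-averaged median, flagged as such in the
output.  Confidence intervals are profile likelihood on the
best-performing model: the 95% interval is the set of parameter values
whose profile deviance stays within χ²₁(0.95) = 3.841; a side whose
profile never crosses the threshold within bounds is reported *open*
(this genuinely happens for weakly-informed social rates), and the lower
box bound 0 closes the interval there when the deviance at 0 is inside
the threshold.

## Pathway decomposition

At the learner's own acquisition event the hazard is a sum of one asocial
and four social components; each event's pathway probabilities are the
component shares p_k = s_k exp(β_S·x) T^{(k)} / R and p_asocial =
exp(β_A·x) / R, which sum to one by construction.  %ST per pathway is the
mean per-event probability × 100.  Events are classed *first-in-cohort*
(no same-brood bird knowledgeable at the event time) versus *subsequent*;
per-class means and medians are both reported, since a median over
per-event probabilities and a mean answer slightly different questions.

## Regressions

* **Exposure** — learned-or-not against log10(count+1) of parental solves
  and parental scrounges between fledging and the juvenile's acquisition
  (non-learners: 15 days post-fledge, the mean latency to first solving).
  The log10 scale makes a one-unit step a tenfold increase in counts and
  keeps zero counts admissible.
* **Side choices** — (1) first-day right-proportion against the parental
  strategy during dependence (none / >90% right / >90% left /
  conflicting); this is a linear model on proportions.  (2) First-day
  choice against the right-proportion among other birds' solves in the
  prior 5 minutes, interacting with how many such solves there were.
  (3) All solves with both information sources available (≥1 other-bird
  solve in 5 min, ≥1 own solve in 1 h): social and personal
  right-proportions, each interacting with cumulative experience per 100
  solves.

The estimator behind these contracts is penalized-likelihood (MAP)
logistic regression under normal priors (sd 10 intercept, sd 5 slopes)
with Laplace intervals, and cluster-robust (by juvenile) covariance where
repeated solves per bird induce within-bird correlation; the single-bird
degenerate case falls back to Laplace intervals with a warning.  Any
engine returning posterior means and 95% intervals under the same priors
is interchangeable with it.

## Synthetic data

The generator emulates the study system at desk scale with known ground
truth: 4 sites × 12 breeding pairs × mean clutch 5 (≈ 240 fledglings,
matching the order of the real populations), half of the breeding pairs
knowledgeable demonstrators (as in the experimental design, which
prioritised exposing juveniles to solving parents), a 2-week demonstrator
seeding period, 10 weeks of tracking with 4 puzzle days and 2 feeder days
per week, lognormal individual solve rates around 6 solves per
experimental day, and a conformity/personal-information side-choice rule
whose coefficients default to odds ratios of the size reported for this
system (social 4.15, personal 7.30, experience interactions 1.22 and 0.76
per 100 solves).  Feeder gatherings are small flocks: a few whole
families per gathering, drawn with heterogeneous gamma-weighted
propensities (some families are feeder regulars, others rare visitors),
siblings attending at 0.9 and parents at 0.6, with rare unrelated
drop-ins.  This yields sibling > vertical > oblique/peer association
strength and — critically — sparse, strongly contrasting cross-family
ties.  The default baseline scale (θ = 5000 days, asocial learning rare)
yields roughly 60–80 juvenile learners dominated by sibling transmission
with oblique second, the regime the pipeline is meant to resolve.  Two
named variants pin down inference behaviour: `recovery_scenario`
(sibling-only transmission, s = 5, θ = 1000, two demonstrators per site)
and `null_scenario` (no social transmission, θ = 300).

The end-to-end scenario diffuses on the whole-study association networks
implied by the simulated feeder stream, so the co-feeding record and the
learning opportunities share one social structure — the structure the
pipeline later re-estimates in ±7-day windows.  The controlled recovery
and null scenarios instead use seeded heterogeneous block networks
(per-dyad Gamma(2, ½) multipliers around the layer means) and fit on the
simulator's exact arrays, because coverage statements only make sense
when the fitted model matches the generating process.

Three structural facts about identifiability drove this design, and they
carry over to real studies.  A near-uniform layer is confounded with the
asocial baseline: if every naive individual carries a similar weighted
sum of knowledgeable neighbours, social transmission through that layer
is absorbed into λ0, so heterogeneous (ideally sparse) associations are
what make a pathway estimable.  Oblique and peer transmission are
separable only while their knowledgeable memberships differ — with few
demonstrators, once juveniles start learning, the two layers' exposure
patterns become collinear; a demonstrator-rich start (here, half the
pairs) anchors the oblique signal before peer exposure exists.  And
window-estimated simple-ratio indices attenuate weak ties far more than
strong family ties, so %ST estimates on re-estimated networks are biased
toward asocial/sibling relative to the generating truth.

The diffusion is simulated by exact event-driven sampling: within each
interval individual hazards are constant multiples of the baseline, so
the next learner comes from competing exponentials in integrated-baseline
time (time rescaling makes this exact for the Weibull family), and each
event's ground-truth pathway label is drawn proportional to the learner's
hazard components.  There is no time discretisation, so the simulator
doubles as a quadrature-free oracle for the likelihood.  The puzzle
stream realises the schedule by placing each learner's first two solves
minutes before its scheduled acquisition and the third exactly at it —
so knowledge-state derivation recovers the schedule — with subsequent
solves on puzzle-deployment days at the bird's individual rate.

What the generator does **not** emulate: spatial movement and
between-site visitors, mortality and emigration (presence is effectively
constant), seasonal drift in association strength, imperfect detection
and antenna misreads, and any dependence of solve rate on time since
acquisition.  Passing tests therefore show that the estimators recover
the truth *when the model matches the generating process and association
strengths are known block values*; on re-estimated networks the
transmission rates are attenuated or inflated by SRI estimation noise,
which is visible in the end-to-end pipeline as less extreme %ST shares
than the ground-truth pathway labels.

## Problem sizes

The test suite fits 16-model network sets on ~50–60 simulated learners
across 4 sites, 20 replicates for the recovery and null studies, and
10,000 Monte-Carlo draws for the next-learner check.  The acceptance
script runs the full pipeline once at the default desk scale, including
both 256-model baselines (512 fits) on the re-estimated diffusion data.

## Known limitations

* The gathering-event detector is a specified stand-in (BIC-selected 1-D
  Gaussian mixtures with a variance floor), not the published
  spatio-temporal clustering tool it replaces; its cluster boundaries on
  heavily overlapping bouts will differ.
* Filtered adults' own acquisition intervals are excluded from the
  likelihood entirely (they enter only as transmitters); alternative
  treatments of their at-risk period are not implemented.
* OADA (order-of-acquisition) and Bayesian NBDA variants are out of
  scope, as is continuous-time interpolation of networks between events.
* Model-averaged medians across bootstrap replicates are not computed —
  only across models.
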