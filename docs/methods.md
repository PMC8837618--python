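# Methods

## The task

`retroval` models an adapted two-stage decision task. On each of 256 trials a
participant chooses between two coloured stage-1 stimuli. Colour alone
determines the transition: colour *c* leads to second-stage state *c* with
probability `p_common = 0.7` (a *common* transition) and to the other state
otherwise (*rare*). Each second-stage state offers two grey shapes; exactly
one of the four shapes pays reward with probability 0.8, the rest with 0.2,
and the best shape is redrawn uniformly every 32 trials. The stage-1 stimuli
additionally carry one of five *outcome-irrelevant* shapes. At the end of
every trial beyond the first 10, one irrelevant shape is probed for a
subjective value rating on a bounded visual-analogue scale; on a designed half
of trials an attention probe (recall of the chosen side) precedes the rating.

Scheduling constraints: stage-1 shape pairs never repeat across consecutive
trials (each trial's pair is drawn uniformly from the shapes not offered on
the previous trial), and the probed shape was offered on neither the current
nor the previous trial. With five shapes and disjoint consecutive pairs,
these constraints leave exactly **one** eligible shape per probe from trial 1
on (three candidates on trial 0, drawn uniformly), so the probe sequence is
essentially determined by the offer schedule. A consequence we measure rather
than impose: the distance between a shape's last stage-1 choice and its probe
averages ≈ 4.9 trials under this scheduler.

Attention flags are an exact half split (random permutation), not per-trial
coin flips. Colour-to-side assignment is randomised per trial. Aborted trials
(stage-1 timeout) are a simulator option with default probability 0; they
carry no stage-2 fields and contribute nothing to likelihoods or analyses.

## The hybrid choice model

Choices come from the classic mixture of a SARSA(λ) model-free learner and a
forward-planning model-based learner with five free parameters:

- α ∈ [0,1] — learning rate (shared by both stages),
- λ ∈ [0,1] — eligibility/temporal discount,
- ω ∈ [0,1] — model-based weight,
- β ≥ 0 — decision precision (inverse temperature),
- π ∈ ℝ — perseverance bonus for the previously chosen colour.

Model-based stage-1 values are recomputed each trial by planning,

    Q_MB(c) = p·max Q_s2(pair of c's common state) + (1−p)·max Q_s2(other pair),

with the true transition matrix (the explicit group was instructed about the
structure; an option to estimate transitions from counts exists but defaults
off). Stage-1 choice probabilities are a softmax over utilities

    u(c) = β·[ω·Q_MB(c) + (1−ω)·Q_MF(c)] + π·1[c = previous choice].

π sits outside β so that it is in utility units directly and β scales only
learned values; at β = 0 value differences are ignored while a perseverance
habit can persist. Stage-2 choices use the same β over the offered pair's
cached values — the model has exactly five parameters, no second temperature.

After the outcome all updates are applied together:

    Q_MF(c)  += α·(Q_s2(chosen) − Q_MF(c)) + α·λ·(r − Q_s2(chosen))
    Q_s2(ch) += α·(r − Q_s2(chosen)),

with the stage-1 error evaluated against the *pre-update* stage-2 value. All
values start at 0. Because updates are batched at outcome time, the
pre-decision and pre-outcome value snapshots of a trial coincide; the latent
trajectory stores one snapshot per trial and exposes both views.

## The four candidate prediction errors

From the pre-update snapshots of each trial:

    TDE_S1 = Q_s2[chosen s2 shape] − Q_MF[chosen colour]
    TDE_S2 = r − Q_s2[chosen s2 shape]
    MFΔQ   = r − Q_MF[retro colour]
    MBΔQ   = r − Q_MB[retro colour]

The *retro colour* is the colour whose common transition leads to the
second-stage state actually reached: the chosen colour on common trials, the
unchosen one on rare trials. MFΔQ and MBΔQ are therefore *retrospective*
teaching signals — they credit the action that most likely *would have*
produced the observed state. On common trials the identity
`MFΔQ − TDE_S2 = TDE_S1` holds exactly and is asserted to 1e−10.

Sensitivity note: MBΔQ's planning value is computed from the pre-outcome
stage-2 snapshot. Using the post-update snapshot instead shifts MBΔQ by
a term of order α on the minority of trials where the updated shape is the
state maximum; the stepwise comparisons reported here are insensitive to
this choice because the two variants correlate near unity.

## The ratings-generation model

Each irrelevant shape carries a latent value v ∈ [0,1], initialised at 0.5.
On each completed trial one shape's value is nudged by
`alpha_rating · RPE` under the configured rule:

- rules `TDE_S1` / `TDE_S2` update the **chosen** shape;
- rules `MFdQ` / `MBdQ` update the shape **carrying the retro colour**
  (the chosen shape on common trials, the other offered shape on rare ones) —
  the retrospective teaching signal lands on the stimulus of the action it
  credits;
- rule `none` performs no update (the type-I / null condition).

Probed ratings are `clip(scale(v) + ε)`, ε ~ N(0, noise_sd²), on a
(0, 400)-pixel scale. Defaults `alpha_rating = 0.3` and `noise_sd = 40`
(10% of the scale) produce per-subject rating SDs far above the 20-pixel
exclusion threshold while leaving single rating changes noise-dominated,
which is what makes the pooled stepwise comparison (rather than any single
subject) informative. A mechanical consequence worth noting: updating the
*chosen* shape by a retrospective RPE would produce an exactly-zero expected
2×2 ratings contrast (the reward terms cancel between the common and rare
columns), so only the retro-target semantics can generate the model-based
transfer signature that the indices measure.

## Estimation

The session likelihood multiplies, over non-aborted trials in order, the
stage-1 and stage-2 softmax probabilities of the observed choices. Fitting
works on an unconstrained scale (logit α, λ, ω; log β; identity π) with
L-BFGS-B and multistarts (default start plus Gaussian draws around the prior
mean; ties broken by objective then by parameter norm). Standard errors come
from the inverse numerical Hessian at the optimum. Non-convergence is
flagged, never raised.

Hierarchical estimation is empirical-Bayes EM: subjects are MAP-fitted under
a Gaussian prior on the transformed parameters; the group mean is the mean of
the subject estimates and the group variance adds the mean Laplace posterior
variance (floored at 1e−3); iteration stops when the group means move less
than `tol`. The default prior (mean 0 on the logit scales, log β centred on
β = 3, SDs 1–1.5) is deliberately weak; single-subject fits accept the same
prior object for plain MAP regularisation.

Parameter recovery at the study's scale (30 subjects × 256 trials, parameters
drawn α, λ ~ U(0.2, 0.8), ω ~ U(0, 1), β ~ U(2, 8), π ~ U(−0.3, 1)) gives
rank correlations ≈ 0.93 (α), 0.86 (ω), 0.97 (β), with λ ≈ 0.7 and π ≈ 0.9
— λ is the weakest-identified parameter, as expected for this model family.

## Analysis stages

**Stay analysis.** Stay is defined on the chosen colour across adjacent
non-aborted trials, tabulated by the previous trial's transition × reward.
The summary indices are

    Choice_MB  = (CR + RU) − (CU + RR),   Choice_MF = (CR + RR) − (CU + RU),

and identically for condition-mean percentile ratings (Ratings_MB/MF), where
each rating is attributed to the last trial its shape was chosen at stage 1.
Ratings are rank-transformed within subject (average ranks, percentile
(rank − ½)/n·100) so the indices are invariant to monotone distortions of
each subject's scale use.

**Regressions.** The cohort stay regression is a mixed logistic model (±1
coding for reward and transition) with per-subject random intercepts and
slopes fitted by variational Bayes; a singular fit falls back to random
intercepts only, then to a cluster-robust population logit, each fallback
logged and recorded in the result. The ratings ANOVA fits the per-subject
condition-mean percentiles with fixed reward, transition and interaction
terms and a per-subject random intercept (with one mean per cell, subject
slopes are saturated); F is the squared Wald statistic on (1, N−4) df.
Under the null rating rule the interaction test is calibrated (≈ 3–5%
rejections at α = 0.05 over 100 cohorts).

**Rating changes and the stepwise comparison.** For each pair of consecutive
ratings of a shape with exactly one stage-1 choice of that shape in between,
the change in percentile rating is paired with the four RPEs at that choice
trial; intervals containing more than one choice are excluded. The stepwise
procedure fits each RPE as a single predictor, enters the best one if its F
test against the intercept-only null passes α = 0.05, reports AIC and
natural-log likelihood ratios for all candidates, attempts one further
forward step (halting on collinearity), and repeats the selection with a
per-subject random intercept and with random slope + intercept. Because the
entry test is applied to the best of four strongly correlated candidates, the
family-wise null entry rate is ≈ 15–20%, not 5%; the selection among
candidates — the quantity of scientific interest — is what the recovery study
validates: with rating-rule cohorts at the study's size (26 subjects), the
procedure identifies the generating rule in essentially all of 50 replicate
cohorts per rule, including the MBΔQ-vs-TDE_S1 cells that carry the
explicit/implicit dissociation. Rule-recovery replays trajectories at the
generating parameters to isolate the ratings-inference stage; the estimation
path is validated separately by parameter recovery.

**Exclusions.** Explicit-group cohorts drop subjects with Choice_MB ≤ 0 and
subjects whose raw rating SD is below 20 pixels (the population-relative
2.4-SD threshold is reported alongside, not enforced); implicit-group cohorts
apply no model-based filter but still screen near-constant raters, and the
number of model-based subjects is reported. Upstream exclusions (e.g. a
corrupt file) are passed in and folded into one report with reason codes.

**Auxiliary analyses.** Location (side) stay and irrelevant-shape stay
regressions (shape stay is evaluated at the next trial where the shape is
offered again, since shapes never repeat immediately); the attention 2×2 on
attention-minus-no-attention condition means; the forward-planning control
(do the rating trial's own reward/transition predict the rating); the
intervening-trial control (does the change in the planning value of the
chosen colour between choice and rating predict the rating); and pooled
correlations between logit-transformed choice indices and the transfer
indices. The choice indices live on [−2, 2] and are mapped through
logit((x + 2)/4) — the transform is a package choice, as no standard form
exists for this quantity. Note that the per-subject ratings indices carry
intrinsic noise of roughly 10–15 percentile points at 246 ratings per
session (the value-update process itself, not just rating noise), so
choice–transfer correlations across a few dozen subjects are weak effects
by construction; the correlation operation is validated on constructed
index tables rather than gated on a simulation.

## Synthetic data: what it does and does not emulate

The generator reproduces the task's probabilistic structure, the schedule
constraints, probe geometry, the bounded rating scale, exact-half attention
probes, optional aborts, and rating noise. It does not emulate: reaction
times, attention-dependent behaviour (none was expected), within-session
parameter drift, lapses or disengagement, subject-specific rating-scale
anchoring beyond an additive noise model, or the spurious task models
implicit-group participants may invent. Passing recovery tests therefore
shows the *pipeline* is correct and well-calibrated under the stated
generative assumptions; it does not by itself certify conclusions about any
particular empirical data set.

## Problem sizes and numerics

Default analysis sizes — 30 (or 26/21) subjects × 256 trials, 50 replicate
cohorts per rating rule, 100 null cohorts — match the study's scale and were
chosen so every recovery and calibration study is a routine desk computation.
Floating-point outputs are written with full precision; test comparisons use
relative tolerance 1e−8 except the snapshot-algebra identity (1e−10 absolute)
and exact replay equivalence (bit-for-bit). Degenerate inputs are defined
behaviour: empty stay cells yield missing probabilities excluded from
averages; constant ratings rank at the 50th percentile and are caught by the
SD screen; a constant RPE column yields a missing correlation entry; prior
dispersions are floored rather than allowed to collapse.

## Known limitations

- The hierarchical EM uses Laplace posteriors; it is not full MCMC, and
  group-level uncertainty is not propagated into the RPE stage.
- The mixed logistic stay regression relies on variational Bayes posteriors;
  its z statistics are mildly anti-conservative at large trial counts, which
  is why effect-size comparisons accompany significance in the tests.
- The stepwise entry test controls per-candidate, not family-wise, error
  (see above).
- External data sets are ingested via the column-mapping config; no
  downloading is performed by the package, and analyses of such data are
  only as comparable as the mapping is faithful.
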