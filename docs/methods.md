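# Methods

## Model

Each latent class k is a conditional Gaussian VAR(p_k) with exogenous
covariates,

x_t = B_k z_t + Σ_{l=1..p_k} A_{k,l} x_{t−l} + ε_t, ε_t ~ N(0, Σ_k),

and each individual belongs to one class with mixing proportion π_k.
The likelihood is *conditional*: the first p occasions of each participant
are conditioned on, not modelled — the standard choice for maximum-likelihood
VAR estimation, and the one that keeps unequally long series comparable.
Occasions are chained within participant in (day, beep) order with no
overnight gap, so the last beep of a day is the lagged predictor of the next
day's first beep. This overstates the overnight coupling relative to the
within-day coupling; it is the price of a model without nested within-day
structure, and a reason coefficients may underestimate intra-day
associations.

Classification operates on individuals, not occasions: the E-step forms
responsibilities r_{ik} ∝ π_k exp(ℓ_{ik}) from each participant's *total*
conditional log-likelihood ℓ_{ik}, normalised by log-sum-exp (stable for
log-likelihood gaps of hundreds of nats — routine here, since a participant
contributes ~80 rows). The M-step solves responsibility-weighted
multivariate least squares per class (normal equations; a trace-scaled ridge
only if the Gram matrix is exactly singular), sets Σ_k to the weighted
residual covariance (symmetrised, eigenvalue-floored at 1e-10), and
π_k to the mean responsibility. Mixing proportions are estimated, not fixed
equal. Σ is class-specific by default (`shared_sigma` pools it), because the
degeneracy-reset rule ("add 10 to every element of Σ") reads most naturally
per class.

## Estimation schedule

Defaults: clusters K ∈ {2, 3}; lag orders p ∈ {1, 2, 3} (homogeneous across
classes by default; `heterogeneous_lags` enumerates non-decreasing
per-class lag vectors, canonicalised to avoid relabelling duplicates);
at least 2 members per class; 15 pseudo-random starts (K random
participants as centres, each fitted alone, everyone hard-assigned to the
best-fitting centre, one-hot softened by 1e-3) plus one rational start
(k-means with 10 restarts on per-participant VAR+covariate coefficient
vectors) plus a warm start from the neighbouring grid cell; at most 50 EM
iterations per start; convergence when the log-likelihood improves by less
than 1e-07. Degenerate classes trigger the Σ+10 reset with uniform
re-randomisation of that class's responsibilities; resets are counted and
exempt the monotonicity of the trace at the reset step only.

Grid cells are ranked by the per-observation Hannan–Quinn criterion
HQC = (−2 logL + 2 q ln ln N)/N with q the free-parameter count
(q = Σ_k [d²p_k + d(c+1) + d(d+1)/2] + K − 1, c = covariate columns) and
N the number of modelled outcome rows; AIC is reported alongside. Ties break
toward fewer parameters, then smaller K, then lower lags. Per-observation
normalisation keeps cells with different lag orders (hence different N)
comparable; absolute HQC values depend on this normalisation convention, so
only the *ranking* is meaningful, and no particular printed magnitude is
promised. The best-log-likelihood fit that respects the minimum class size
wins a cell whether or not it converged within the iteration budget
(non-convergence is recorded; usable non-converged solutions are a known
outcome of this estimation style).

All randomness flows from one config seed through counter-based
`SeedSequence(entropy=seed, spawn_key=(cell, start))` streams, so any grid
cell reproduces independently.

## Data preparation

Compliance: a prompt counts as completed only if *every* item was answered
(the delivery app expired whole questionnaires), and the denominator is the
full schedule D×B; the default inclusion rule keeps participants with ≥ 50
completed prompts of 84 (60%). Item-level partial missingness remains
representable and is imputed.

Imputation is chained-equations, single imputation: initialise missing cells
at variable means, then sweep variable-by-variable, regressing each
incomplete variable on all others pooled across occasions and participants,
drawing coefficients and noise from the approximate posterior
(Bayesian-draw linear regression; predictive-mean matching with 5 donors as
an option), clamping to the 0–100 slider. The default budget is 500 sweeps,
read as chained-equation iterations; tests and examples use 5–20 sweeps
because the chain mixes in a handful of sweeps at these missingness levels.
Pooling across participants (no participant effects in the imputation
model) is the simplest faithful scheme and a known limitation: it shrinks
imputed values toward the pooled regression surface.

Variables are z-scored pooled across the sample before fitting (off by
default in `standardize`-free workflows; the pipeline does it by default),
so lagged coefficients read as standardised effects of the ±0.15 magnitude
scale. Time of day enters as B−1 beep indicators (reference: first beep)
because the daytime-course summaries are per-beep means; continuous clock
time and a linear day trend are config alternatives.

## Synthetic panels

The generator emulates the study design: 14 days × 6 beeps of 0–100 slider
items, class-specific stable VAR dynamics (every emitted model's companion
spectral radius is capped below 1 by exact s^l rescaling of the lag-l
matrices), class-linked trait tables, and MCAR item-level missingness (a
beep-dependent MAR option exists because evening beeps plausibly differ;
a dropout rule can impose whole-prompt completion counts for roster
experiments). Diurnal profiles are *target means* per (beep, variable);
internally they become per-occasion intercepts c_t = μ_t − Σ_l A_l μ_{t−l},
which makes the stationary per-beep means match the profiles exactly. The
default appetite profile is the diurnal "M-curve": hunger/craving means
peaking mid-morning and late afternoon. A 50-step burn-in precedes each
recorded series; recording clamps to [0, 100] while the recursion itself
stays unclamped — default scales (base ~45–50, amplitude 15, innovation SD
8) keep clamping below 1% so the mild nonlinearity does not disturb
recovery tests. Cluster assignment is redrawn (bounded retries) until every
class has ≥ 2 members.

What the generator does *not* emulate: non-Gaussian innovations,
within-day nesting or random effects, autocorrelated missingness,
reactivity, and real circadian physiology. Passing recovery tests therefore
show the estimator works when its assumptions hold — they do not certify
behaviour on real EMA data, where model misspecification is the norm.

The shuffled-null control permutes each participant × variable series in
time (missing cells travel with their values), preserving marginals while
destroying lagged structure; refitting on such panels should and does
collapse the lagged coefficients (mean |A| ≈ 0.02–0.03 against a 0.05
bound at n=50, T=84).

## Characterisation

One-way ANOVAs report SS_num, SS_den, F, p and generalised eta-squared
(= SS_num/(SS_num+SS_den) in this one-way design); Tukey HSD contrasts use
the studentized-range distribution with the Δ_(b−a) sign convention; the
gender × cluster table uses an exact Fisher test implemented by full
enumeration of all tables with the observed margins via log-factorial
accumulation, with the two-sided p defined by probability ordering (sum of
probabilities of all tables no more probable than the observed one — the
convention of the common statistical software; other two-sided definitions
exist and can differ in the third decimal). A zero row/column margin is
degenerate and returns p = 1 with a warning; enumeration is refused above
10,000 observations. Participants missing a trait are dropped listwise per
test; no multiple-testing correction is applied by default (a Holm flag
exists).

## Problem sizes and numerical choices

The test and acceptance suites run the estimation studies at n = 50–60
participants, T = 84 occasions, d = 4 variables, K up to 3, lags up to 3,
with the default 15+1 starts — sizes chosen so each full grid search takes
a few seconds while leaving the per-class designs (~1,600 rows × 17
predictors) well-conditioned. Designated cross-lagged effects of ±0.35
separate every pair of classes by 0.7 on some entry; under these conditions
membership recovery is essentially exact (median adjusted Rand index 1.0),
coefficients come back within ~0.07 absolute error, and the HQC grid picks
the true (K, lag) in 5/5 replicates.

Other numerical details: Cholesky-based Gaussian densities everywhere;
hard labels are argmax responsibilities with ties to the lowest class
index; `information_criteria` refuses N ≤ e (ln ln undefined); nearest-PD
projection (eigenvalue flooring) guards the Σ+10 reset; the per-participant
VAR fits inside starts use a small fixed ridge (1e-6) since 80-occasion
individual fits are frequently ill-conditioned.
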