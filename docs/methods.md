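# Methods

This note documents the models implemented in `prefobs`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## The subjective-value model

A social preference is a scalar `P ∈ [0, 1]`: the proportion of points a
person ideally keeps for themself (0 fully prosocial, 1 fully selfish). An
allocation `x` (also a proportion-for-self) has subjective value

    s(x) = 1 − (x − P)²

— single-peaked at `P`, falling off quadratically. Everything downstream is
a function of subjective values: decision difficulty is `|s(left) −
s(right)|` (0 = hardest), estimation accuracy is `1 − |estimate − truth|`,
and the chance level of an uninformed guesser is `E[1 − |U − P|] = 1 − (P² +
(1−P)²)/2` for `U ~ Uniform(0,1)`, which the Monte-Carlo
`empirical_chance_level` reproduces (both routes are kept and
cross-checked).

Accuracy is oriented so that larger is better. Equidistant options in the
consistency metric are reported as a third state (`tie`) and excluded from
consistency rates rather than counted either way.

## Dictator model: drift diffusion

A decision between two allocations is a Wiener process with unit diffusion
coefficient between absorbing boundaries at 0 and `b`, starting unbiased at
`b/2`, with per-trial drift

    v_t = w · (s(left_t) − s(right_t)),

`w ≥ 0` the drift scale. The upper boundary maps to the left option.
Observed RT adds a non-decision time `τ`. The unbiased start, unit
diffusion, and the upper=left sign convention are field-standard defaults;
a reflection-symmetry test (mirror all allocations and the preference)
guards the convention.

The first-passage density is evaluated with the classical pair of series
expansions (sum over image charges for small normalised time, sine series
for large), switching to whichever needs fewer terms at truncation
tolerance 1e−6 (capped at 120 terms). Two independent oracles validate it:
the closed-form absorption probability `P(upper) = 1/(1 + e^{−v·b})` (mass
agreement to 1e−3 by quadrature) and an Euler–Maruyama simulation with
Brownian-bridge within-step crossing detection (dt = 1e−3), which removes
the leading-order discretisation bias of plain Euler–Maruyama; histograms
agree bin-wise within 3 binomial SEs wherever expected counts are ≥ 5 (the
normal approximation is invalid below that).

### Preference from RTs alone

Because the choice is unobserved in the RT-only condition, the likelihood
of each trial is the first-passage density *marginalised over both
boundaries*, `f(rt, left) + f(rt, right)`. `RTPreferenceDDM` maximises the
summed log marginal over `(P, b, τ, w)` with multi-start L-BFGS-B (default
10 restarts, initial points uniform within bounds `P ∈ (0,1)`,
`b ∈ (0.1, 10.1)`, `τ ∈ (0, min rt)`, `w ∈ (0, 20)` — the same bounds the
Bayes-optimal grid uses, for comparability). RTs at or below a candidate τ
receive a density floor of 1e−10 instead of −∞ so the optimiser can
traverse the τ axis. Constant-RT inputs are flagged degenerate. Choice-only
estimation (`ChoicePreferenceSoftmax`) is the analogous 2-parameter MLE of
the logistic choice rule `P(left) = 1/(1 + e^{β(s(right)−s(left))})` with β
capped at 100; hitting the cap (near-deterministic data) is flagged, since
the preference is then identified only up to the interval rationalising all
choices.

## Informative-trial selection

Per dictator, RT is regressed on difficulty (`rt = b0 + b1·|s(left) −
s(right)|`, OLS; `b1 < 0` on diffusion-like data). Trials are categorised:
*slow* if `rt > b0` (slower than the hardest-possible trial is predicted to
be, so the preference likely sits near the pair midpoint), *fast* if
`rt < b0 + b1·(left − right)²` (faster than any midpoint-preference account
allows — the preference lies outside the option interval; `(left − right)²`
is the maximal difficulty the pair can attain), the rest uninformative.
Inconsistent choices (chosen option strictly farther from the preference)
are dropped; equidistant options survive. The observation set is the 6
fastest fast trials plus the 6 slow trials with midpoint closest to the
preference; the next 2 + 2 become prediction problems. Ties break by trial
index for reproducibility.

The trial order is chosen to be learnable: orderings are scored by running
the RL forward model in all four conditions and summing |final estimate −
P|. Exhausting all 12! orderings is infeasible, so the search is exact only
below a configurable permutation count and otherwise evaluates a seeded
random sample (default budget 50–200 orderings, always including the input
order).

## Observational reinforcement learning

The observer keeps a point estimate `P_t`, updated after every observed
trial by `P_t = P_{t−1} + α(O_t − P_{t−1})`. The teaching signal:

| condition   | outcome `O_t` |
|-------------|----------------|
| choice only | 1 if the chosen allocation is the larger (more selfish) one, else 0 |
| RT only     | slow trial → pair midpoint; fast trial → selfishness of the option with higher `s(·)` under `P_{t−1}` |
| both        | `(1−ω)·O_choice + ω·O_RT` (the weighted variant; the unweighted slow→midpoint / fast→choice variant is available) |
| none        | pair midpoint |

A trial is *slow* when its RT strictly exceeds the running mean of all RTs
seen for this dictator, current trial included — so a first trial is never
slow. All outcomes lie in [0, 1], and the delta rule is a convex
combination, so `P_t` provably never leaves the unit interval (asserted,
not clipped).

Slider estimates are Gaussian around `P_t` with fixed SD σ (default 0.1 —
the estimation-noise scale is a fixed configuration constant, not a fitted
parameter); predictions use a softmax with inverse temperature `β_p` on
subjective values at the final estimate. The prediction objective is the
negative *log* softmax probability; a literal negated-probability variant
is selectable (`literal_eq14=True`) because the two readings of the
objective differ only in that logarithm.

`ObserverRLModel` fits `(α, P0, ω, β_p)` per observer by minimising the
summed estimation + prediction negative log-likelihood (unweighted sum),
with restart initial values drawn from Beta(1.1, 1.1) for α, Gamma(1.2, 5)
for `β_p`, uniforms for `P0` and ω (no prior is specified for those two),
and 50 restarts by default. `P0` is shared across an observer's sessions
(a single parameter). Fitting uses a compiled per-session representation —
speed labels and choice outcomes are parameter-independent and precomputed
— which is verified against the reference forward pass to 1e−10 and makes
a 16-session fit take about a second.

## Bayes-optimal benchmark

The ideal observer assumes the generative DDM above and maintains a
discretised joint posterior over its five parameters with priors
Beta(3.5, 3) on `P ∈ (0,1)`, Gamma(shape 1.2, scale 5) on `β ∈ (0,100)`,
Gamma(2, 2) on the boundary `∈ (0.1, 10.1)`, Normal(0, 5) truncated and
renormalised on the drift scale `∈ (0, 20)`, and uniform non-decision time
`∈ (0.1, 0.5)`. The Gamma parameters are read as (shape, scale); the rate
reading would put nearly all β mass below 1 (essentially random choice),
which is inconsistent with their use as restart priors. Cells are centred
at midpoints of equal-width bins, 15 per axis by default (≈ 7.6e5 cells);
doubling the preference resolution changes the estimate by < 0.01 on a
reference session.

Per observed trial the grid weights are multiplied by: the WFPT density at
the observed (choice, RT) in the both condition; the softmax choice
probability in choice-only; the WFPT density summed over both boundaries in
RT-only; a constant in the none condition (posterior = prior, exactly).
Updates accumulate in log space and renormalise each trial; the
separable structure (the WFPT factor is constant across β, the softmax
factor constant across the DDM axes) keeps a 12-trial session under a
second. The reported estimate is the mean of the marginal posterior over
`P` (stable on coarse grids); the joint-MAP cell is available because
"maximise the posterior" is the other defensible reading. Posterior
predictions of choices average the softmax probability over the (P, β)
marginal.

## Synthetic-study generator

`make_design` builds the canonical Dictator-Game design: 11 allocation
levels (0 to 1 in 0.1 steps), all 55 distinct pairs, 3 repeats (165
trials), per-trial truncated-normal noise on each allocation (mean 0, SD
0.02, bounded at ±0.05 — the bound is on the noise draw; post-noise values
are clipped to [0, 1] and exact ties are resampled), and left/right
placement balanced across repeats. `sample_dictators` draws 16 agents with
preferences stratified over [0.05, 0.95] (so every 4-dictator condition
block spans the range) and DDM parameters in realistic mid-ranges of the
observer prior bounds (boundary 1.5–2.5, τ 0.2–0.4, drift scale 4–8).
Observer sessions follow the 2×2 within-subject design: per observer, the
preference-sorted dictators are dealt round-robin into the four conditions
with a random rotation per block; choice and RT fields are masked per
condition; estimation slots sit before observing and after trials 4, 8, 12;
4 held-out prediction problems (2 fast, 2 slow) follow.

What the generator does *not* emulate: slider kinematics and motor noise,
attention lapses, sequential condition-order effects, imperfect time
perception (observers classify fast/slow from exact RTs), or payment-driven
motivation changes. Passing tests therefore show that the estimation and
learning machinery is correct and well-calibrated on data that satisfy the
models' assumptions — not that humans behave this way. One consequence is
worth stating: with exact RT perception and midpoint-optimised slow trials,
the forward RL observer learns nearly as well from RTs alone as from
choices alone, so cohort simulations reliably show both > {choice-only,
RT-only} > none but no stable choice-vs-RT gap; a human-like RT deficit
would require injecting speed-misclassification noise, which the generator
deliberately does not do.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and the acceptance script are the
package's own defaults: 16 dictators × 165 trials, 46 observers × 16
sessions, 10 optimiser restarts for per-dictator and per-observer fits
(50 remains the library default for RL fitting), order-search budget 50,
1e5 Euler–Maruyama paths for density validation, grid resolution 15 per
axis. Seeds propagate from a single master seed via `SeedSequence.spawn`,
so a (config, seed) pair determines every output byte. CSV is the only
interchange format; every table carries a schema-version comment line and
is validated (with row numbers) on read and write.

Known limitations: no across-trial DDM variability parameters (sv, st, sz)
and no start-point bias; no hierarchical fitting; the RT-only likelihood
surface is mildly multimodal (reflection-like local maxima), so a handful
of restarts genuinely matters — single-start fits occasionally land a
mirrored preference; BO slider estimates are deterministic summaries of the
posterior (no report noise), so BO "behavior" should be compared to RL at
the level of estimates, not estimate noise.
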