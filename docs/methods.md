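# Methods

This note documents the models implemented in `infoflow`, the
assumptions behind them, the defaults that matter, and what the
synthetic generator does and does not emulate.

## Engagement dynamics

**State definition.** Engagement is *observational*: a user is engaged
at day *t* if they posted or reshared a link of the tracked category in
the half-open trailing window (*t* − τ, *t*]; active users are defined
the same way over all events.  The default window is **τ = 3 days** —
short enough to track the fast pace of the platform — and is
configurable everywhere.  The same half-open convention is applied to
engagement, disengagement and activity.

**Rate inversion.** With E and N the engaged and active counts, the SIS
balance equations dE⁺ₜ = αₜ·E(N−E)/N and dE⁻ₜ = βₜ·E are inverted using
*predecessor* states (exposure at *t* − 1 drives the transition at *t*):

    alpha_t = dE+_t * N_{t-1} / (E_{t-1} (N_{t-1} - E_{t-1}))
    beta_t  = dE-_t / E_{t-1}
    R_t     = alpha_t / beta_t

Days where the inversion is undefined (E = 0; E = N for α; β = 0 for R)
carry NaN rather than a fabricated zero, so early- and late-stream days
cannot produce spurious infinities.  The conservation identity
Eₜ − Eₜ₋₁ = dE⁺ₜ − dE⁻ₜ holds exactly by construction of the per-user
engagement intervals.

**Peak detection.** Rₜ series are noisy and gappy.  The detector
linearly interpolates gaps of at most 2 days, smooths with a centered
rolling median (default width 7 days), and returns local maxima above a
configurable quantile of the smoothed series (default 0.90), keeping
only the higher of any two peaks closer than the minimum separation
(default 7 days).  The rolling *median* was chosen over a mean so that
isolated undefined/extreme days cannot manufacture or displace a peak;
the width trades localisation (±1–2 days) against robustness.

## Retweet hypergraph and its flow

Each original tweet with ≥ 1 distinct retweeter forms a directed
hyper-edge ⟨tail = poster, head = retweeters⟩.  Duplicate retweets of
one root by one user collapse; self-retweets are dropped (so the head
size |α| stays meaningful); originals without retweets contribute only
their node.  Retweets whose root is missing from the stream keep the
retweeter and a synthetic `unknown:<root>` tail, and are logged.
Hyper-edges are not time-decayed; temporal analysis instead rebuilds
per-period hypergraphs.

The random walk picks an incident hyper-edge uniformly (not weighted by
head size), then a head node uniformly, giving

    T[i->j] = sum_{α in E(i,j)} |α|^-1 / sum_{k, α in E(i,k)} |α|^-1.

When every head has size 1 this reduces exactly to the row-normalized
weighted retweet digraph; that degenerate case is used as an
independent oracle in the tests.

**Teleportation.** Real retweet graphs are weakly connected with many
dangling nodes, so the steady state of T alone is ill-defined.  The
package completes the chain in the standard way: dangling rows are
replaced by the uniform distribution and the walk teleports uniformly
at rate 1 − damping, with **damping = 0.85** by default (damping = 1 is
allowed on ergodic graphs).  The stationary distribution is computed by
power iteration to an L1 residual of 1e−12 (non-convergence is an
error, never silently accepted).

**Edge flow.** p(i,j) = M[j→i]·p(j) is the steady-state probability of
observing a step from j to i, *including* the teleport/dangling
completion, so that Σ p(i,j) = 1 exactly and both marginals equal p.
Internally the flow is stored as a sparse link part plus a uniform
rank-one remainder, which keeps all block sums exact without dense
matrices.  A consequence is that escape probabilities have a
teleportation floor: even a perfectly isolated community leaks
(1 − damping) · (1 − |C|/n) of its mass per step.

## Community detection

Communities maximize the one-step auto-covariance of the walk projected
on the partition,

    Q = sum_C sum_{i,j in C} [ p(i,j) - gamma * p(i) p(j) ],

i.e. directed modularity with stationary-distribution weights; the
resolution gamma defaults to 1 (multi-scale Markov times are out of
scope).  The optimizer is a Louvain-style greedy multi-level scheme:
local moves in a seeded random node order, ties broken toward the
lowest community id, then aggregation, until no gain remains.  Results
are deterministic given the seed; labels are relabelled by decreasing
community size.  The rank-one teleport term is carried through
aggregation exactly rather than dropped.

Per community, the diagnostics are the average visit probability
p(C)/|C| (per-capita stationary mass, a proxy for flow participation)
and the escape probability p(C̄|C) = Σ_{i∉C, j∈C} p(i,j) / p(C) (the
tendency of a walker — a piece of information — to leave).  For
restricted analyses (category-only or media-only sub-hypergraphs,
per-period streams) the partition is computed **once** on the
full-period full-content graph and held fixed, and the hypergraph is
rebuilt on the full node set so the partition remains applicable;
default period breakpoints are 2020-11-11 and 2021-06-01 (configurable;
breakpoints outside the stream fall back to a single period with a
warning).

## Content profiles

Item occurrences are counted once per tweet-or-retweet (a retweet
re-counts its items; duplicates within one posting count once).  The
joint P(i,a) is restricted to the top-K items by count and top-M
communities by user count (both default 50) and normalized over the
restricted sets; both marginals are derived from the restricted joint,
making ξ = P(i,a) − P(i)P(a) a proper covariance-like score with
Σξ = 0 exactly.  (Using raw tweet volumes for P(i) would be
dimensionally inconsistent with a product of probabilities, so
normalized frequencies are used throughout.)  Rows and columns of ξ are
clustered *independently* with agglomerative hierarchical clustering
(average linkage, Euclidean metric by default); the flat group counts
(7 for hashtag profiles, 2 for URL profiles) are reporting defaults,
not algorithmic outputs.  Dendrograms can be exported as newick.

## Synthetic generator

The generator emulates: daily event streams in the canonical format,
planted user blocks with assortative retweeting (row-stochastic block
mixing matrix, default 0.7 on the diagonal), geometric cascade head
sizes (mean 3, capped), SIS-driven adoption of a tagged URL category,
per-block hashtag biases (multiplicative factor 3 on a block's
vocabulary slice), and optional per-period mixing overrides.  Default
study conditions: 2000 users, 100 days, α\* = 0.3, β\* = 0.1, τ = 3,
10 initial engaged seeds.

**Engagement coupling.** Ground truth is defined directly on the
observational state.  When a user engages, a spell length
D ~ Geometric(β) is drawn and the user posts category content daily up
to max(0, D − τ) days later, so the windowed observer sees an engaged
spell of exactly max(D, τ) days and the estimator's E-series equals the
planted one *exactly* (asserted in the tests).  New engagements are
drawn among observationally uncommitted users with probability
α·Eₜ₋₁/N, making the α estimator unbiased by construction.  The one
irreducible distortion is the τ-day floor: spells shorter than τ cannot
be observed by a trailing-window definition (a single post implies τ
engaged days), which shortens the effective mean spell and biases β̂
down by ≈ 10% at the defaults (β = 0.1, τ = 3, mean observed spell
10.29 days vs 10); R̂ is correspondingly high by a similar margin.  This
floor is a property of the windowed observation itself, not of the
estimator.

**Activity.** Every user posts a plain heartbeat original at least once
per τ days (staggered offsets), pinning the active count N at the full
population so the simulated contact process and the windowed estimator
agree on N.  Real streams have churn in N; the estimator handles that
(N is measured per day), but the recovery guarantees are stated at
constant N.

**Mesoscale mode.** For echo-chamber experiments, SIS adoption can be
replaced by per-block category posting rates with a separate category
mixing matrix.  The shipped echo/spreader scenario posts category
content at rates (0.30, 0.05, 0.05) per user-day across
(echo, spreader, audience) blocks; category cascades from the echo
block stay 90% internal, spreader cascades go 80% outward, audience
cascades are absorbed 60% by the echo block.  Media mixing is mildly
reversed (echo more outward on media) so the expected ordering on the
media subgraph is a deterministic reversal rather than a sampling-noise
coin flip — the echo-chamber role is content-specific by design.

**What the generator does not emulate:** sub-daily timestamps, a
follower graph, tweet text, bursty circadian activity, user churn, or
heavy-tailed user activity.  Passing recovery tests on these streams
shows the estimators are correct under the stated model; it does not
show robustness to mis-specification on real platform data.

## Problem sizes and numerical choices

Tests and the acceptance script use: 2000 users × 100 days for rate
recovery, 1000 users × 30 days for partition recovery, 300 users ×
40 days for the mesoscale contrast, 10-node fixtures with 1e5 simulated
walks for the operator oracle.  Power iteration tolerance 1e−12 (L1);
row-stochasticity asserted to 1e−12; Louvain gain threshold 1e−15 with
lowest-id tie-breaks for determinism.  Degenerate inputs fail loudly:
empty hypergraphs, empty communities, unknown categories and
non-convergence raise instead of returning defaults.

## Known limitations

* The stability objective is evaluated at unitary Markov time only.
* Escape probabilities include the teleportation floor; comparisons
  across graphs should hold damping fixed.
* `simulate_engagement` draws a spell's hazard from β at engagement
  time, so per-day β arrays are honoured only at spell starts.
* URL normalization is site-level (scheme/`www.`/path stripped), not a
  full public-suffix registered-domain computation.
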