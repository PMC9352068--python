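# infoflow

Tools for studying how a content category — for instance links to
vaccine-critical websites — circulates through a Twitter-like platform,
from a plain chronological stream of tweet and retweet events at daily
resolution.

The package is aimed at computational social scientists and
infodemiology researchers who want to quantify two things:

1. **Whether engagement with the content spreads by contact.**  A user
   is *engaged* at day *t* if they posted or reshared a category link in
   the trailing window (*t* − τ, *t*]; an *active* user posted anything
   in that window.  Treating engaged users as the infectious compartment
   of an SIS process,

   dE⁺ₜ = αₜ Eₜ₋₁ (Nₜ₋₁ − Eₜ₋₁) / Nₜ₋₁,  dE⁻ₜ = βₜ Eₜ₋₁,

   the observed daily inflow dE⁺ₜ and outflow dE⁻ₜ of engaged users
   invert to a time-varying engagement rate αₜ, a disengagement rate βₜ
   and the reproduction number **Rₜ = αₜ/βₜ**; Rₜ > 1 means the engaged
   population grows through contact, and peaks of Rₜ localize the events
   that trigger engagement waves.

2. **Which communities circulate the content, and how.**  Each original
   tweet with its retweeters is a *directed hyper-edge* (tail = poster,
   head = set of retweeters) — unlike a pairwise retweet graph, this
   distinguishes one tweet retweeted N times from N tweets retweeted
   once.  A random walker picks an incident hyper-edge uniformly, then a
   head node uniformly, giving the effective transition matrix

   T(i→j) = Σ_{α∈E(i,j)} |α|⁻¹ / Σ_{k, α∈E(i,k)} |α|⁻¹,

   with |α| the head size.  From the stationary distribution p(i) and
   the steady-state edge flow p(i,j) the package detects flow-based
   communities (directed Louvain on the one-step auto-covariance) and
   computes, per community C, the **average visit probability** p(C)/|C|
   and the **escape probability** p(C̄|C) — low escape with high visit is
   the signature of an echo chamber.  Community content preferences are
   profiled with the over-usage score ξᵢₐ = P(i,a) − P(i)P(a) over the
   top hashtags/URL domains, followed by hierarchical co-clustering.

A seeded synthetic generator produces event streams with planted ground
truth (SIS adoption, assortative retweet blocks, role-differentiated
echo/spreader blocks, biased hashtag vocabularies) for every analysis.

## Worked example

`examples/engagement_rates.py` simulates 2000 users for 100 days with
true rates α\* = 0.3, β\* = 0.1 (R\* = 3) and re-estimates them from the
emitted stream:

```
stream: 310775 events, 2000 users, 100 days
peak engaged users: 1407
alpha_hat = 0.302   (true 0.3)
beta_hat  = 0.086   (true 0.1)
R_hat     = 3.44    (true 3.0)
R > 1 means engagement with the content spreads by contact.
```

The engagement rate is recovered almost exactly; the disengagement rate
is slightly under-estimated because a single category post keeps a user
observationally engaged for τ days (see `docs/methods.md`).

`examples/community_flow.py` recovers four planted retweet blocks
exactly (ARI = 1.00) and contrasts an echo-chamber block with a spreader
block on content-restricted hypergraphs:

```
vaccine_critical subgraph:
  echo chamber   escape = 0.19   avg visit = 8.50e-03
  spreader       escape = 0.86   avg visit = 1.03e-03
media subgraph:
  echo chamber   escape = 0.80   avg visit = 3.00e-03
  spreader       escape = 0.61   avg visit = 3.83e-03
```

The echo chamber keeps 81% of category flow internal while being
visited eight times more per capita than the spreader; on media content
the ordering reverses — the roles are content-specific.

The other examples cover the micro hypergraph walk
(`hypergraph_flow.py`), hashtag over-usage profiling
(`hashtag_profiles.py`), and the one-shot pipeline (`end_to_end.py`).
The same pipeline is available from the shell:

```sh
infoflow simulate --scenario echo --out-dir sim
infoflow run-all --events sim/events.jsonl --catalog sim/catalog.csv --out-dir out
```

## Input formats

Event streams are line-delimited JSON (or CSV) with fields
`tweet_id, user_id, day, is_retweet, root_tweet_id, urls, hashtags`;
days are integers or ISO dates.  URL catalogs are two-column CSVs
(`domain, category`) with categories `vaccine_critical` / `media`; the
catalog can be extended by 1-hop dilation on the user co-occurrence
network of domains (`build_url_cooccurrence`, `dilate_seed_set`).

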