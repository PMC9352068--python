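"""Synthetic event streams with known ground truth.

The generator emulates the statistical structure of a daily tweet/retweet
stream: planted user blocks with assortative retweeting, heavy-tailed
cascade head sizes, a tagged minority content category whose adoption
follows an SIS-type contact process with engagement rate ``alpha`` and
disengagement rate ``beta``, and community-biased hashtag usage.  Streams
come out in the canonical event format, so every downstream module can be
exercised end-to-end against the planted truth.

Ground truth is defined directly on the *observational* engagement state
(posted category content within the trailing tau-day window).  When a
user engages, a spell length ``D ~ Geometric(beta)`` is drawn; the user
posts category content daily up to ``D - tau`` days (at least one post),
so the windowed observer sees an engaged spell of exactly ``max(D, tau)``
days.  New engagements are drawn among users the observer counts as
uncommitted, with the exact contact probability ``alpha * E/N``, so the
rate estimator's inflow is unbiased by construction; the only residual
bias is the tau-day floor on observable spells (see docs/methods.md).
Every user posts a plain "heartbeat" original at least once per tau days,
which pins the active-user count N_t at the full population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .ingest import TweetEvent, UrlCatalog, write_events

DEFAULT_CATEGORY_DOMAINS = (
    "vaxtruth-synthetic.example",
    "naturalcure-synthetic.example",
    "freedomhealth-synthetic.example",
)
DEFAULT_MEDIA_DOMAINS = (
    "dailynews-synthetic.example",
    "lejournal-synthetic.example",
    "tvinfo-synthetic.example",
)
DEFAULT_HASHTAGS = (
    "vaccine", "pass", "health", "gov", "pharma", "freedom",
    "science", "alert", "truth", "news", "covid", "debate",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic stream.

    Rates are per-day probabilities; the mixing matrix row ``b`` gives the
    block distribution of a retweeter given a poster in block ``b``.
    ``alpha`` and ``beta`` may be scalars or per-day arrays.  When
    ``block_category_rate`` is set, SIS adoption is disabled and each
    user instead posts category content at their block's daily rate
    (mesoscale-fixture mode).
    """

    n_users: int = 2000
    block_sizes: tuple = ()  # empty -> 4 equal blocks
    mixing: tuple = ()  # empty -> 0.7 diagonal assortative
    tweet_rate: float = 0.2  # background originals per user-day
    media_url_prob: float = 0.5  # background original carries a media URL
    head_size_mean: float = 3.0
    head_size_dist: str = "geometric"  # or "powerlaw"
    head_powerlaw_exponent: float = 2.5
    head_size_max: int = 50
    alpha: float | tuple = 0.3
    beta: float | tuple = 0.1
    tau: int = 3
    n_days: int = 100
    n_seed_engaged: int = 10
    heartbeat: bool = True
    media_retweets: bool = True
    category_retweets: bool = False
    block_category_rate: tuple | None = None
    category_mixing: tuple = ()  # empty -> same as mixing
    category_domains: tuple = DEFAULT_CATEGORY_DOMAINS
    media_domains: tuple = DEFAULT_MEDIA_DOMAINS
    hashtags: tuple = DEFAULT_HASHTAGS
    hashtag_bias: float = 3.0  # over-usage factor of a block's own tag slice
    hashtag_prob: float = 0.8  # probability an original carries one hashtag
    period_breaks: tuple = ()
    period_mixing: tuple = ()  # per-period mixing overrides, aligned with periods
    seed: int = 0

    def resolved_blocks(self) -> np.ndarray:
        sizes = self.block_sizes or self._default_blocks()
        if sum(sizes) != self.n_users:
            raise ValueError("block sizes must sum to n_users")
        return np.repeat(np.arange(len(sizes)), sizes)

    def _default_blocks(self) -> tuple:
        k = 4
        base = self.n_users // k
        sizes = [base] * k
        sizes[-1] += self.n_users - base * k
        return tuple(sizes)

    def resolved_mixing(self) -> np.ndarray:
        k = len(self.block_sizes or self._default_blocks())
        if self.mixing:
            m = np.asarray(self.mixing, dtype=float)
        else:
            m = np.full((k, k), 0.3 / max(1, k - 1))
            np.fill_diagonal(m, 0.7)
            if k == 1:
                m = np.ones((1, 1))
        if m.shape != (k, k) or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("mixing must be a row-stochastic k x k matrix")
        return m

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), (self.n_days,)).copy()
        beta = np.broadcast_to(np.asarray(self.beta, dtype=float), (self.n_days,)).copy()
        if (alpha < 0).any() or (beta < 0).any():
            raise ValueError("rates must be non-negative")
        if (alpha > 1).any():
            raise ValueError("alpha is a per-day probability and must be <= 1")
        return alpha, beta


@dataclass
class SimTruth:
    """Planted ground truth accompanying a generated stream."""

    users: list
    blocks: np.ndarray  # user index -> block id
    engaged: np.ndarray  # observed engaged count per day
    spells: list = field(default_factory=list)  # (user_idx, start, post_until, obs_until)
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None

    def block_of(self, user_id: str) -> int:
        return int(self.blocks[self.users.index(user_id)])

    def partition(self) -> dict:
        return {u: int(b) for u, b in zip(self.users, self.blocks)}


@dataclass
class SimulationResult:
    events: list
    truth: SimTruth


def _user_ids(n: int) -> list:
    width = len(str(n - 1))
    return [f"u{str(i).zfill(width)}" for i in range(n)]


def simulate_engagement(config: GeneratorConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Simulate SIS-type adoption and return per-user spell ground truth.

    The contact process runs on the observational engagement state with
    N fixed at the full population (the heartbeat guarantees every user
    is active).  Seeds engage on day 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_users
    tau = config.tau
    alpha, beta = config.rates()
    blocks = config.resolved_blocks()
    users = _user_ids(n)
    obs_until = np.full(n, -10 * tau)  # last day of current/most recent spell
    spells: list[tuple] = []
    engaged_count = np.zeros(config.n_days, dtype=np.int64)

    def _start_spell(u: int, t: int) -> None:
        b = beta[t]
        if b <= 0:
            d = config.n_days + tau  # absorbing: never disengages in-horizon
        else:
            d = int(rng.geometric(b))
        post_until = t + max(0, d - tau)
        spells.append((int(u), t, post_until, t + max(d, tau) - 1))
        obs_until[u] = t + max(d, tau) - 1

    if config.block_category_rate is None:
        for t in range(config.n_days):
            if t == 0:
                if config.n_seed_engaged > 0:
                    seeds = rng.choice(n, size=min(config.n_seed_engaged, n), replace=False)
                    for u in sorted(seeds):
                        _start_spell(u, 0)
            else:
                e_prev = int((obs_until >= t - 1).sum())
                if e_prev > 0 and alpha[t] > 0:
                    p_engage = alpha[t] * e_prev / n
                    eligible = np.flatnonzero(obs_until < t - 1)
                    draws = eligible[rng.random(eligible.size) < p_engage]
                    for u in draws:
                        _start_spell(u, t)
            engaged_count[t] = int((obs_until >= t).sum())
    return SimTruth(
        users=users, blocks=blocks, engaged=engaged_count,
        spells=spells, alpha=alpha, beta=beta,
    )


def _head_size(config: GeneratorConfig, rng: np.random.Generator) -> int:
    if config.head_size_dist == "geometric":
        h = int(rng.geometric(1.0 / config.head_size_mean))
    elif config.head_size_dist == "powerlaw":
        # discrete truncated power law via inverse-CDF on a Pareto draw
        h = int(np.floor(rng.pareto(config.head_powerlaw_exponent - 1.0)) + 1)
    else:
        raise ValueError(f"unknown head size distribution {config.head_size_dist!r}")
    return min(h, config.head_size_max)


def _sample_head(
    rng: np.random.Generator,
    poster: int,
    size: int,
    mixing_row: np.ndarray,
    users_by_block: list,
) -> list:
    counts = rng.multinomial(size, mixing_row)
    head: list[int] = []
    for b, cnt in enumerate(counts):
        if cnt == 0:
            continue
        pool = users_by_block[b]
        pool = pool[pool != poster]
        cnt = min(cnt, pool.size)
        if cnt:
            head.extend(rng.choice(pool, size=cnt, replace=False).tolist())
    return head


def simulate_cascades(
    config: GeneratorConfig,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> list:
    """Emit the full event stream implied by the config and planted truth.

    Per day: category posts from engagement spells (or per-block category
    rates), heartbeat and background originals, and retweet cascades whose
    head users are drawn from blocks via the (category/period-specific)
    mixing matrix, with geometric head sizes.  Output is sorted by day and
    valid input for :func:`infoflow.ingest.read_events`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = config.n_users
    users = truth.users
    blocks = truth.blocks
    k = blocks.max() + 1
    users_by_block = [np.flatnonzero(blocks == b) for b in range(k)]
    mixing = config.resolved_mixing()
    cat_mixing = (
        np.asarray(config.category_mixing, dtype=float) if len(config.category_mixing) else mixing
    )
    n_blocks_tags = max(1, k)
    tag_slices = [list(config.hashtags)[b::n_blocks_tags] for b in range(n_blocks_tags)]

    cat_posters_by_day: dict[int, list] = {}
    if config.block_category_rate is not None:
        rates = np.asarray(config.block_category_rate, dtype=float)[blocks]
        for t in range(config.n_days):
            drawn = np.flatnonzero(rng.random(n) < rates)
            cat_posters_by_day[t] = drawn.tolist()
    else:
        for (u, start, post_until, _obs) in truth.spells:
            for d in range(start, min(post_until, config.n_days - 1) + 1):
                cat_posters_by_day.setdefault(d, []).append(u)

    def _mixing_at(t: int) -> np.ndarray:
        if config.period_breaks and len(config.period_mixing):
            pi = int(np.searchsorted(np.asarray(config.period_breaks), t, side="right"))
            if pi < len(config.period_mixing):
                return np.asarray(config.period_mixing[pi], dtype=float)
        return mixing

    def _hashtag(u: int) -> list:
        if not config.hashtags or rng.random() >= config.hashtag_prob:
            return []
        b = blocks[u]
        weights = np.ones(len(config.hashtags))
        own = tag_slices[b % n_blocks_tags]
        for i, tag in enumerate(config.hashtags):
            if tag in own:
                weights[i] = config.hashtag_bias
        weights /= weights.sum()
        return [config.hashtags[rng.choice(len(config.hashtags), p=weights)]]

    events: list[TweetEvent] = []
    next_id = 0

    def _emit(user_idx: int, day: int, urls, hashtags, root: str | None = None) -> str:
        nonlocal next_id
        tid = f"t{next_id:08d}"
        next_id += 1
        events.append(
            TweetEvent(
                tweet_id=tid,
                user_id=users[user_idx],
                day=day,
                is_retweet=root is not None,
                root_tweet_id=root if root is not None else tid,
                urls=frozenset(urls),
                hashtags=frozenset(hashtags),
            )
        )
        return tid

    def _cascade(poster: int, day: int, urls, hashtags, mix: np.ndarray) -> None:
        root = _emit(poster, day, urls, hashtags)
        size = _head_size(config, rng)
        for u in sorted(_sample_head(rng, poster, size, mix[blocks[poster]], users_by_block)):
            _emit(int(u), day, urls, hashtags, root=root)

    for t in range(config.n_days):
        # category content
        for u in sorted(set(cat_posters_by_day.get(t, []))):
            url = config.category_domains[int(blocks[u]) % len(config.category_domains)]
            tags = _hashtag(u)
            if config.category_retweets:
                _cascade(u, t, [url], tags, cat_mixing)
            else:
                _emit(u, t, [url], tags)
        # heartbeat originals keep every user active within each tau window
        if config.heartbeat:
            for u in range(n):
                if t % config.tau == u % config.tau:
                    _emit(u, t, [], [])
        # background originals, optionally with media URLs and cascades
        mix_t = _mixing_at(t)
        for u in np.flatnonzero(rng.random(n) < config.tweet_rate):
            urls = (
                [config.media_domains[int(blocks[u]) % len(config.media_domains)]]
                if rng.random() < config.media_url_prob
                else []
            )
            tags = _hashtag(int(u))
            if config.media_retweets:
                _cascade(int(u), t, urls, tags, mix_t)
            else:
                _emit(int(u), t, urls, tags)
    events.sort(key=lambda e: e.day)
    return events


def simulate(config: GeneratorConfig, seed: int | None = None) -> SimulationResult:
    """Run engagement then cascade emission with one seeded generator."""
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    truth = simulate_engagement(config, rng)
    events = simulate_cascades(config, truth, rng)
    return SimulationResult(events=events, truth=truth)


def default_catalog(config: GeneratorConfig) -> UrlCatalog:
    """Catalog classifying the generator's URL pools."""
    return UrlCatalog.from_seeds(
        vaccine_critical=config.category_domains, media=config.media_domains
    )


# ---------------------------------------------------------------------------
# Scenario factories (study conditions used across tests and examples)
# ---------------------------------------------------------------------------

def rate_recovery_config(seed: int = 0) -> GeneratorConfig:
    """Constant-rate SIS stream for estimator round trips (R* = 3)."""
    return GeneratorConfig(
        n_users=2000, alpha=0.3, beta=0.1, tau=3, n_days=100,
        n_seed_engaged=10, seed=seed,
    )


def spike_config(spike_day: int = 50, seed: int = 0) -> GeneratorConfig:
    """Low-baseline stream with a single Gaussian contact-rate spike."""
    days = np.arange(100)
    alpha = 0.08 + 0.85 * np.exp(-((days - spike_day) ** 2) / (2 * 2.0**2))
    return GeneratorConfig(
        n_users=2000, alpha=tuple(alpha), beta=0.1, tau=3, n_days=100,
        n_seed_engaged=150, seed=seed,
    )


def planted_partition_config(
    n_users: int = 1000, n_blocks: int = 4, n_days: int = 30, seed: int = 0
) -> GeneratorConfig:
    """Strongly assortative blocks with media cascades only (no SIS)."""
    sizes = [n_users // n_blocks] * n_blocks
    sizes[-1] += n_users - sum(sizes)
    m = np.full((n_blocks, n_blocks), 0.15 / (n_blocks - 1))
    np.fill_diagonal(m, 0.85)
    return GeneratorConfig(
        n_users=n_users, block_sizes=tuple(sizes),
        mixing=tuple(map(tuple, m)), tweet_rate=0.2, media_url_prob=1.0,
        alpha=0.0, n_seed_engaged=0, n_days=n_days, seed=seed,
    )


def echo_spreader_config(n_days: int = 40, seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """Echo-chamber block vs spreader block vs audience.

    The echo block adopts category content heavily and recirculates it
    internally while absorbing the audience's category posts; the spreader
    block adopts rarely but its category cascades land mostly outside.
    Media mixing is mildly reversed (echo more outward), so the category
    contrast is content-specific rather than purely topological.
    """
    sizes = (int(80 * scale), int(80 * scale), int(140 * scale))
    return GeneratorConfig(
        n_users=sum(sizes), block_sizes=sizes,
        mixing=((0.20, 0.20, 0.60), (0.20, 0.40, 0.40), (0.30, 0.30, 0.40)),
        category_mixing=((0.90, 0.02, 0.08), (0.10, 0.10, 0.80), (0.60, 0.10, 0.30)),
        block_category_rate=(0.30, 0.05, 0.05),
        category_retweets=True,
        tweet_rate=0.2, media_url_prob=0.9,
        alpha=0.0, n_seed_engaged=0, n_days=n_days, seed=seed,
    )


# ---------------------------------------------------------------------------
# Micro-fixture suite
# ---------------------------------------------------------------------------

def _micro_two_cycle() -> list:
    return [
        TweetEvent("t0", "A", 0, False, "t0"),
        TweetEvent("t1", "B", 0, True, "t0"),
        TweetEvent("t2", "B", 1, False, "t2"),
        TweetEvent("t3", "A", 1, True, "t2"),
    ]


def _micro_star() -> list:
    """Two cascades from A: heads {B, C} and {B}; T[A->B]=3/4, T[A->C]=1/4."""
    return [
        TweetEvent("t0", "A", 0, False, "t0"),
        TweetEvent("t1", "B", 0, True, "t0"),
        TweetEvent("t2", "C", 0, True, "t0"),
        TweetEvent("t3", "A", 1, False, "t3"),
        TweetEvent("t4", "B", 1, True, "t3"),
    ]


def _micro_two_clique() -> list:
    """Two 5-node groups of mutual retweeters joined by one weak cascade."""
    events = []
    tid = 0
    groups = [["a0", "a1", "a2", "a3", "a4"], ["b0", "b1", "b2", "b3", "b4"]]
    for g in groups:
        for day, poster in enumerate(g):
            root = f"t{tid}"
            events.append(TweetEvent(root, poster, day, False, root))
            tid += 1
            for other in g:
                if other != poster:
                    events.append(TweetEvent(f"t{tid}", other, day, True, root))
                    tid += 1
    root = f"t{tid}"
    events.append(TweetEvent(root, "a0", 5, False, root))
    events.append(TweetEvent(f"t{tid + 1}", "b0", 5, True, root))
    return events


def make_fixture_suite(seed: int, out_dir) -> dict:
    """Write the named micro-fixtures plus a manifest of expected values.

    Deterministic: the same seed yields byte-identical files.  Returns the
    manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    files = {}

    def _write(name: str, events) -> None:
        write_events(events, out / name)
        files[name.split(".")[0]] = name

    _write("two_cycle.jsonl", _micro_two_cycle())
    _write("star_cascade.jsonl", _micro_star())
    _write("two_clique.jsonl", _micro_two_clique())

    planted = simulate(planted_partition_config(n_users=40, n_days=10, seed=seed))
    _write("planted_blocks.jsonl", planted.events)
    planted_labels = {u: int(b) for u, b in zip(planted.truth.users, planted.truth.blocks)}

    echo_cfg = echo_spreader_config(n_days=12, seed=seed, scale=0.25)
    echo = simulate(echo_cfg)
    _write("echo_spreader.jsonl", echo.events)
    default_catalog(echo_cfg).to_csv(out / "echo_spreader_catalog.csv")
    files["echo_spreader_catalog"] = "echo_spreader_catalog.csv"

    manifest = {
        "seed": seed,
        "provenance": "synthetic",
        "files": files,
        "expected": {
            "star_cascade_transitions": {"A->B": 0.75, "A->C": 0.25},
            "two_cycle_stationary": {"A": 0.5, "B": 0.5},
            "two_clique_n_communities": 2,
            "planted_blocks_labels": planted_labels,
            "echo_spreader_blocks": {
                u: int(b) for u, b in zip(echo.truth.users, echo.truth.blocks)
            },
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
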