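import numpy as np
import pytest

from infoflow import (
    GeneratorConfig,
    TweetEvent,
    build_hypergraph,
    simulate,
)
from infoflow.synthetic import (
    _micro_star,
    _micro_two_clique,
    _micro_two_cycle,
    echo_spreader_config,
    planted_partition_config,
    rate_recovery_config,
)


def ev(tweet_id, user, day, root=None, urls=(), tags=()):
    """Shorthand event constructor for fixtures."""
    return TweetEvent(
        tweet_id=str(tweet_id),
        user_id=str(user),
        day=day,
        is_retweet=root is not None,
        root_tweet_id=str(root) if root is not None else str(tweet_id),
        urls=frozenset(urls),
        hashtags=frozenset(tags),
    )


@pytest.fixture
def star_events():
    return _micro_star()


@pytest.fixture
def two_cycle_events():
    return _micro_two_cycle()


@pytest.fixture
def two_clique_events():
    return _micro_two_clique()


@pytest.fixture(scope="session")
def rate_recovery_sim():
    """The constant-rate SIS stream (2000 users, alpha .3, beta .1, 100 d)."""
    return simulate(rate_recovery_config(seed=11))


@pytest.fixture(scope="session")
def planted_sim_small():
    return simulate(planted_partition_config(n_users=200, n_days=25, seed=7))


@pytest.fixture(scope="session")
def echo_sim_small():
    cfg = echo_spreader_config(n_days=25, seed=5, scale=0.5)
    return cfg, simulate(cfg)


def category_events_of(result, config=None):
    pool = set((config or GeneratorConfig()).category_domains)
    return [e for e in result.events if e.urls & pool]
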