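"""Reading and normalizing tweet event streams and URL source catalogs.

The raw analysis unit is a *posting*: an original tweet or a retweet, at
daily resolution, carrying a set of URL domains and a set of hashtags.
Event streams are line-delimited JSON or CSV.  URL sources are classified
into content categories (vaccine-critical, news media) via a two-column
catalog that can be extended by 1-hop dilation on the user co-occurrence
network of domains.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Recognised content categories for URL domains.
CATEGORIES = ("vaccine_critical", "media")

_LIST_SEP = "|"  # separator for multi-valued CSV cells


def parse_day(value) -> int:
    """Convert a day field to an integer day index.

    Integers (or digit strings) pass through; ISO dates (``YYYY-MM-DD``,
    optionally with a time suffix) map to the proleptic Gregorian ordinal,
    so date-labelled and integer-labelled streams share one arithmetic.
    """
    if isinstance(value, bool):
        raise ValueError(f"not a day: {value!r}")
    if isinstance(value, int):
        return value
    s = str(value).strip()
    if s.lstrip("-").isdigit():
        return int(s)
    return date.fromisoformat(s[:10]).toordinal()


def day_to_date(day: int) -> date:
    """Inverse of :func:`parse_day` for ordinal day indices."""
    return date.fromordinal(day)


def normalize_url(url: str) -> str:
    """Reduce a URL to its bare, lower-cased domain.

    Strips the scheme, credentials, port, path, query and a leading
    ``www.`` so that e.g. ``https://www.Example.org/p?q=1`` and
    ``example.org`` collapse to the same site-level key.
    """
    s = url.strip().lower()
    if "//" in s:
        s = s.split("//", 1)[1]
    for sep in "/?#":
        s = s.split(sep, 1)[0]
    if "@" in s:
        s = s.rsplit("@", 1)[1]
    s = s.split(":", 1)[0]
    if s.startswith("www."):
        s = s[4:]
    return s.rstrip(".")


def normalize_hashtag(tag: str) -> str:
    return tag.strip().lstrip("#").lower()


@dataclass(frozen=True)
class TweetEvent:
    """One posting: an original tweet or a retweet.

    ``root_tweet_id`` equals ``tweet_id`` for originals and points to the
    retweeted original otherwise.  ``urls`` holds normalized domains and
    ``hashtags`` lower-cased tags; both may be empty.
    """

    tweet_id: str
    user_id: str
    day: int
    is_retweet: bool
    root_tweet_id: str
    urls: frozenset = frozenset()
    hashtags: frozenset = frozenset()


def _event_from_record(rec: Mapping) -> TweetEvent:
    tweet_id = str(rec["tweet_id"])
    is_retweet = rec["is_retweet"]
    if isinstance(is_retweet, str):
        is_retweet = is_retweet.strip().lower() in ("1", "true", "yes")
    root = rec.get("root_tweet_id")
    if root in (None, ""):
        if is_retweet:
            raise ValueError("retweet without root_tweet_id")
        root = tweet_id
    urls = rec.get("urls") or ()
    hashtags = rec.get("hashtags") or ()
    if isinstance(urls, str):
        urls = [u for u in urls.split(_LIST_SEP) if u]
    if isinstance(hashtags, str):
        hashtags = [h for h in hashtags.split(_LIST_SEP) if h]
    return TweetEvent(
        tweet_id=tweet_id,
        user_id=str(rec["user_id"]),
        day=parse_day(rec["day"] if "day" in rec else rec["date"]),
        is_retweet=bool(is_retweet),
        root_tweet_id=str(root),
        urls=frozenset(normalize_url(u) for u in urls if normalize_url(u)),
        hashtags=frozenset(normalize_hashtag(h) for h in hashtags if normalize_hashtag(h)),
    )


def read_events(path) -> tuple[list[TweetEvent], int]:
    """Read an event stream file, returning ``(events, n_rejected)``.

    Events are returned sorted by day (stable within a day).  Malformed
    records are counted, logged and skipped; an unreadable file raises.
    Format is chosen by extension: ``.csv`` else line-delimited JSON.
    """
    path = Path(path)
    events: list[TweetEvent] = []
    rejected = 0
    with open(path, newline="") as fh:
        if path.suffix.lower() == ".csv":
            records: Iterable[Mapping] = csv.DictReader(fh)
            for lineno, rec in enumerate(records, start=2):
                try:
                    events.append(_event_from_record(rec))
                except Exception as exc:  # malformed record
                    rejected += 1
                    logger.warning("rejected line %d of %s: %s", lineno, path, exc)
        else:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    events.append(_event_from_record(json.loads(line)))
                except Exception as exc:
                    rejected += 1
                    logger.warning("rejected line %d of %s: %s", lineno, path, exc)
    events.sort(key=lambda e: e.day)
    if rejected:
        logger.warning("%s: rejected %d malformed record(s)", path, rejected)
    return events, rejected


def write_events(events: Sequence[TweetEvent], path) -> None:
    """Write events as line-delimited JSON (the canonical stream format)."""
    path = Path(path)
    with open(path, "w") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": e.tweet_id,
                        "user_id": e.user_id,
                        "day": e.day,
                        "is_retweet": e.is_retweet,
                        "root_tweet_id": e.root_tweet_id,
                        "urls": sorted(e.urls),
                        "hashtags": sorted(e.hashtags),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def build_url_cooccurrence(events: Sequence[TweetEvent]) -> nx.Graph:
    """Weighted undirected co-occurrence graph of URL domains.

    Two domains are connected if at least one user posted (tweeted or
    retweeted) both of them anywhere in the stream; the edge weight is the
    number of distinct users sharing both.
    """
    by_user: dict[str, set] = {}
    for e in events:
        if e.urls:
            by_user.setdefault(e.user_id, set()).update(e.urls)
    g = nx.Graph()
    for e in events:
        g.add_nodes_from(e.urls)
    for domains in by_user.values():
        for u, v in combinations(sorted(domains), 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    return g


def dilate_seed_set(graph: nx.Graph, seeds: Iterable[str]) -> set:
    """1-hop dilation: the seed set plus all its graph neighbours.

    Seeds absent from the graph pass through unchanged.  No edge-weight
    threshold is applied.
    """
    seeds = set(seeds)
    out = set(seeds)
    for s in seeds:
        if s in graph:
            out.update(graph.neighbors(s))
    return out


@dataclass
class UrlCatalog:
    """Domain -> category map with seed/dilated provenance.

    Categories are disjoint by construction (one entry per domain); seed
    domains keep their seed category when dilated candidates are merged in.
    """

    categories: dict = field(default_factory=dict)  # domain -> category
    provenance: dict = field(default_factory=dict)  # domain -> "seed" | "dilated"

    @classmethod
    def from_seeds(cls, vaccine_critical: Iterable[str] = (), media: Iterable[str] = ()) -> "UrlCatalog":
        cat = cls()
        for d in vaccine_critical:
            cat.add(d, "vaccine_critical", "seed")
        for d in media:
            cat.add(d, "media", "seed")
        return cat

    @classmethod
    def from_csv(cls, path) -> "UrlCatalog":
        """Load a (domain, category[, provenance]) CSV, header optional."""
        cat = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() == "domain":
                    continue
                domain = normalize_url(row[0])
                category = row[1].strip()
                prov = row[2].strip() if len(row) > 2 and row[2].strip() else "seed"
                cat.add(domain, category, prov)
        return cat

    def add(self, domain: str, category: str, provenance: str = "seed") -> None:
        if category not in CATEGORIES and category != "unclassified":
            raise ValueError(f"unknown category {category!r}")
        domain = normalize_url(domain)
        if self.provenance.get(domain) == "seed" and provenance == "dilated":
            return  # seeds keep their seed category
        self.categories[domain] = category
        self.provenance[domain] = provenance

    def domains(self, category: str) -> set:
        if category not in CATEGORIES and category != "unclassified":
            raise ValueError(f"unknown category {category!r}")
        return {d for d, c in self.categories.items() if c == category}

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["domain", "category", "provenance"])
            for d in sorted(self.categories):
                w.writerow([d, self.categories[d], self.provenance.get(d, "seed")])


def classify_events(
    events: Sequence[TweetEvent], catalog: UrlCatalog, category: str
) -> list[TweetEvent]:
    """Events whose URL set intersects the requested catalog category.

    An event carrying URLs of both categories appears in both restricted
    selections.  Events without URLs are never selected.
    """
    domains = catalog.domains(category)  # raises on unknown category
    return [e for e in events if e.urls & domains]
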