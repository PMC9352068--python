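"""Sliding-window engagement dynamics of a content category.

A user is *engaged* at day t if they posted or reshared a link of the
tracked category within the trailing window (t - tau, t]; an *active* user
posted anything in that window.  Treating engaged users as the infectious
compartment of an SIS process, the daily inflow of newly engaged users and
outflow of disengaging users invert to a time-varying contact rate
``alpha_t``, a loss-of-interest rate ``beta_t`` and their ratio, the
reproduction number ``R_t = alpha_t / beta_t``: values above 1 mean the
engaged population grows by contact.

Rates are inverted with predecessor states (exposure at t-1 drives the
transition at t)::

    alpha_t = dE+_t * N_{t-1} / (E_{t-1} * (N_{t-1} - E_{t-1}))
    beta_t  = dE-_t / E_{t-1}

Days where the inversion is undefined (E=0, or E=N for alpha) carry NaN,
never a fabricated zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ingest import TweetEvent

DEFAULT_TAU = 3  # days; short windows track the fast pace of the platform


def _user_days(events: Sequence[TweetEvent]) -> dict:
    out: dict[str, set] = {}
    for e in events:
        out.setdefault(e.user_id, set()).add(e.day)
    return out


def _intervals(days: set, tau: int) -> list[tuple[int, int]]:
    """Merge posting days into maximal closed engagement intervals.

    A post at day d keeps the user in-state for days d .. d+tau-1; posts
    closer than tau days chain into one interval.
    """
    merged: list[list[int]] = []
    for d in sorted(days):
        end = d + tau - 1
        if merged and d <= merged[-1][1] + 1:
            if end > merged[-1][1]:
                merged[-1][1] = end
        else:
            merged.append([d, end])
    return [(a, b) for a, b in merged]


def state_counts(
    events: Sequence[TweetEvent],
    category_events: Sequence[TweetEvent],
    tau: int = DEFAULT_TAU,
    day_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Daily engagement bookkeeping over the stream's day range.

    Returns a frame indexed by day with columns ``E`` (engaged users),
    ``N`` (active users), ``dE_plus`` (uncommitted->engaged transitions)
    and ``dE_minus`` (engaged->uncommitted transitions).  The conservation
    identity ``E_t - E_{t-1} = dE_plus_t - dE_minus_t`` holds exactly.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if day_range is None:
        if not events:
            return pd.DataFrame(
                columns=["E", "N", "dE_plus", "dE_minus"], index=pd.Index([], name="day")
            )
        day_range = (min(e.day for e in events), max(e.day for e in events))
    lo, hi = day_range
    n_days = hi - lo + 1
    e_diff = np.zeros(n_days + 1, dtype=np.int64)
    n_diff = np.zeros(n_days + 1, dtype=np.int64)
    inflow = np.zeros(n_days, dtype=np.int64)
    outflow = np.zeros(n_days, dtype=np.int64)

    def _accumulate(days_by_user, diff, flows):
        for days in days_by_user.values():
            for a, b in _intervals(days, tau):
                a_c = max(a, lo)
                b_c = min(b, hi)
                if a_c > b_c:
                    continue
                diff[a_c - lo] += 1
                diff[b_c - lo + 1] -= 1
                if flows is not None:
                    if a >= lo:
                        flows[0][a - lo] += 1
                    if b + 1 <= hi:
                        flows[1][b + 1 - lo] += 1

    _accumulate(_user_days(category_events), e_diff, (inflow, outflow))
    _accumulate(_user_days(events), n_diff, None)
    frame = pd.DataFrame(
        {
            "E": np.cumsum(e_diff[:-1]),
            "N": np.cumsum(n_diff[:-1]),
            "dE_plus": inflow,
            "dE_minus": outflow,
        },
        index=pd.RangeIndex(lo, hi + 1, name="day"),
    )
    return frame


def engagement_states(
    events: Sequence[TweetEvent],
    category_events: Sequence[TweetEvent],
    tau: int,
    t: int,
) -> tuple[int, int]:
    """(E_t, N_t) at a single day; (0, 0) before the stream starts."""
    if not events:
        return (0, 0)
    lo = min(e.day for e in events)
    if t < lo:
        return (0, 0)
    frame = state_counts(events, category_events, tau, (lo, t))
    row = frame.loc[t]
    return int(row["E"]), int(row["N"])


def flows(engaged_sets: Sequence[set]) -> tuple[np.ndarray, np.ndarray]:
    """Daily in/out transition counts from a sequence of engaged-user sets.

    ``dE_plus[t]`` counts users present at t but not t-1; ``dE_minus[t]``
    the reverse.  Day 0 has zero flows by convention (no predecessor).
    """
    n = len(engaged_sets)
    de_plus = np.zeros(n, dtype=np.int64)
    de_minus = np.zeros(n, dtype=np.int64)
    for t in range(1, n):
        de_plus[t] = len(engaged_sets[t] - engaged_sets[t - 1])
        de_minus[t] = len(engaged_sets[t - 1] - engaged_sets[t])
    return de_plus, de_minus


def estimate_rates(series: pd.DataFrame) -> pd.DataFrame:
    """Add ``alpha`` and ``beta`` columns by inverting the SIS flow model.

    Uses predecessor states; undefined days (E_{t-1}=0 for beta, or
    E_{t-1} in {0, N_{t-1}} for alpha, and the first day) are NaN.
    """
    out = series.copy()
    E0 = out["E"].shift(1)
    N0 = out["N"].shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = out["dE_plus"] * N0 / (E0 * (N0 - E0))
        beta = out["dE_minus"] / E0
    alpha[(E0 <= 0) | (E0 >= N0)] = np.nan
    beta[E0 <= 0] = np.nan
    out["alpha"] = alpha
    out["beta"] = beta
    return out


def reproduction_number(alpha, beta):
    """R = alpha / beta with NaN propagation; beta = 0 yields NaN."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = alpha / beta
    r = np.where(beta == 0, np.nan, r)
    return r


def engagement_series(
    events: Sequence[TweetEvent],
    category_events: Sequence[TweetEvent],
    tau: int = DEFAULT_TAU,
    day_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Full engagement table: states, flows, rates and R per day."""
    frame = state_counts(events, category_events, tau, day_range)
    frame = estimate_rates(frame)
    frame["R"] = reproduction_number(frame["alpha"], frame["beta"])
    return frame


def detect_engagement_events(
    r: pd.Series | Sequence[float],
    days: Sequence[int] | None = None,
    smooth_window: int = 7,
    quantile: float = 0.90,
    min_separation: int = 7,
    max_gap: int = 2,
) -> pd.DataFrame:
    """Peak days of a (noisy, gappy) R_t series.

    The series is linearly interpolated across gaps of at most ``max_gap``
    days, smoothed with a centered rolling median of ``smooth_window``
    days, and local maxima above the ``quantile`` level of the smoothed
    series are returned; peaks closer than ``min_separation`` days keep
    only the higher one.  Deterministic given the configuration.
    """
    if isinstance(r, pd.Series):
        s = r.astype(float)
    else:
        idx = pd.Index(days) if days is not None else pd.RangeIndex(len(r))
        s = pd.Series(np.asarray(r, dtype=float), index=idx)
    if s.empty or s.isna().all():
        return pd.DataFrame(columns=["day", "R"]).set_index("day")
    filled = s.interpolate(limit=max_gap, limit_area="inside")
    sm = filled.rolling(smooth_window, center=True, min_periods=max(1, smooth_window // 2)).median()
    if sm.isna().all():
        return pd.DataFrame(columns=["day", "R"]).set_index("day")
    level = np.nanquantile(sm.to_numpy(), quantile)
    values = sm.fillna(-np.inf).to_numpy()
    peaks, _ = find_peaks(values, height=level, distance=max(1, min_separation))
    return pd.DataFrame({"day": sm.index[peaks], "R": values[peaks]}).set_index("day")
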