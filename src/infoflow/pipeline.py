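"""End-to-end orchestration: events in, analysis tables out.

``run_all`` chains ingest -> engagement (per content category) ->
hypergraph -> community detection -> restricted/per-period flow ->
content profiles, writing every table as CSV into the output directory
together with the fully resolved configuration, so a run is reproducible
from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import communities as cm
from . import engagement as eng
from . import hypergraph as hg
from . import profiles as pr
from .ingest import CATEGORIES, UrlCatalog, classify_events, parse_day, read_events

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated, serializable configuration of a full pipeline run."""

    events_path: str = ""
    catalog_path: str = ""
    out_dir: str = "infoflow_out"
    tau: int = 3
    damping: float = 0.85
    resolution: float = 1.0
    seed: int = 0
    # default period breakpoints: Pfizer announcement / health-pass debate
    breakpoints: list = field(default_factory=lambda: ["2020-11-11", "2021-06-01"])
    top_items: int = 50
    top_communities: int = 50
    n_hashtag_groups: int = 7
    n_url_groups: int = 2
    peak_smooth_window: int = 7
    peak_quantile: float = 0.90
    peak_min_separation: int = 7

    def validate(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must be in (0, 1]")
        if not 0 < self.peak_quantile < 1:
            raise ValueError("peak_quantile must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _resolve_breakpoints(breakpoints, lo: int, hi: int) -> list:
    days = [parse_day(b) for b in breakpoints]
    inside = [d for d in days if lo < d <= hi]
    if days and not inside:
        logger.warning(
            "all breakpoints fall outside the stream range [%d, %d]; single period", lo, hi
        )
    return sorted(inside)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of output paths and key counts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"outputs": {}}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("ingest")
        events, rejected = read_events(config.events_path)
        if not events:
            raise ValueError("event stream is empty")
        catalog = UrlCatalog.from_csv(config.catalog_path)
        report["n_events"] = len(events)
        report["n_rejected"] = rejected
        by_category = {c: classify_events(events, catalog, c) for c in CATEGORIES}
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    lo = min(e.day for e in events)
    hi = max(e.day for e in events)
    breakpoints = _resolve_breakpoints(config.breakpoints, lo, hi)

    try:
        _stage("engagement")
        share_rows = []
        for cat, cat_events in by_category.items():
            series = eng.engagement_series(events, cat_events, tau=config.tau)
            series.to_csv(out / f"engagement_{cat}.csv")
            report["outputs"][f"engagement_{cat}"] = f"engagement_{cat}.csv"
            peaks = eng.detect_engagement_events(
                series["R"],
                smooth_window=config.peak_smooth_window,
                quantile=config.peak_quantile,
                min_separation=config.peak_min_separation,
            )
            peaks.to_csv(out / f"peaks_{cat}.csv")
            report["outputs"][f"peaks_{cat}"] = f"peaks_{cat}.csv"
        # daily share of events carrying a category URL (content volume view)
        total = pd.Series(0, index=pd.RangeIndex(lo, hi + 1, name="day"), dtype=int)
        for e in events:
            total[e.day] += 1
        share = pd.DataFrame({"n_events": total})
        for cat, cat_events in by_category.items():
            cnt = pd.Series(0, index=total.index, dtype=int)
            for e in cat_events:
                cnt[e.day] += 1
            share[f"share_{cat}"] = cnt / total.replace(0, np.nan)
        share.to_csv(out / "daily_share.csv")
        report["outputs"]["daily_share"] = "daily_share.csv"
    except Exception as exc:
        raise PipelineError("engagement", exc) from exc

    try:
        _stage("hypergraph")
        H = hg.build_hypergraph(events)
        flow = hg.compute_flow(H, damping=config.damping)
        report["n_nodes"] = H.n_nodes
        report["n_cascades"] = H.n_edges
    except Exception as exc:
        raise PipelineError("hypergraph", exc) from exc

    try:
        _stage("communities")
        labels = cm.detect_communities(flow, resolution=config.resolution, seed=config.seed)
        partition = cm.partition_dict(H, labels)
        pd.DataFrame(
            {"user_id": H.nodes, "community": labels}
        ).to_csv(out / "partition.csv", index=False)
        report["outputs"]["partition"] = "partition.csv"
        report["n_communities"] = int(labels.max() + 1)
    except Exception as exc:
        raise PipelineError("communities", exc) from exc

    try:
        _stage("flow")
        summary = cm.per_period_flow(
            events, breakpoints, partition, catalog, damping=config.damping
        )
        summary.to_csv(out / "flow_summary.csv", index=False)
        report["outputs"]["flow_summary"] = "flow_summary.csv"
    except Exception as exc:
        raise PipelineError("flow", exc) from exc

    try:
        _stage("profiles")
        joint, p_i, p_a = pr.joint_usage(
            events, partition, item_kind="hashtag",
            top_items=config.top_items, top_communities=config.top_communities,
        )
        xi = pr.overusage(joint, p_i, p_a)
        pr.xi_long(xi).to_csv(out / "xi_hashtags.csv", index=False)
        report["outputs"]["xi_hashtags"] = "xi_hashtags.csv"
        groups = pr.cocluster(
            xi,
            n_row_groups=min(config.n_hashtag_groups, xi.shape[0]),
            n_col_groups=min(config.n_hashtag_groups, xi.shape[1]),
        )
        (out / "hashtag_communities.nwk").write_text(
            pr.linkage_to_newick(groups.row_linkage, [str(i) for i in xi.index])
        )
        report["outputs"]["hashtag_dendrogram"] = "hashtag_communities.nwk"
        critical = by_category["vaccine_critical"]
        if critical:
            joint_u, pi_u, pa_u = pr.joint_usage(
                critical, partition, item_kind="url",
                top_items=config.top_items, top_communities=config.top_communities,
            )
            xi_u = pr.overusage(joint_u, pi_u, pa_u)
            pr.xi_long(xi_u).to_csv(out / "xi_urls.csv", index=False)
            report["outputs"]["xi_urls"] = "xi_urls.csv"
    except Exception as exc:
        raise PipelineError("profiles", exc) from exc

    # period volumes
    edges = [lo] + breakpoints + [hi + 1]
    volumes = []
    for pi in range(len(edges) - 1):
        a, b = edges[pi], edges[pi + 1]
        volumes.append(
            {
                "period": pi,
                "start_day": a,
                "end_day": b - 1,
                "n_events": sum(1 for e in events if a <= e.day < b),
            }
        )
    report["period_volumes"] = volumes
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    report["outputs"]["summary"] = "summary.json"
    return report
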