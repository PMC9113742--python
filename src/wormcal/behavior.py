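"""Swimming fatigue metrics from bend/curl event tables.

Worms swimming in buffer are scored by eye for body bends and curling
events over a fixed window; the curl fraction (curls/bends, as a percent)
is the fatigue metric.  Curl events are inputs — scored upstream or
generated synthetically — not detected from video here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BehaviorRecord", "CurlSummary", "summarize_behavior", "group_behavior"]


@dataclass
class BehaviorRecord:
    """One worm's scored swimming events over an observation window."""

    worm_id: str
    group: str
    bends: int
    curls: int
    minutes: float

    def __post_init__(self) -> None:
        if self.bends < 0 or self.curls < 0:
            raise ValueError("counts must be >= 0")
        if self.minutes <= 0:
            raise ValueError("minutes must be > 0")


@dataclass
class CurlSummary:
    """Per-worm rates: bends/min and curl percentage (100 * curls / bends)."""

    bends_per_min: float
    curl_pct: float              # nan when undefined (no bends)
    undefined: bool = False      # True when bends == 0
    miscount: bool = False       # True when curls > bends (scoring slip)


def summarize_behavior(record: BehaviorRecord) -> CurlSummary:
    """Bend rate and curl percentage of a single worm.

    A worm with zero bends has an undefined curl percentage and is flagged
    rather than erroring; curls exceeding bends are flagged as a miscount
    but still summarised.
    """
    bends_per_min = record.bends / record.minutes
    if record.bends == 0:
        return CurlSummary(bends_per_min, float("nan"), undefined=True)
    return CurlSummary(
        bends_per_min,
        100.0 * record.curls / record.bends,
        miscount=record.curls > record.bends,
    )


def group_behavior(records: pd.DataFrame, value: str = "curl_pct",
                   alpha: float = 0.05) -> dict:
    """Per-group mean ± SEM of a behaviour metric, with the omnibus test.

    ``records`` needs columns worm_id, group, bends, curls, minutes.  Two
    groups are compared by unpaired two-tailed Student t; three or more by
    one-way ANOVA with Tukey–Kramer pairwise comparisons.  The pooled-count
    curl percentage per group is reported alongside the primary
    per-worm-then-average value.
    """
    from .stats import one_way_anova, t_test, tukey_kramer

    required = {"worm_id", "group", "bends", "curls", "minutes"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    df = records.copy()
    df["bends_per_min"] = df["bends"] / df["minutes"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["curl_pct"] = 100.0 * df["curls"] / df["bends"]
    if value not in ("curl_pct", "bends_per_min"):
        raise ValueError("value must be 'curl_pct' or 'bends_per_min'")

    groups: dict[str, np.ndarray] = {}
    summary = {}
    for name, sub in df.groupby("group", sort=True):
        vals = sub[value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"group {name!r} has no usable records")
        groups[name] = vals
        summary[name] = {
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan"),
            "pooled_curl_pct": float(100.0 * sub["curls"].sum() / sub["bends"].sum())
            if sub["bends"].sum() > 0 else float("nan"),
        }
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups to compare")
    result = {"metric": value, "groups": summary}
    if len(names) == 2:
        t, p = t_test(groups[names[0]], groups[names[1]])
        result["test"] = {"name": "student_t", "statistic": t, "p_value": p}
    else:
        f, p = one_way_anova(list(groups.values()))
        pairs = tukey_kramer(list(groups.values()), alpha=alpha)
        result["test"] = {"name": "one_way_anova", "statistic": f, "p_value": p}
        result["tukey"] = [
            {"pair": (names[i], names[j]), "p_adj": padj, "significant": sig}
            for (i, j, padj, sig) in pairs
        ]
    return result
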