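"""Study-level aggregation: scenario / driver / group tallies, printed
percentages, and the sensitivity filters.

Pooling vocabulary: "tetrapods" = mammals + birds + squamates + amphibians;
"endotherms" = mammals + birds; "ectotherms" = squamates + amphibians.
Percentages are rounded half-up at the displayed precision and always
emitted next to the raw counts they summarize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .battery import DRIVER_OF, SelectionTable

__all__ = [
    "percent",
    "aggregate_counts",
    "sensitivity_filter",
    "tally_second_best",
    "StudySummary",
]

TETRAPODS = ("mammal", "bird", "squamate", "amphibian")
ENDOTHERMS = ("mammal", "bird")
ECTOTHERMS = ("squamate", "amphibian")


def percent(count: int, total: int, digits: int = 0) -> float:
    """100 * count / total, rounded half-up to ``digits`` decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= count <= total):
        raise ValueError("need 0 <= count <= total")
    q = Decimal(1).scaleb(-digits)
    val = (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(val)


@dataclass
class StudySummary:
    """Counts and cross-tabulations for one (possibly filtered) study."""

    n_clades: int
    by_scenario: pd.Series
    by_driver: pd.Series
    scenario_by_group: pd.DataFrame
    scenario_by_pool: pd.DataFrame
    scenario_by_cluster: pd.DataFrame | None
    unclassified: list[str] = field(default_factory=list)

    def percent_of(self, margin: str, key, digits: int = 0) -> float:
        series = {"scenario": self.by_scenario, "driver": self.by_driver}[margin]
        return percent(int(series.get(key, 0)), self.n_clades, digits)


def _pool(group: str) -> str:
    return "plant" if group == "plant" else "tetrapod"


def aggregate_counts(
    calls: dict[str, object],
    records: list,
    clusters: dict[str, object] | None = None,
    drivers: dict[str, str] | None = None,
) -> StudySummary:
    """Tabulate scenario calls against taxon groups, pooled groups,
    bioregion clusters and driver classes.

    Clades present in ``records`` but missing a call are reported in an
    ``unclassified`` bucket, never dropped silently.
    """
    recs = {r.clade_id: r for r in records}
    unclassified = sorted(set(recs) - set(calls))
    rows = []
    for cid, call in calls.items():
        if cid not in recs:
            continue
        r = recs[cid]
        rows.append(
            {
                "clade_id": cid,
                "scenario": call.scenario,
                "group": r.taxon_group,
                "pool": _pool(r.taxon_group),
                "thermo": (
                    "plant" if r.taxon_group == "plant"
                    else "endotherm" if r.taxon_group in ENDOTHERMS else "ectotherm"
                ),
                "cluster": (clusters or {}).get(cid, "unassigned"),
                "driver": (drivers or {}).get(cid, "unknown"),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no classified clades to aggregate")
    return StudySummary(
        n_clades=len(df),
        by_scenario=df["scenario"].value_counts(),
        by_driver=df["driver"].value_counts(),
        scenario_by_group=pd.crosstab(df["scenario"], df["group"]),
        scenario_by_pool=pd.crosstab(df["scenario"], df["pool"]),
        scenario_by_cluster=(
            pd.crosstab(df["scenario"], df["cluster"]) if clusters else None
        ),
        unclassified=unclassified,
    )


def sensitivity_filter(records: list, rule: str) -> list:
    """Strict sensitivity filters: drop small (<20 tips) or poorly sampled
    (<20% of described species) clades."""
    if rule == "min_tips_20":
        return [r for r in records if r.n_sampled >= 20]
    if rule == "min_sampling_0.2":
        return [r for r in records if r.sampling_fraction >= 0.2]
    raise ValueError(f"unknown sensitivity rule {rule!r}")


def tally_second_best(tables: dict[str, SelectionTable]) -> pd.DataFrame:
    """Driver-class counts using the rank-1 and rank-2 battery winners."""
    rows = {"rank1": {}, "rank2": {}}
    for table in tables.values():
        d1 = DRIVER_OF.get(table.best_model, "other")
        rows["rank1"][d1] = rows["rank1"].get(d1, 0) + 1
        if table.second_best_model:
            d2 = DRIVER_OF.get(table.second_best_model, "other")
            rows["rank2"][d2] = rows["rank2"].get(d2, 0) + 1
    return pd.DataFrame(rows).fillna(0).astype(int)
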