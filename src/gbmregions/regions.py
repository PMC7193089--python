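"""Cluster profile summaries and rule-based region typing.

Each cluster found by the hierarchical clustering is summarized marker by
marker (median z-score, interquartile range, raw mean fraction) and
discretized into low / moderate / high — or *variable* when the spread is
too large for the marker to characterize the cluster at all.  Explicit,
editable rules then map discretized profiles onto the eight named region
types; each region type belongs to one of five upper-level
pathophysiological groups, and three of them mirror intertumoral
expression subtypes (TNReg~proneural, HPReg~proliferative,
MSReg~mesenchymal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import marker_columns
from .panel import MARKERS, UNCLASSIFIED, subtype, upper_group

__all__ = [
    "LEVELS",
    "ClusterSummary",
    "RegionTypeRule",
    "RegionCall",
    "summarize_cluster",
    "default_region_rules",
    "assign_region_type",
    "rules_to_yaml",
    "rules_from_yaml",
]

LEVELS = ("low", "moderate", "high", "variable")
_LEVEL_ORDER = {"low": 0, "moderate": 1, "high": 2}

#: Discretization thresholds on the cluster's median z-score, and the IQR
#: above which a marker is declared too variable to characterize the cluster.
LOW_Z, HIGH_Z, VARIABLE_IQR = -0.5, 0.5, 2.0


@dataclass(frozen=True)
class ClusterSummary:
    """Per-marker location/spread/level summary of one cluster."""

    cluster_id: int
    n_members: int
    median_z: dict[str, float]
    iqr: dict[str, float]
    mean_fraction: dict[str, float]
    levels: dict[str, str]
    low_confidence: bool = False  # singleton cluster


def _discretize(median: float, iqr: float) -> str:
    if iqr > VARIABLE_IQR:
        return "variable"
    if median <= LOW_Z:
        return "low"
    if median >= HIGH_Z:
        return "high"
    return "moderate"


def summarize_cluster(
    ztable: pd.DataFrame,
    assignment: dict[str, int],
    cluster_id: int,
    raw_table: pd.DataFrame | None = None,
) -> ClusterSummary:
    """Summarize one cluster of a z-scored cohort table.

    Level per marker from the member median z: <= -0.5 low, >= +0.5 high,
    else moderate; overridden to *variable* when the member IQR exceeds
    2.0.  ``raw_table`` (same rows, original fractions) supplies the raw
    mean fractions; singleton clusters are flagged low-confidence but still
    summarized.
    """
    member_ids = [r for r, c in assignment.items() if c == cluster_id]
    if not member_ids:
        raise ValueError(f"cluster {cluster_id} has no members")
    members = ztable[ztable["roi_id"].isin(member_ids)]
    raw = None
    if raw_table is not None:
        raw = raw_table[raw_table["roi_id"].isin(member_ids)]
    median_z, iqr, mean_frac, levels = {}, {}, {}, {}
    for m in marker_columns(ztable):
        vals = members[m].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            median_z[m] = np.nan
            iqr[m] = np.nan
            levels[m] = "variable"  # nothing observed: marker cannot characterize
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            median_z[m] = float(med)
            iqr[m] = float(q3 - q1)
            levels[m] = _discretize(median_z[m], iqr[m])
        if raw is not None and m in raw:
            rv = raw[m].to_numpy(dtype=float)
            rv = rv[np.isfinite(rv)]
            mean_frac[m] = float(rv.mean()) if len(rv) else np.nan
        else:
            mean_frac[m] = np.nan
    return ClusterSummary(
        cluster_id=cluster_id,
        n_members=len(members),
        median_z=median_z,
        iqr=iqr,
        mean_fraction=mean_frac,
        levels=levels,
        low_confidence=len(members) < 2,
    )


#: Admissible clause constraints on a discretized level.
CONSTRAINTS = ("low", "moderate", "high", "at-most-low", "at-most-moderate",
               "at-least-moderate", "at-least-high")


def clause_satisfied(level: str, constraint: str) -> bool:
    """Whether a discretized level satisfies a rule clause.

    A *variable* level satisfies no clause — a marker too variable to
    characterize the cluster cannot support a requirement on it.
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    if level == "variable":
        return False
    o = _LEVEL_ORDER[level]
    if constraint in _LEVEL_ORDER:
        return o == _LEVEL_ORDER[constraint]
    bound = constraint.rsplit("-", 1)[1]
    if constraint.startswith("at-most"):
        return o <= _LEVEL_ORDER[bound]
    return o >= _LEVEL_ORDER[bound]


@dataclass(frozen=True)
class RegionTypeRule:
    """Named region type defined by level constraints on markers."""

    name: str
    required: dict[str, str]  # marker -> constraint
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError(f"rule {self.name!r} has no clauses")
        unknown = set(self.required) - set(MARKERS)
        if unknown:
            raise ValueError(f"rule {self.name!r} references unknown markers {sorted(unknown)}")

    def score(self, levels: dict[str, str]) -> float:
        """Weighted fraction of satisfied clauses, in [0, 1]."""
        total = got = 0.0
        for marker, constraint in self.required.items():
            w = self.weights.get(marker, 1.0)
            total += w
            if clause_satisfied(levels[marker], constraint):
                got += w
        return got / total


def default_region_rules() -> list[RegionTypeRule]:
    """The eight region-type rules.

    Each rule encodes the qualitative marker description of its region
    type: e.g. hypoxic regions are CA-IX-high with everything else low;
    mutation regions pair strong EGFR with a low proliferation rate.
    """
    low_rest = {m: "at-most-low" for m in MARKERS}
    return [
        # ALDH1 dominance distinguishes ASReg from the GFAP-dominated ARReg
        # (and vice versa), hence the reciprocal at-most-moderate clauses.
        RegionTypeRule("ASReg", {"ALDH1": "high", "GFAP": "at-most-moderate"}),
        RegionTypeRule("HReg", {**low_rest, "CA-IX": "high"}),
        RegionTypeRule("HPReg", {
            "Mib1": "high",
            "GFAP": "at-most-low",
            "NeuN": "at-most-low",
            "Nestin": "at-most-low",
            "EGFR": "at-most-low",
            "Vimentin": "at-most-low",
        }),
        RegionTypeRule("PPReg", {
            "Mib1": "at-least-moderate",
            "Nestin": "high",
            "EGFR": "at-least-moderate",
        }),
        RegionTypeRule("TNReg", {
            "NeuN": "high",
            "MAP2": "at-least-moderate",
            "EGFR": "at-least-moderate",
            "ALDH1": "at-most-low",
            "Nestin": "at-most-low",
            "Vimentin": "at-most-low",
            "CA-IX": "at-most-low",
            "GFAP": "at-most-low",
        }),
        RegionTypeRule("MSReg", {"Nestin": "high", "Vimentin": "high"}),
        RegionTypeRule("ARReg", {"GFAP": "high", "ALDH1": "at-most-moderate"}),
        RegionTypeRule("MReg", {"EGFR": "high", "Mib1": "at-most-low"}),
    ]


@dataclass(frozen=True)
class RegionCall:
    """Assignment of one cluster to a region type, group and subtype."""

    cluster_id: int
    region_type: str
    score: float
    group: str
    subtype: str


MIN_MATCH_SCORE = 0.75


def assign_region_type(
    summary: ClusterSummary,
    rules: list[RegionTypeRule] | None = None,
    min_score: float = MIN_MATCH_SCORE,
) -> RegionCall:
    """Best-matching region type for a cluster summary.

    The highest-scoring rule with score >= ``min_score`` wins; ties break
    toward the more specific rule (more clauses), then rule order.  Below
    the floor the cluster is left *unclassified* (group/subtype "none").
    """
    rules = default_region_rules() if rules is None else rules
    if not rules:
        raise ValueError("empty rule list")
    best_rule, best_score = None, -1.0
    for rule in rules:
        s = rule.score(summary.levels)
        if s > best_score or (
            s == best_score
            and best_rule is not None
            and len(rule.required) > len(best_rule.required)
        ):
            best_rule, best_score = rule, s
    if best_score < min_score:
        return RegionCall(summary.cluster_id, UNCLASSIFIED, best_score, "none", "none")
    assert best_rule is not None
    return RegionCall(
        cluster_id=summary.cluster_id,
        region_type=best_rule.name,
        score=best_score,
        group=upper_group(best_rule.name),
        subtype=subtype(best_rule.name),
    )


def rules_to_yaml(rules: list[RegionTypeRule], path: str | Path) -> None:
    """Serialize rules as an editable YAML document."""
    doc = [
        {"name": r.name, "required": dict(r.required),
         **({"weights": dict(r.weights)} if r.weights else {})}
        for r in rules
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def rules_from_yaml(path: str | Path) -> list[RegionTypeRule]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        RegionTypeRule(d["name"], dict(d["required"]), dict(d.get("weights", {})))
        for d in doc
    ]
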