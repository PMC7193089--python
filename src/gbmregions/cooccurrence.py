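"""Per-tumor region-type composition and co-occurrence analysis.

Once every cluster has a region-type call, each tumor is described by the
set of region types among its RoIs.  The co-occurrence matrix counts, for
every pair of region types, the tumors containing both; a pair with zero
co-occurrence and adequately common members (marginal floor, default 3
tumors) is flagged as mutually exclusive.  Exclusivity here is
descriptive — observed absence, not a hypothesis test — though a Fisher
exact test is available for orientation.  Presence counts are also split
by relapse status, since some region types may be absent from pretreated
relapsing tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .panel import REGION_TYPES, UNCLASSIFIED

__all__ = [
    "TumorComposition",
    "CooccurrenceMatrix",
    "tumor_composition",
    "cooccurrence_matrix",
    "exclusivity_flags",
    "relapse_contrast",
]


@dataclass(frozen=True)
class TumorComposition:
    tumor_id: str
    relapse: bool
    region_types: frozenset[str]
    n_rois: int


def tumor_composition(
    table: pd.DataFrame,
    assignment: dict[str, int],
    calls: dict[int, str],
) -> list[TumorComposition]:
    """Region-type set per tumor from RoI cluster assignment and region calls.

    ``assignment`` maps roi_id -> cluster id, ``calls`` maps cluster id ->
    region type (possibly unclassified).  Every RoI must be covered.
    """
    out: list[TumorComposition] = []
    for tumor_id, grp in table.groupby("tumor_id", sort=True):
        types = set()
        for roi in grp["roi_id"]:
            if roi not in assignment:
                raise KeyError(f"RoI {roi!r} has no cluster assignment")
            cluster = assignment[roi]
            if cluster not in calls:
                raise KeyError(f"cluster {cluster} has no region call")
            types.add(calls[cluster])
        out.append(TumorComposition(
            tumor_id=str(tumor_id),
            relapse=bool(grp["relapse"].iloc[0]),
            region_types=frozenset(types),
            n_rois=len(grp),
        ))
    return out


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric tumor counts per region-type pair; diagonal = marginals."""

    counts: pd.DataFrame
    n_unclassified_tumors: int  # tumors containing an unclassified cluster

    def marginal(self, region_type: str) -> int:
        return int(self.counts.loc[region_type, region_type])


def cooccurrence_matrix(compositions: list[TumorComposition]) -> CooccurrenceMatrix:
    """Count tumors containing each region-type pair.

    Unclassified regions are excluded from the 8x8 matrix and reported
    separately as a tumor count.
    """
    types = list(REGION_TYPES)
    counts = pd.DataFrame(0, index=types, columns=types)
    n_unclassified = 0
    for comp in compositions:
        present = sorted(comp.region_types & set(types))
        if UNCLASSIFIED in comp.region_types:
            n_unclassified += 1
        for i, a in enumerate(present):
            for b in present[i:]:
                counts.loc[a, b] += 1
                if a != b:
                    counts.loc[b, a] += 1
    return CooccurrenceMatrix(counts=counts, n_unclassified_tumors=n_unclassified)


def exclusivity_flags(
    matrix: CooccurrenceMatrix,
    min_marginal: int = 3,
    fisher: bool = False,
    n_tumors: int | None = None,
) -> pd.DataFrame:
    """Region-type pairs never observed together in one tumor.

    A pair is flagged iff its co-count is zero and both marginals reach
    ``min_marginal`` tumors (pairs of rare types are uninformative).  With
    ``fisher=True`` (requires ``n_tumors``, the cohort size) a two-sided
    Fisher exact p-value is added per pair for orientation only.
    """
    if fisher and n_tumors is None:
        raise ValueError("fisher=True requires n_tumors (total cohort size)")
    rows = []
    types = list(REGION_TYPES)
    for i, a in enumerate(types):
        for b in types[i + 1:]:
            co = int(matrix.counts.loc[a, b])
            ma, mb = matrix.marginal(a), matrix.marginal(b)
            row = {"type_a": a, "type_b": b, "co_count": co,
                   "marginal_a": ma, "marginal_b": mb,
                   "exclusive": co == 0 and ma >= min_marginal and mb >= min_marginal}
            if fisher:
                contingency = [
                    [co, ma - co],
                    [mb - co, max(n_tumors - ma - mb + co, 0)],
                ]
                row["fisher_p"] = float(stats.fisher_exact(contingency)[1])
            rows.append(row)
    return pd.DataFrame(rows)


def relapse_contrast(compositions: list[TumorComposition]) -> pd.DataFrame:
    """Per region type: tumors containing it, split by relapse status.

    Columns ``newly_diagnosed`` and ``relapse`` count tumors where the type
    is present.
    """
    rows = []
    for t in REGION_TYPES:
        newly = sum(1 for c in compositions if t in c.region_types and not c.relapse)
        rel = sum(1 for c in compositions if t in c.region_types and c.relapse)
        rows.append({"region_type": t, "newly_diagnosed": newly, "relapse": rel})
    return pd.DataFrame(rows).set_index("region_type")
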