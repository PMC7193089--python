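"""Cluster summaries, discretization, and region-type rule assignment."""

import numpy as np
import pandas as pd
import pytest

from gbmregions.clustering import (
    complete_linkage,
    cut_tree_k,
    distance_matrix,
    zscore_columns,
)
from gbmregions.panel import MARKERS, REGION_TYPES, SUBTYPES, UPPER_GROUPS
from gbmregions.regions import (
    ClusterSummary,
    RegionTypeRule,
    assign_region_type,
    default_region_rules,
    rules_from_yaml,
    rules_to_yaml,
    summarize_cluster,
)
from gbmregions.synthetic import CohortSpec, simulate_cohort


def _summary(levels: dict[str, str]) -> ClusterSummary:
    return ClusterSummary(
        cluster_id=1, n_members=5,
        median_z={m: 0.0 for m in MARKERS},
        iqr={m: 0.5 for m in MARKERS},
        mean_fraction={m: 0.2 for m in MARKERS},
        levels=levels,
    )


class TestSummarizeCluster:
    def _ztable(self, rows: np.ndarray) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=MARKERS)
        df.insert(0, "tumor_id", "T1")
        df.insert(1, "roi_id", [f"R{i}" for i in range(len(df))])
        df.insert(2, "relapse", 0)
        return df

    def test_identical_members_have_zero_iqr_no_variable(self):
        profile = np.linspace(-1, 1, 9)
        z = self._ztable(np.tile(profile, (4, 1)))
        s = summarize_cluster(z, {f"R{i}": 1 for i in range(4)}, 1)
        assert all(v == 0.0 for v in s.iqr.values())
        assert "variable" not in s.levels.values()

    def test_hypoxia_pattern_discretizes_high_caix_rest_low(self):
        rows = np.full((4, 9), -1.0)
        rows[:, MARKERS.index("CA-IX")] = 1.5
        s = summarize_cluster(self._ztable(rows), {f"R{i}": 1 for i in range(4)}, 1)
        assert s.levels["CA-IX"] == "high"
        assert all(s.levels[m] == "low" for m in MARKERS if m != "CA-IX")

    def test_wide_spread_overrides_to_variable(self):
        # (-2, -1, 1, 2): median 0, IQR well above 2 -> variable
        rows = np.zeros((4, 9))
        rows[:, 0] = [-2, -1, 1, 2]
        s = summarize_cluster(self._ztable(rows), {f"R{i}": 1 for i in range(4)}, 1)
        assert s.median_z[MARKERS[0]] == pytest.approx(0.0)
        assert s.iqr[MARKERS[0]] > 2.0
        assert s.levels[MARKERS[0]] == "variable"

    def test_singleton_flagged_low_confidence_with_levels(self):
        rows = np.zeros((1, 9))
        s = summarize_cluster(self._ztable(rows), {"R0": 1}, 1)
        assert s.low_confidence
        assert set(s.levels.values()) <= {"low", "moderate", "high"}

    def test_raw_table_supplies_mean_fractions(self):
        rows = np.zeros((2, 9))
        z = self._ztable(rows)
        raw = self._ztable(np.full((2, 9), 0.24))
        s = summarize_cluster(z, {"R0": 1, "R1": 1}, 1, raw_table=raw)
        assert s.mean_fraction["Mib1"] == pytest.approx(0.24)


class TestDefaultRules:
    def test_exactly_eight_uniquely_named(self):
        rules = default_region_rules()
        assert len(rules) == 8
        assert sorted(r.name for r in rules) == sorted(REGION_TYPES)

    def test_noise_free_archetypes_recover_their_own_names(self, archetype_table):
        z = zscore_columns(archetype_table)
        assignment = {row: i + 1 for i, row in enumerate(archetype_table["roi_id"])}
        for i, name in enumerate(archetype_table["roi_id"]):
            s = summarize_cluster(z, assignment, i + 1, raw_table=archetype_table)
            call = assign_region_type(s)
            assert call.region_type == name
            assert call.score == pytest.approx(1.0)

    def test_hypoxia_rule_rejects_all_low_profile(self):
        rules = {r.name: r for r in default_region_rules()}
        all_low = {m: "low" for m in MARKERS}
        assert rules["HReg"].score(all_low) < 1.0  # CA-IX clause fails
        assert not rules["HReg"].score(all_low) >= 1.0

    def test_empty_rule_rejected(self):
        with pytest.raises(ValueError):
            RegionTypeRule("X", {})

    def test_yaml_roundtrip(self, tmp_path):
        rules = default_region_rules()
        path = tmp_path / "rules.yaml"
        rules_to_yaml(rules, path)
        back = rules_from_yaml(path)
        assert [(r.name, r.required) for r in back] == [(r.name, r.required) for r in rules]


class TestAssignRegionType:
    def test_hypoxia_pattern_maps_to_hypoxia_group(self):
        levels = {m: "low" for m in MARKERS}
        levels["CA-IX"] = "high"
        call = assign_region_type(_summary(levels))
        assert call.region_type == "HReg"
        assert call.group == "Hypoxia"

    def test_mesenchymal_pattern_maps_to_mes_subtype(self):
        levels = {m: "low" for m in MARKERS}
        levels["Nestin"] = "high"
        levels["Vimentin"] = "high"
        call = assign_region_type(_summary(levels))
        assert call.region_type == "MSReg"
        assert call.subtype == "Mes"

    def test_all_moderate_profile_is_unclassified(self):
        call = assign_region_type(_summary({m: "moderate" for m in MARKERS}))
        assert call.region_type == "unclassified"
        assert call.group == "none" and call.subtype == "none"

    def test_variable_levels_satisfy_no_clause(self):
        levels = {m: "low" for m in MARKERS}
        levels["CA-IX"] = "variable"
        rules = {r.name: r for r in default_region_rules()}
        assert rules["HReg"].score(levels) == pytest.approx(8 / 9)

    def test_empty_rule_list_rejected(self):
        with pytest.raises(ValueError):
            assign_region_type(_summary({m: "low" for m in MARKERS}), rules=[])

    def test_group_and_subtype_maps_are_total_and_constant(self):
        assert UPPER_GROUPS == {
            "ASReg": "Stem-cell-and-resistance",
            "MSReg": "Stem-cell-and-resistance",
            "ARReg": "Stem-cell-and-resistance",
            "HReg": "Hypoxia",
            "HPReg": "Proliferative",
            "PPReg": "Proliferative",
            "TNReg": "Transformed-neuronal",
            "MReg": "Mutation",
        }
        assert SUBTYPES == {"TNReg": "PN", "HPReg": "Prolif", "MSReg": "Mes"}

    def test_rule_order_irrelevant_without_ties(self, archetype_table):
        z = zscore_columns(archetype_table)
        assignment = {row: i + 1 for i, row in enumerate(archetype_table["roi_id"])}
        summaries = [
            summarize_cluster(z, assignment, i + 1)
            for i in range(len(archetype_table))
        ]
        base = [assign_region_type(s).region_type for s in summaries]
        rules = default_region_rules()
        rng = np.random.default_rng(3)
        for _ in range(5):
            perm = [rules[i] for i in rng.permutation(len(rules))]
            assert [assign_region_type(s, perm).region_type for s in summaries] == base


def _end_to_end_accuracy(sd: float, seed: int) -> float:
    cohort = simulate_cohort(CohortSpec(n_tumors=45, sd=sd, missing_rate=0.0, seed=seed))
    z = zscore_columns(cohort.table)
    d, _, _ = distance_matrix(z)
    tree = complete_linkage(d, leaf_names=list(z["roi_id"]))
    assignment = cut_tree_k(tree, 8)
    summaries = {
        c: summarize_cluster(z, assignment, c, raw_table=cohort.table)
        for c in set(assignment.values())
    }
    calls = {c: assign_region_type(s).region_type for c, s in summaries.items()}
    correct = sum(
        calls[assignment[r]] == cohort.truth_labels[r] for r in cohort.truth_labels.index
    )
    return correct / len(cohort.truth_labels)


class TestNoiseDegradation:
    def test_accuracy_nonincreasing_in_noise(self):
        """RoI-level call accuracy at sd 0.05 / 0.1 / 0.2 degrades with noise."""
        acc = {sd: np.mean([_end_to_end_accuracy(sd, s) for s in (31, 32)])
               for sd in (0.05, 0.1, 0.2)}
        assert acc[0.05] >= acc[0.1] >= acc[0.2]
        assert acc[0.05] >= 0.9
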