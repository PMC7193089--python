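"""Pipeline configuration and staged orchestration.

The full analysis is correlate -> cluster -> classify -> co-occur, each
stage reading and writing documented TSV formats so that the chained CLI
subcommands and :func:`run_pipeline` produce byte-identical results.  Every
output directory carries a ``manifest.json`` stamped with the config hash
and seed; a plain-text log records the counts at each stage (RoIs in,
pairs imputed, clusters found, regions called).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .clustering import (
    ClusteringConfig,
    complete_linkage,
    cut_tree,
    cut_tree_k,
    distance_matrix,
    to_newick,
    zscore_columns,
)
from .cohort import marker_columns, read_cohort_table, write_cohort_table
from .cooccurrence import (
    cooccurrence_matrix,
    exclusivity_flags,
    relapse_contrast,
    tumor_composition,
)
from .correlation import spearman_matrix
from .ihc import QuantConfig
from .panel import MARKERS
from .regions import (
    MIN_MATCH_SCORE,
    assign_region_type,
    default_region_rules,
    rules_from_yaml,
    summarize_cluster,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "stage_correlate", "stage_cluster", "stage_classify", "stage_cooccur"]

logger = logging.getLogger("gbmregions")

FLOAT_FORMAT = "%.6f"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, serializable to YAML losslessly."""

    markers: tuple[str, ...] = MARKERS
    quant: QuantConfig = field(default_factory=QuantConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    n_clusters: int | None = None  # overrides cutoff_height when set
    rules_path: str | None = None  # None -> built-in default rules
    min_match_score: float = MIN_MATCH_SCORE
    min_marginal: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["markers"] = list(self.markers)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        quant = d.pop("quant", {})
        stains = quant.pop("stains", None)
        if stains is not None:
            from .ihc import StainVectors
            stains = StainVectors(**{
                k: tuple(v) if v is not None else None for k, v in stains.items()
            })
            quant["stains"] = stains
        d["quant"] = QuantConfig(**quant)
        d["clustering"] = ClusteringConfig(**d.pop("clustering", {}))
        d["markers"] = tuple(d.pop("markers", MARKERS))
        return cls(**d)

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every pipeline product."""

    table: pd.DataFrame
    correlation: object
    ztable: pd.DataFrame
    tree: object
    assignment: dict[str, int]
    summaries: list
    calls: list
    compositions: list
    cooccurrence: object
    flags: pd.DataFrame
    relapse: pd.DataFrame
    report: dict


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _manifest(outdir: Path, config: PipelineConfig, entries: list[str]) -> None:
    path = outdir / "manifest.json"
    existing = json.loads(path.read_text()) if path.exists() else {
        "config_hash": config.hash(), "seed": config.seed, "outputs": []}
    if existing["config_hash"] != config.hash():
        existing = {"config_hash": config.hash(), "seed": config.seed, "outputs": []}
    existing["outputs"] = sorted(set(existing["outputs"]) | set(entries))
    path.write_text(json.dumps(existing, indent=2, sort_keys=True) + "\n")


def _load_table(cohort: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return read_cohort_table(cohort)


def stage_correlate(cohort: str | Path | pd.DataFrame, outdir: str | Path,
                    config: PipelineConfig | None = None) -> "object":
    """Spearman correlation stage; writes matrix and long-format TSVs."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_table(cohort)
    corr = spearman_matrix(table)
    corr.write(outdir / "correlation_matrix.tsv", outdir / "correlations_long.tsv")
    _manifest(outdir, config, ["correlation_matrix.tsv", "correlations_long.tsv"])
    logger.info("correlate: %d RoIs, %d marker pairs not computable",
                len(table), int(corr.not_computable.to_numpy().sum() // 2))
    return corr


def _impute_noncomputable(ztable: pd.DataFrame, bad_pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Cohort-mean (z = 0) imputation of missing cells, only for RoIs in
    non-computable pairs."""
    affected = sorted({r for pair in bad_pairs for r in pair})
    out = ztable.copy()
    rows = out["roi_id"].isin(affected)
    for m in marker_columns(out):
        col = out.loc[rows, m]
        out.loc[rows, m] = col.fillna(0.0)
    logger.info("cluster: imputed missing values for %d RoIs in %d non-computable pairs",
                len(affected), len(bad_pairs))
    return out


def stage_cluster(cohort: str | Path | pd.DataFrame, outdir: str | Path,
                  config: PipelineConfig | None = None):
    """Z-score, distance matrix, complete linkage, cut; writes assignment,
    merge list, newick dendrogram and the z-scored table."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_table(cohort)
    if len(table) == 0:
        raise ValueError("empty cohort: nothing to cluster")
    ztable = zscore_columns(table)
    d, shared, bad_pairs = distance_matrix(ztable, config.clustering)
    if bad_pairs:
        ztable = _impute_noncomputable(ztable, bad_pairs)
        d, shared, bad_pairs = distance_matrix(ztable, config.clustering)
    tree = complete_linkage(d, leaf_names=list(ztable["roi_id"]))
    if config.n_clusters is not None:
        assignment = cut_tree_k(tree, config.n_clusters)
    else:
        assignment = cut_tree(tree, config.clustering.cutoff_height)
    n_clusters = len(set(assignment.values()))
    logger.info("cluster: %d RoIs -> %d clusters", len(table), n_clusters)

    assign_df = table[["tumor_id", "roi_id"]].copy()
    assign_df["cluster"] = assign_df["roi_id"].map(assignment)
    _write_tsv(assign_df, outdir / "assignments.tsv")
    _write_tsv(tree.to_frame(), outdir / "merges.tsv")
    (outdir / "dendrogram.nwk").write_text(to_newick(tree) + "\n")
    write_cohort_table(ztable, outdir / "zscored.tsv")
    _manifest(outdir, config,
              ["assignments.tsv", "merges.tsv", "dendrogram.nwk", "zscored.tsv"])
    return ztable, tree, assignment


def stage_classify(cohort: str | Path | pd.DataFrame,
                   assignment: dict[str, int] | str | Path,
                   outdir: str | Path,
                   config: PipelineConfig | None = None,
                   ztable: pd.DataFrame | None = None):
    """Summarize clusters, discretize, assign region types; writes
    cluster_summaries.tsv and region_calls.tsv."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_table(cohort)
    if not isinstance(assignment, dict):
        adf = pd.read_csv(assignment, sep="\t", dtype={"roi_id": str})
        assignment = dict(zip(adf["roi_id"], adf["cluster"].astype(int)))
    if ztable is None:
        ztable = zscore_columns(table)
    rules = (rules_from_yaml(config.rules_path) if config.rules_path
             else default_region_rules())
    cluster_ids = sorted(set(assignment.values()))
    summaries, calls = [], []
    for cid in cluster_ids:
        s = summarize_cluster(ztable, assignment, cid, raw_table=table)
        summaries.append(s)
        calls.append(assign_region_type(s, rules, config.min_match_score))
    sum_rows = []
    for s in summaries:
        for m in marker_columns(table):
            sum_rows.append({
                "cluster": s.cluster_id, "marker": m,
                "median_z": s.median_z[m], "iqr": s.iqr[m],
                "mean_fraction": s.mean_fraction[m], "level": s.levels[m],
                "n_members": s.n_members,
            })
    _write_tsv(pd.DataFrame(sum_rows), outdir / "cluster_summaries.tsv")
    calls_df = pd.DataFrame(
        [{"cluster": c.cluster_id, "region_type": c.region_type,
          "score": c.score, "group": c.group, "subtype": c.subtype}
         for c in calls])
    _write_tsv(calls_df, outdir / "region_calls.tsv")
    _manifest(outdir, config, ["cluster_summaries.tsv", "region_calls.tsv"])
    logger.info("classify: %d clusters, %d classified",
                len(calls), sum(c.region_type != "unclassified" for c in calls))
    return summaries, calls


def stage_cooccur(cohort: str | Path | pd.DataFrame,
                  assignment: dict[str, int] | str | Path,
                  calls: dict[int, str] | str | Path,
                  outdir: str | Path,
                  config: PipelineConfig | None = None):
    """Tumor compositions, co-occurrence matrix, exclusivity flags and
    relapse contrast; writes the four TSVs."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_table(cohort)
    if not isinstance(assignment, dict):
        adf = pd.read_csv(assignment, sep="\t", dtype={"roi_id": str})
        assignment = dict(zip(adf["roi_id"], adf["cluster"].astype(int)))
    if not isinstance(calls, dict):
        cdf = pd.read_csv(calls, sep="\t")
        calls = dict(zip(cdf["cluster"].astype(int), cdf["region_type"]))
    comps = tumor_composition(table, assignment, calls)
    matrix = cooccurrence_matrix(comps)
    flags = exclusivity_flags(matrix, min_marginal=config.min_marginal)
    relapse = relapse_contrast(comps)
    comp_df = pd.DataFrame(
        [{"tumor_id": c.tumor_id, "relapse": int(c.relapse),
          "n_rois": c.n_rois,
          "region_types": ",".join(sorted(c.region_types))}
         for c in comps])
    _write_tsv(comp_df, outdir / "compositions.tsv")
    _write_tsv(matrix.counts, outdir / "cooccurrence.tsv", index=True)
    _write_tsv(flags, outdir / "exclusivity.tsv")
    _write_tsv(relapse, outdir / "relapse_contrast.tsv", index=True)
    _manifest(outdir, config, ["compositions.tsv", "cooccurrence.tsv",
                               "exclusivity.tsv", "relapse_contrast.tsv"])
    logger.info("cooccur: %d tumors, %d exclusive pairs flagged",
                len(comps), int(flags["exclusive"].sum()))
    return comps, matrix, flags, relapse


def run_pipeline(config: PipelineConfig,
                 cohort: str | Path | pd.DataFrame,
                 outdir: str | Path) -> PipelineResult:
    """Execute correlate -> cluster -> classify -> cooccur on one cohort.

    Deterministic: identical config and cohort give byte-identical output
    files, equal to the chained individual stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        table = _load_table(cohort)
        if len(table) == 0:
            raise ValueError("empty cohort: nothing to analyze")
        logger.info("input: %d RoIs from %d tumors",
                    len(table), table["tumor_id"].nunique())
        try:
            corr = stage_correlate(table, outdir, config)
        except Exception as e:
            raise RuntimeError(f"stage correlate failed: {e}") from e
        try:
            ztable, tree, assignment = stage_cluster(table, outdir, config)
        except Exception as e:
            raise RuntimeError(f"stage cluster failed: {e}") from e
        try:
            summaries, calls = stage_classify(table, assignment, outdir, config,
                                              ztable=ztable)
        except Exception as e:
            raise RuntimeError(f"stage classify failed: {e}") from e
        calls_map = {c.cluster_id: c.region_type for c in calls}
        try:
            comps, matrix, flags, relapse = stage_cooccur(
                table, assignment, calls_map, outdir, config)
        except Exception as e:
            raise RuntimeError(f"stage cooccur failed: {e}") from e
        report = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "n_tumors": int(table["tumor_id"].nunique()),
            "n_rois": int(len(table)),
            "n_clusters": len(set(assignment.values())),
            "n_region_calls": sum(c.region_type != "unclassified" for c in calls),
            "region_types": sorted({c.region_type for c in calls}),
            "n_exclusive_pairs": int(flags["exclusive"].sum()),
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        config.to_yaml(outdir / "config.yaml")
        return PipelineResult(
            table=table, correlation=corr, ztable=ztable, tree=tree,
            assignment=assignment, summaries=summaries, calls=calls,
            compositions=comps, cooccurrence=matrix, flags=flags,
            relapse=relapse, report=report,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
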