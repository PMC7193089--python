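"""Summarize each cluster's marker profile and assign region types.

Per cluster: median z-score and IQR per marker, discretized to low /
moderate / high (or variable when the IQR exceeds 2), then matched against
the eight region-type rules; each call carries its upper-level
pathophysiological group and, where applicable, the mirrored intertumoral
subtype (PN / Prolif / Mes).

Writes results/cluster_summaries.tsv and results/region_calls.tsv.
"""

import argparse
from pathlib import Path

from gbmregions.pipeline import PipelineConfig, stage_classify

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort.tsv"))
ap.add_argument("--assignment", type=Path, default=Path("results/assignments.tsv"))
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

summaries, calls = stage_classify(args.cohort, args.assignment, args.outdir,
                                  PipelineConfig())
for s, c in zip(summaries, calls):
    mib1_pct = 100 * s.mean_fraction["Mib1"]
    print(f"cluster {c.cluster_id} ({s.n_members:3d} RoIs): {c.region_type:12s} "
          f"score {c.score:.2f}  group {c.group:24s} subtype {c.subtype:6s} "
          f"mean Mib1 {mib1_pct:.1f}%")
n_called = sum(c.region_type != "unclassified" for c in calls)
print(f"{n_called}/{len(calls)} clusters assigned a region type")
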