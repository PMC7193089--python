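"""Within-tumor co-occurrence and mutual exclusivity of region types.

Builds each tumor's set of region types from the cluster calls, counts
co-occurrence over the cohort, flags pairs never seen together (with both
marginals at the informativeness floor), and contrasts presence between
newly diagnosed and relapse tumors.

Writes results/compositions.tsv, cooccurrence.tsv, exclusivity.tsv,
relapse_contrast.tsv.
"""

import argparse
from pathlib import Path

from gbmregions.pipeline import PipelineConfig, stage_cooccur

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", type=Path, default=Path("results/cohort.tsv"))
ap.add_argument("--assignment", type=Path, default=Path("results/assignments.tsv"))
ap.add_argument("--calls", type=Path, default=Path("results/region_calls.tsv"))
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

comps, matrix, flags, relapse = stage_cooccur(
    args.cohort, args.assignment, args.calls, args.outdir, PipelineConfig())

sizes = sorted(len(c.region_types) for c in comps)
print(f"{len(comps)} tumors; region types per tumor: "
      f"min {sizes[0]}, median {sizes[len(sizes) // 2]}, max {sizes[-1]}")
excl = flags[flags["exclusive"]]
if len(excl):
    pairs = [f"({r.type_a}, {r.type_b})" for r in excl.itertuples()]
    print("mutually exclusive region-type pairs:", ", ".join(pairs))
else:
    print("no mutually exclusive pairs at the marginal floor")
print("presence by relapse status:")
print(relapse.to_string())
tn_relapse = int(relapse.loc["TNReg", "relapse"])
print(f"TNReg in relapse tumors: {tn_relapse}")
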