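# Methods

## Overview

The package analyzes regional immunoreactivity profiles of glioblastoma:
each region of interest (RoI) on a stained section yields one positive
fraction per marker of a nine-marker panel (ALDH1, CA-IX, EGFR, GFAP,
MAP2, Mib1/Ki-67, Nestin, NeuN, Vimentin), and the analysis asks whether
recurring regional profiles exist, what they are, and how they combine
within individual tumors. Because the underlying clinical cohort cannot be
redistributed, a first-class synthetic generator reproduces the cohort's
statistical structure with known ground truth; every result the pipeline
reports on synthetic data is a *recovery* of planted structure, which is
what the test suite and the acceptance script measure.

## IHC quantification

An 8-bit RGB image is converted per channel to optical density,
OD = −log₁₀((I + 1)/256), which is ~0 for white and ~2.408 for black. Each
pixel's OD vector is expressed in an H-DAB stain basis (unit vectors:
hematoxylin (0.650, 0.704, 0.286), DAB (0.268, 0.570, 0.776), residual =
their normalized cross product — the standard Ruifrok–Johnston vectors,
overridable in `StainVectors`). Basis coordinates are the stain
concentrations; negative coordinates, which arise only from noise or
quantization, are clipped to zero after solving. The immunoreactivity of
an RoI is the fraction of analyzable pixels (RoI mask minus exclusion mask
for necrosis, vessels, hemorrhage, artifacts) whose DAB concentration
exceeds `dab_od_threshold`.

Parameters: `dab_od_threshold` = 0.15 OD units (separates
counterstain-only background from stained tissue in the rendered
fixtures; it is a calibration constant, not a biological threshold);
`min_roi_pixels` = 100 (an RoI smaller than this after exclusion is an
error, not a 0/0). The measure is **area-based** (positive pixels), not
cell-based: per-cell counting would require nuclear segmentation, which is
out of scope, so a "proliferation rate of 24%" is treated as a positive
area fraction throughout.

## Marker correlation

Spearman ρ per marker pair over all RoIs, with pairwise-complete deletion
(missing cells come from technical tissue loss, so n varies per pair);
average ranks for ties; two-sided p-values from the t-approximation, kept
raw (no multiple-testing correction — the banding, not the stars, carries
the interpretation). Pairs with fewer than 3 complete rows, or a constant
input, are flagged not-computable rather than silently NaN. Bands on |ρ|:
< 0.1 absent, < 0.4 weak, < 0.6 moderate, ≥ 0.6 strong; the 0.4 boundary
is the only choice consistent with calling coefficients of 0.401–0.533
moderate while everything below is weak.

## Profile clustering

Marker columns are z-transformed (sample sd, non-missing cells; missing
stays missing). The distance between two RoIs is d = 1 − r, where r is
the Pearson correlation of their z-scored nine-marker profiles computed
over markers observed in both; d ∈ [0, 2]. A variant sqrt(2(1 − r)) is
selectable. The published analysis used a correlation-derived distance
whose exact normalization is not recoverable; 1 − r is this package's
declared stand-in, and the absolute cutoff height it inherits (1.75,
below a root above 1.75) is kept as `cut_tree`'s default.

A pair sharing fewer than `min_shared_markers` = 6 of 9 markers is
non-computable — with up to 3 missing markers per RoI, a lower floor
would allow correlations on 3 points. `complete_linkage` refuses matrices
containing non-computable pairs; the pipeline resolves them beforehand by
imputing the missing cells of only the affected RoIs at the cohort mean
(z = 0) and logging the count. Complete linkage (inter-cluster distance =
maximum over cross-cluster pairs) is implemented directly — it is the
analysis's core step — with the Lance–Williams max update; ties in the
minimal-distance search break on the smallest (left id, right id) pair,
making the merge sequence fully deterministic. Heights are provably
non-decreasing, and the implementation is tested for exact agreement with
an exhaustive O(n⁴) re-scan oracle and with an independent library
implementation.

Cutting: `cut_tree(h)` takes the connected components of all merges below
height h; `cut_tree_k(k)` undoes the last k − 1 merges. Cluster ids are
numbered 1..k in left-to-right dendrogram leaf order. On synthetic
cohorts the analyses cut into k = 8 (the size of the region-type
taxonomy) rather than at 1.75: the synthetic between-archetype linkage
heights depend on the banded generator means and the 1 − r stand-in, so
an absolute height calibrated on a different cohort and distance
normalization does not transfer (it yields ~4–5 clusters here; the
driver `analysis/04_cluster_profiles.py` reports both).

## Region typing

Each cluster is summarized per marker by the member median z-score and
IQR (linear-interpolation quartiles) and discretized: median ≤ −0.5 →
low, ≥ +0.5 → high, else moderate, overridden to **variable** when
IQR > 2.0 — a marker too variable to characterize the cluster, which
therefore satisfies no rule clause. The ±0.5 z thresholds and the IQR
bound are calibrated so that the noise-free archetype profiles discretize
exactly to their qualitative descriptions (verified in tests). Singleton
clusters are summarized but flagged low-confidence.

Rules are explicit and serializable (YAML): each region type is a set of
level constraints (high, at-most-low, at-least-moderate, ...). A cluster
is assigned the highest-scoring rule (weighted fraction of satisfied
clauses) with score ≥ 0.75; ties break to the more specific rule (more
clauses), then rule order; below 0.75 the cluster is *unclassified* — the
published taxonomy assigns every cluster, but a reusable tool must handle
non-matching inputs explicitly. The ASReg and ARReg rules carry
reciprocal dominance clauses (ALDH1-high requires GFAP at-most-moderate
and vice versa); without them the two single-clause rules can tie at 1.0
on borderline clusters and the call would depend on rule order.

Group and subtype maps are fixed: {ASReg, MSReg, ARReg} →
Stem-cell-and-resistance, HReg → Hypoxia, {HPReg, PPReg} → Proliferative,
TNReg → Transformed-neuronal, MReg → Mutation; TNReg → PN, HPReg →
Prolif, MSReg → Mes, else none.

## Co-occurrence

A tumor's composition is the set of region types among its RoIs. The 8×8
co-occurrence matrix counts tumors containing both members of each pair
(diagonal = marginals); unclassified regions are excluded from the matrix
and reported separately. A pair is flagged mutually exclusive iff its
co-count is zero and both marginals are ≥ `min_marginal` = 3 tumors — a
descriptive criterion, not a hypothesis test, because observed absence in
a 61-tumor cohort cannot support significance claims; a Fisher exact
option exists for orientation only. The relapse contrast counts, per
region type, tumors containing it among newly diagnosed vs relapse cases.

## Synthetic cohort generator

The generator emulates the study conditions: 61 tumors; RoI count uniform
on 2–7 per tumor (the real cohort's RoI-count distribution is unpublished;
uniform gives ~275 RoIs); 8/61 tumors are relapses; relapse tumors never
receive a TNReg; (HPReg, PPReg) and (MSReg, MReg) are mutually exclusive
within a tumor (archetypes are drawn uniformly from the admissible set,
given types already present); marker values are normal draws clipped to
[0, 1]; missing cells are injected completely at random at rate 0.02,
capped at 3 of 9 markers per RoI (isolated gaps, and clustering needs ≥ 6
shared markers).

Archetype means use a four-level band palette — high 0.60, elevated 0.45,
moderate 0.30, low 0.05 — for every marker whose level is qualitative;
the three informative Mib1 rates are fixed at 0.24 (HPReg), 0.12 (PPReg)
and 0.066 (MReg), with a 0.12 baseline elsewhere (a typical bulk GBM
Ki-67 rate, and necessary for MReg's 6.6% to be genuinely *low* after
z-scoring) and 0.05 in hypoxic regions. Signature assignments (which
marker is high where, and which markers are required low) follow the
region-type descriptions verbatim. The remaining secondary cells are free
design parameters; they were fixed by a constrained randomized search
maximizing a noise-aware separation score (between-archetype profile
distance minus the predicted within-archetype correlation spread),
subject to three hard validity constraints: every low cell must
discretize low, every archetype must satisfy its own rule exactly, and no
archetype may fully satisfy a foreign rule. Two structural consequences
are worth noting: every column needs at least two non-low archetypes
(otherwise the "low" group z-scores to only −0.35 and discretizes
moderate), and flat profiles are fragile under noise, which is why HPReg
carries elevated CA-IX and moderate ALDH1 (proliferation outpacing
neovascularization induces hypoxic stress) rather than being a bare Mib1
spike.

Default noise: sd 0.10 for the eight structural markers, 0.04 for Mib1 —
Mib1's entire planted range is 0.05–0.24, so 0.10 noise on it would be
40–150% of the signal and would erase the planted proliferation
structure; 0.04 preserves the same noise-to-range ratio as the structural
markers. `CohortSpec(sd=...)` overrides all sds globally for sensitivity
analyses.

The image renderer produces DAB blobs by thresholding a Gaussian-smoothed
random field at the (1 − fraction) quantile, so the truth mask hits the
requested positive fraction to within one pixel, over a uniform
hematoxylin counterstain (OD 0.25); DAB intensity is 1.0 OD by default,
far above the 0.15 threshold, so quantification recovery on these
fixtures is exact up to pixel quantization.

**What the generator does not emulate** — and therefore what passing
recovery tests do not show about real data: spatial structure within
sections (no serial-section registration, no necrosis/vessel morphology),
correlated noise between markers of one RoI, non-random missingness,
archetype prevalence differences between tumors (prevalence is uniform;
the real per-cluster RoI counts are unpublished), intermediate/mixed
regional phenotypes, and staining batch effects. Recovery on this
generator demonstrates the pipeline's correctness and its behavior under
noise, not the biological validity of the taxonomy.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds carried in
the parameter dataclasses; identical parameters and seed give
byte-identical outputs (tables are
written as TSV with 6-decimal fractions). Linkage ties break
lexicographically; z-scores use sample sd (n − 1); quartiles use numpy's
linear interpolation; degenerate inputs fail loudly (constant columns,
empty cohorts, RoIs smaller than the pixel floor, unsatisfiable archetype
constraints) rather than propagating NaN. Problem sizes in the test suite
(45–61 tumors, 100 linkage-oracle instances of n ≤ 10, 200 random
Spearman tables) keep the default run around half a minute while leaving
the recovery margins wide (30-seed minimum ARI 0.962 against the 0.9
acceptance floor).

## Known limitations

- The exact correlation-distance normalization and linkage parameter of
  the original analysis are unrecoverable; 1 − r with complete linkage is
  a declared stand-in, and absolute cutoff heights are therefore not
  comparable across cohorts.
- Area-based positive fractions are not cell-level positivity rates; for
  nuclear markers (Mib1, NeuN) the two can diverge.
- The rule system formalizes qualitative profile descriptions; on real
  data the 0.75 score floor and the ±0.5/IQR 2.0 discretization would
  need recalibration against expert annotation.
- Mutual-exclusivity flags are descriptive; with 8 relapse tumors and
  marginals of a handful, absence of a combination is weak evidence.
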