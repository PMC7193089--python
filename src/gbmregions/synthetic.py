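"""Synthetic cohort and image generation.

The study data this package analyzes — 61 glioblastomas, 2–7 regions of
interest (RoIs) each, nine immunohistochemistry markers per RoI — is not
publicly distributable, so this module generates cohorts with the same
statistical structure: eight recurring marker-profile archetypes (the
region types), truncated-normal within-archetype noise, missing values from
technical tissue loss, within-tumor mutual-exclusion constraints between
region types, and region types never observed in relapsing tumors.  Ground
truth labels are returned alongside the table for recovery testing.

It also renders small synthetic DAB/hematoxylin RoI images with known
positive-pixel fractions, used to exercise the stain-separation
quantification end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort import write_cohort_table
from .panel import MARKERS, REGION_TYPES

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "SyntheticCohort",
    "ConstraintError",
    "make_default_archetypes",
    "simulate_cohort",
    "render_ihc_roi",
    "write_truth_labels",
]


class ConstraintError(ValueError):
    """Raised when archetype constraints leave no admissible assignment."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """Mean/sd marker profile of one region-type archetype.

    ``marker_means`` are mean positive fractions in [0, 1] for all nine
    panel markers; ``marker_sd`` are the within-archetype standard
    deviations (>= 0) of the truncated-normal noise.
    """

    name: str
    marker_means: dict[str, float]
    marker_sd: dict[str, float]

    def __post_init__(self) -> None:
        for mapping, label in ((self.marker_means, "mean"), (self.marker_sd, "sd")):
            missing = set(MARKERS) - set(mapping)
            if missing:
                raise ValueError(f"{self.name}: missing {label} for {sorted(missing)}")
        for m, v in self.marker_means.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: mean for {m} out of [0, 1]: {v}")
        for m, v in self.marker_sd.items():
            if v < 0:
                raise ValueError(f"{self.name}: negative sd for {m}: {v}")

    def mean_vector(self) -> np.ndarray:
        return np.array([self.marker_means[m] for m in MARKERS])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.marker_sd[m] for m in MARKERS])


# Expression bands used for archetype means that are qualitative in origin.
HIGH, ELEVATED, MODERATE, LOW = 0.60, 0.45, 0.30, 0.05

# Proliferation (Mib1) means.  The three informative rates — 24% in the
# highly proliferative archetype, 12% in the proliferative progenitor
# archetype, 6.6% in the EGFR-amplified archetype — are fixed; the
# remaining archetypes sit at a 12% baseline typical of glioblastoma bulk,
# except hypoxic regions where proliferation is suppressed.
MIB1_HP, MIB1_PP, MIB1_M, MIB1_BASE, MIB1_HYPOXIC = 0.24, 0.12, 0.066, 0.12, 0.05

# marker order: ALDH1, GFAP, CA-IX, Vimentin, Mib1, Nestin, EGFR, MAP2, NeuN
# Secondary (non-signature) moderate/elevated expressions spread the
# panel's variation across archetypes — every marker must genuinely vary
# over region types for z-scoring and discretization to be meaningful —
# while keeping distinct archetypes well separated in profile-correlation
# distance so the planted structure is recoverable under realistic noise.
_ARCHETYPE_MEANS: dict[str, tuple[float, ...]] = {
    # ALDH1-positive stem cell region: mixed-differentiation background
    # (elevated Nestin, MAP2, entrapped neurons) bordering hypoxia (CA-IX).
    "ASReg": (HIGH, LOW, ELEVATED, LOW, MIB1_BASE, ELEVATED, LOW, ELEVATED, ELEVATED),
    # Hypoxia: CA-IX alone is high, everything else very low.
    "HReg": (LOW, LOW, HIGH, LOW, MIB1_HYPOXIC, LOW, LOW, LOW, LOW),
    # Highly proliferative: top Mib1; growth outpacing neovascularization
    # brings incipient hypoxia (CA-IX) and moderate stress-coping ALDH1;
    # neuronal/glial/stem filaments barely present.
    "HPReg": (MODERATE, LOW, ELEVATED, LOW, MIB1_HP, LOW, LOW, LOW, LOW),
    # Proliferative progenitor: moderate Mib1 with high Nestin, elevated
    # EGFR and MAP2, mild hypoxic tinge.
    "PPReg": (LOW, LOW, MODERATE, LOW, MIB1_PP, HIGH, ELEVATED, ELEVATED, LOW),
    # Transformed neuronal: dominant NeuN, elevated MAP2 and EGFR,
    # stem/resistance markers low.
    "TNReg": (LOW, LOW, LOW, LOW, MIB1_BASE, LOW, ELEVATED, ELEVATED, HIGH),
    # Mesenchymal stem cell: the intermediate filaments Nestin and
    # Vimentin, with moderate stem/hypoxia background.
    "MSReg": (MODERATE, LOW, MODERATE, HIGH, MIB1_BASE, HIGH, LOW, MODERATE, LOW),
    # Astrocytic resistance: dominated by GFAP with moderate ALDH1 and
    # Vimentin (shared resistance program) and elevated MAP2.
    "ARReg": (MODERATE, HIGH, LOW, MODERATE, MIB1_BASE, LOW, LOW, ELEVATED, LOW),
    # Mutation region: strong EGFR over an elevated glial background
    # (ALDH1, GFAP, entrapped neurons), with a low 6.6% proliferation rate.
    "MReg": (ELEVATED, ELEVATED, LOW, MODERATE, MIB1_M, LOW, HIGH, LOW, ELEVATED),
}

#: Default within-archetype noise sd: 0.10 for the structural markers,
#: 0.04 for Mib1 whose dynamic range (0.05–0.24) is four times narrower.
DEFAULT_SD = 0.10
DEFAULT_MIB1_SD = 0.04


def make_default_archetypes() -> list[ArchetypeSpec]:
    """The eight default region-type archetypes.

    Returns one :class:`ArchetypeSpec` per region type, in canonical
    region-type order.  Only the three Mib1 rates (0.24, 0.12, 0.066) are
    quantitative observations; all other means are banded stand-ins
    (high 0.60 / elevated 0.45 / moderate 0.30 / low 0.05) encoding the
    qualitative per-region marker descriptions.
    """
    out = []
    for name in REGION_TYPES:
        means = dict(zip(MARKERS, _ARCHETYPE_MEANS[name]))
        sds = {m: (DEFAULT_MIB1_SD if m == "Mib1" else DEFAULT_SD) for m in MARKERS}
        out.append(ArchetypeSpec(name=name, marker_means=means, marker_sd=sds))
    return out


#: Within-tumor region-type pairs never observed together, and region types
#: never observed in relapsing tumors — the cohort's planted constraints.
DEFAULT_EXCLUSION_PAIRS: tuple[tuple[str, str], ...] = (
    ("HPReg", "PPReg"),
    ("MSReg", "MReg"),
)
DEFAULT_RELAPSE_FORBIDDEN: tuple[str, ...] = ("TNReg",)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 61 tumors with 2–7 RoIs each,
    8 of 61 tumors relapses, no TNReg in relapses, mutually exclusive
    (HPReg, PPReg) and (MSReg, MReg), and 2% missing cells from technical
    tissue loss (never more than 3 of 9 markers in one RoI).  ``sd``
    overrides every archetype's per-marker noise sd when set.
    """

    n_tumors: int = 61
    rois_per_tumor: tuple[int, int] = (2, 7)
    archetypes: tuple[ArchetypeSpec, ...] = tuple(make_default_archetypes())
    exclusion_pairs: tuple[tuple[str, str], ...] = DEFAULT_EXCLUSION_PAIRS
    relapse_fraction: float = 8 / 61
    relapse_forbidden_types: tuple[str, ...] = DEFAULT_RELAPSE_FORBIDDEN
    missing_rate: float = 0.02
    sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be positive")
        lo, hi = self.rois_per_tumor
        if lo < 1 or hi < lo:
            raise ValueError(f"bad rois_per_tumor range: {self.rois_per_tumor}")
        if not 0.0 <= self.relapse_fraction <= 1.0:
            raise ValueError("relapse_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        names = [a.name for a in self.archetypes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate archetype names: {names}")
        known = set(names)
        for a, b in self.exclusion_pairs:
            if a not in known or b not in known:
                raise ValueError(f"exclusion pair ({a}, {b}) references unknown archetype")
        unknown = set(self.relapse_forbidden_types) - known
        if unknown:
            raise ValueError(f"relapse_forbidden_types not in archetype set: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticCohort:
    """A simulated cohort table plus its ground-truth region-type labels."""

    table: pd.DataFrame
    truth_labels: pd.Series  # index: roi_id, values: archetype name
    spec: CohortSpec


MAX_MISSING_PER_ROI = 3


def _draw_archetype(
    rng: np.random.Generator,
    names: list[str],
    present: set[str],
    excluded_with: dict[str, set[str]],
    forbidden: set[str],
) -> str:
    allowed = [
        n for n in names
        if n not in forbidden and not (excluded_with[n] & present)
    ]
    if not allowed:
        raise ConstraintError(
            "no admissible archetype: all candidates forbidden by "
            f"relapse restriction or exclusion with present types {sorted(present)}"
        )
    return allowed[rng.integers(len(allowed))]


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a cohort under ``spec``; deterministic for a fixed seed.

    Per tumor the RoI count is uniform over the configured range and each
    RoI's archetype is drawn uniformly from those admissible given the
    exclusion pairs (against types already present in that tumor) and, for
    relapse tumors, the relapse-forbidden list.  Marker values are normal
    draws clipped to [0, 1]; missing cells are injected completely at
    random at ``missing_rate``, capped at 3 of 9 markers per RoI.
    """
    rng = np.random.default_rng(spec.seed)
    names = [a.name for a in spec.archetypes]
    by_name = {a.name: a for a in spec.archetypes}
    excluded_with: dict[str, set[str]] = {n: set() for n in names}
    for a, b in spec.exclusion_pairs:
        excluded_with[a].add(b)
        excluded_with[b].add(a)
    forbidden_relapse = set(spec.relapse_forbidden_types)

    n_relapse = int(round(spec.n_tumors * spec.relapse_fraction))
    relapse_flags = np.zeros(spec.n_tumors, dtype=int)
    relapse_flags[rng.choice(spec.n_tumors, size=n_relapse, replace=False)] = 1

    lo, hi = spec.rois_per_tumor
    rows, labels, roi_ids = [], [], []
    for t in range(spec.n_tumors):
        tumor_id = f"T{t + 1:03d}"
        relapse = int(relapse_flags[t])
        n_rois = int(rng.integers(lo, hi + 1))
        present: set[str] = set()
        for r in range(n_rois):
            arch_name = _draw_archetype(
                rng, names, present, excluded_with,
                forbidden_relapse if relapse else set(),
            )
            present.add(arch_name)
            arch = by_name[arch_name]
            mean = arch.mean_vector()
            sd = np.full(len(MARKERS), spec.sd) if spec.sd is not None else arch.sd_vector()
            values = np.clip(rng.normal(mean, sd), 0.0, 1.0)
            roi_id = f"{tumor_id}-R{r + 1}"
            rows.append([tumor_id, roi_id, relapse, *values])
            roi_ids.append(roi_id)
            labels.append(arch_name)

    table = pd.DataFrame(rows, columns=["tumor_id", "roi_id", "relapse", *MARKERS])
    if spec.missing_rate > 0:
        mask = rng.random((len(table), len(MARKERS))) < spec.missing_rate
        for i in range(len(table)):
            hit = np.flatnonzero(mask[i])
            if len(hit) > MAX_MISSING_PER_ROI:
                keep = rng.choice(hit, size=MAX_MISSING_PER_ROI, replace=False)
                mask[i, :] = False
                mask[i, keep] = True
        values = table[list(MARKERS)].to_numpy()
        values[mask] = np.nan
        table[list(MARKERS)] = values

    truth = pd.Series(labels, index=pd.Index(roi_ids, name="roi_id"), name="region_type")
    return SyntheticCohort(table=table, truth_labels=truth, spec=spec)


def write_truth_labels(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write ground-truth labels as a two-column TSV (roi_id, region_type)."""
    cohort.truth_labels.rename_axis("roi_id").to_frame().to_csv(path, sep="\t")


def write_cohort(cohort: SyntheticCohort, table_path: str | Path,
                 truth_path: str | Path | None = None) -> None:
    """Write the cohort table (and optionally the truth labels) as TSV."""
    write_cohort_table(cohort.table, table_path)
    if truth_path is not None:
        write_truth_labels(cohort, truth_path)


# ---------------------------------------------------------------------------
# Synthetic IHC RoI rendering

# Ruifrok–Johnston H-DAB optical-density unit vectors.
_HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
_DAB_OD = np.array([0.268, 0.570, 0.776])
_BACKGROUND_HEMATOXYLIN = 0.25  # counterstain OD everywhere


def render_ihc_roi(
    width: int,
    height: int,
    positive_fraction: float,
    intensity: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic DAB-stained RoI and its ground-truth mask.

    A smoothed random field thresholded at the (1 - positive_fraction)
    quantile gives blob-shaped DAB-positive areas whose pixel fraction
    matches ``positive_fraction`` to within one pixel.  Positive pixels
    carry DAB at optical density ``intensity`` on top of a uniform
    hematoxylin counterstain; the rest show counterstain only.

    Returns ``(rgb, mask)``: an (H, W, 3) uint8 image and an (H, W) bool
    truth mask.  Deterministic per seed.
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"image dimensions must be positive, got {width}x{height}")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError(f"positive_fraction out of [0, 1]: {positive_fraction}")
    rng = np.random.default_rng(seed)
    if positive_fraction == 0.0:
        mask = np.zeros((height, width), dtype=bool)
    elif positive_fraction == 1.0:
        mask = np.ones((height, width), dtype=bool)
    else:
        fieldv = ndimage.gaussian_filter(rng.standard_normal((height, width)), sigma=3.0)
        thresh = np.quantile(fieldv, 1.0 - positive_fraction)
        mask = fieldv > thresh

    od = np.empty((height, width, 3))
    od[:] = _BACKGROUND_HEMATOXYLIN * _HEMATOXYLIN_OD
    od[mask] += intensity * _DAB_OD
    # invert OD = -log10((I + 1)/256)  =>  I = 256 * 10**-OD - 1
    rgb = np.clip(np.round(256.0 * 10.0 ** (-od) - 1.0), 0, 255).astype(np.uint8)
    return rgb, mask
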