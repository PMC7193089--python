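"""The nine-marker immunohistochemistry panel and the region-type taxonomy.

The panel covers stemness (ALDH1, Nestin), hypoxia (CA-IX), receptor
amplification (EGFR), glial and neuronal differentiation (GFAP, MAP2, NeuN),
proliferation (Mib1/Ki-67) and mesenchymal character (Vimentin).  Marker
order follows the clustered-heatmap convention and is fixed so that every
table written by this package has identical column order.
"""

from __future__ import annotations

#: Canonical marker order used in every table and profile vector.
MARKERS: tuple[str, ...] = (
    "ALDH1",
    "GFAP",
    "CA-IX",
    "Vimentin",
    "Mib1",
    "Nestin",
    "EGFR",
    "MAP2",
    "NeuN",
)

#: The eight recurring region types (tumor-architecture archetypes).
REGION_TYPES: tuple[str, ...] = (
    "ASReg",  # ALDH1-positive stem cell region
    "HReg",   # region of hypoxia (CA-IX)
    "HPReg",  # highly proliferative region
    "PPReg",  # proliferative progenitor cell region (Nestin+)
    "TNReg",  # transformed neuronal region (NeuN/MAP2)
    "MSReg",  # mesenchymal stem cell region (Nestin/Vimentin)
    "ARReg",  # astrocytic resistance region (GFAP)
    "MReg",   # mutation region (EGFR overexpression)
)

#: Region type -> upper-level pathophysiological group (five groups).
UPPER_GROUPS: dict[str, str] = {
    "ASReg": "Stem-cell-and-resistance",
    "MSReg": "Stem-cell-and-resistance",
    "ARReg": "Stem-cell-and-resistance",
    "HReg": "Hypoxia",
    "HPReg": "Proliferative",
    "PPReg": "Proliferative",
    "TNReg": "Transformed-neuronal",
    "MReg": "Mutation",
}

#: Region type -> intertumoral expression subtype mirrored regionally.
SUBTYPES: dict[str, str] = {
    "TNReg": "PN",      # proneural
    "HPReg": "Prolif",  # proliferative
    "MSReg": "Mes",     # mesenchymal
}

#: Sentinel for clusters no rule matches.
UNCLASSIFIED = "unclassified"

#: Required identifier columns of a cohort table, before marker columns.
ID_COLUMNS: tuple[str, ...] = ("tumor_id", "roi_id", "relapse")


def upper_group(region_type: str) -> str:
    """Upper-level group of a region type; ``"none"`` for unclassified."""
    return UPPER_GROUPS.get(region_type, "none")


def subtype(region_type: str) -> str:
    """Intertumoral subtype label of a region type (``"none"`` if unmapped)."""
    return SUBTYPES.get(region_type, "none")
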