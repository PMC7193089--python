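"""Positive-fraction quantification of DAB immunohistochemistry images.

Pipeline: RGB -> per-channel optical density (Beer–Lambert) -> linear
unmixing into hematoxylin / DAB / residual concentrations in a fixed stain
basis (Ruifrok–Johnston H-DAB vectors by default) -> fraction of RoI pixels
whose DAB concentration exceeds a threshold, after removing excluded areas
(necrosis, vessels, hemorrhages, artifacts).  The result is one
proportional immunoreactivity value per RoI per marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StainVectors",
    "QuantConfig",
    "QuantResult",
    "RoiTooSmallError",
    "od_transform",
    "separate_stains",
    "positive_fraction",
    "quantify_roi",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Unit optical-density vectors of the stain basis.

    ``residual`` defaults to the normalized cross product of hematoxylin
    and DAB, completing an invertible 3x3 basis.
    """

    hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    dab: tuple[float, float, float] = (0.268, 0.570, 0.776)
    residual: tuple[float, float, float] | None = None

    def basis(self) -> np.ndarray:
        """3x3 matrix with stain vectors as columns (H, DAB, residual)."""
        h = _unit(np.asarray(self.hematoxylin, dtype=float))
        d = _unit(np.asarray(self.dab, dtype=float))
        if self.residual is None:
            r = _unit(np.cross(h, d))
        else:
            r = _unit(np.asarray(self.residual, dtype=float))
        basis = np.column_stack([h, d, r])
        if abs(np.linalg.det(basis)) < 1e-9:
            raise ValueError("stain vectors do not form an invertible basis")
        return basis


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    ``dab_od_threshold`` — DAB concentration above which a pixel counts as
    positive (OD units; default 0.15 separates counterstain-only background
    from genuinely stained areas).  ``min_roi_pixels`` — smallest analyzable
    RoI after exclusion.
    """

    dab_od_threshold: float = 0.15
    min_roi_pixels: int = 100
    stains: StainVectors = StainVectors()

    def __post_init__(self) -> None:
        if not np.isfinite(self.dab_od_threshold) or self.dab_od_threshold <= 0:
            raise ValueError(f"dab_od_threshold must be finite and positive: {self.dab_od_threshold}")
        if self.min_roi_pixels < 1:
            raise ValueError("min_roi_pixels must be positive")


@dataclass(frozen=True)
class QuantResult:
    roi_id: str
    marker: str
    positive_fraction: float
    n_pixels_analyzed: int


class RoiTooSmallError(ValueError):
    """RoI has too few analyzable pixels after exclusion."""


def od_transform(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB image.

    OD = -log10((I + 1) / 256); 0 for white (~0.0017) up to ~2.408 for black.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {rgb.shape}")
    return -np.log10((rgb.astype(float) + 1.0) / 256.0)


def separate_stains(od: np.ndarray, vectors: StainVectors | None = None) -> np.ndarray:
    """Unmix an OD image into stain concentrations (H, DAB, residual).

    Concentrations are the coordinates of each pixel's OD vector in the
    stain basis; recombining ``basis @ concentrations`` reproduces the OD
    image exactly for clip-free inputs.  Negative coordinates (noise,
    quantization) are clipped to zero after solving.
    """
    vectors = vectors or StainVectors()
    basis = vectors.basis()
    od = np.asarray(od, dtype=float)
    flat = od.reshape(-1, 3).T
    conc = np.linalg.solve(basis, flat).T.reshape(od.shape)
    return np.clip(conc, 0.0, None)


def positive_fraction(
    dab: np.ndarray,
    roi_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    config: QuantConfig | None = None,
    roi_id: str = "roi",
    marker: str = "marker",
) -> QuantResult:
    """Fraction of analyzable RoI pixels with DAB concentration above threshold.

    ``exclusion_mask`` marks pixels removed from analysis (necrosis,
    vessels, hemorrhages, artifacts).  Raises :class:`RoiTooSmallError`
    when fewer than ``min_roi_pixels`` pixels remain.
    """
    config = config or QuantConfig()
    dab = np.asarray(dab, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != dab.shape:
        raise ValueError("roi_mask shape does not match image")
    analyzed = roi_mask.copy()
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != dab.shape:
            raise ValueError("exclusion_mask shape does not match image")
        analyzed &= ~exclusion_mask
    n = int(analyzed.sum())
    if n < config.min_roi_pixels:
        raise RoiTooSmallError(
            f"RoI {roi_id!r}: only {n} analyzable pixels after exclusion "
            f"(minimum {config.min_roi_pixels})"
        )
    frac = float((dab[analyzed] > config.dab_od_threshold).sum()) / n
    return QuantResult(roi_id=roi_id, marker=marker,
                       positive_fraction=frac, n_pixels_analyzed=n)


def quantify_roi(
    rgb: np.ndarray,
    roi_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    config: QuantConfig | None = None,
    roi_id: str = "roi",
    marker: str = "marker",
) -> QuantResult:
    """RGB image -> OD -> stain separation -> DAB positive fraction."""
    config = config or QuantConfig()
    conc = separate_stains(od_transform(rgb), config.stains)
    return positive_fraction(conc[..., 1], roi_mask, exclusion_mask, config,
                             roi_id=roi_id, marker=marker)
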