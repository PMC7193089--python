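"""Pairwise Spearman correlation of the marker panel across all RoIs.

Missing cells (tissue lost during staining) are handled by pairwise-complete
deletion, so the effective n differs per marker pair.  Coefficients are
banded into absent / weak / moderate / strong by absolute value; p-values
are the usual two-sided t-approximation and are reported raw, without
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import marker_columns

__all__ = [
    "CorrelationMatrix",
    "spearman_matrix",
    "classify_strength",
    "MIN_PAIRWISE_N",
]

#: Minimum pairwise-complete observations for a computable coefficient.
MIN_PAIRWISE_N = 3

#: Absolute-rho band edges: absent < 0.1 <= weak < 0.4 <= moderate < 0.6 <= strong.
BAND_EDGES = (0.1, 0.4, 0.6)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Spearman rho / p-value / pairwise-n matrices over the panel."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n_pairs: pd.DataFrame
    not_computable: pd.DataFrame  # bool: pair had < MIN_PAIRWISE_N complete rows

    @property
    def markers(self) -> list[str]:
        return list(self.rho.columns)

    def to_long(self) -> pd.DataFrame:
        """Long format (marker_a, marker_b, rho, p, n, band), upper triangle."""
        rows = []
        ms = self.markers
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                rho = self.rho.loc[a, b]
                rows.append({
                    "marker_a": a,
                    "marker_b": b,
                    "rho": rho,
                    "p": self.p_value.loc[a, b],
                    "n": int(self.n_pairs.loc[a, b]),
                    "band": "not-computable" if self.not_computable.loc[a, b]
                            else classify_strength(rho),
                })
        return pd.DataFrame(rows)

    def write(self, matrix_path: str | Path, long_path: str | Path) -> None:
        self.rho.to_csv(matrix_path, sep="\t", float_format="%.6f")
        self.to_long().to_csv(long_path, sep="\t", index=False, float_format="%.6f")


def spearman_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Spearman correlation matrix over all marker pairs, pairwise complete.

    Ranks use average ranks for ties; p-values come from the two-sided
    t-approximation.  Pairs with fewer than :data:`MIN_PAIRWISE_N` complete
    rows are flagged not-computable (rho/p NaN) rather than silently
    propagated.
    """
    ms = marker_columns(table)
    k = len(ms)
    values = table[ms].to_numpy(dtype=float)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    npairs = np.zeros((k, k), dtype=int)
    bad = np.zeros((k, k), dtype=bool)
    for i in range(k):
        npairs[i, i] = np.isfinite(values[:, i]).sum()
        for j in range(i + 1, k):
            ok = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            n = int(ok.sum())
            npairs[i, j] = npairs[j, i] = n
            if n < MIN_PAIRWISE_N:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                bad[i, j] = bad[j, i] = True
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                res = stats.spearmanr(values[ok, i], values[ok, j])
            if not np.isfinite(res.statistic):  # constant input: rho undefined
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                bad[i, j] = bad[j, i] = True
                continue
            rho[i, j] = rho[j, i] = res.statistic
            pval[i, j] = pval[j, i] = res.pvalue
    idx = pd.Index(ms)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_value=pd.DataFrame(pval, index=idx, columns=idx),
        n_pairs=pd.DataFrame(npairs, index=idx, columns=idx),
        not_computable=pd.DataFrame(bad, index=idx, columns=idx),
    )


def classify_strength(rho: float) -> str:
    """Band a correlation coefficient: absent / weak / moderate / strong.

    |rho| < 0.1 absent; < 0.4 weak; < 0.6 moderate; >= 0.6 strong.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation coefficient out of [-1, 1]: {rho}")
    a = abs(rho)
    if a < BAND_EDGES[0]:
        return "absent"
    if a < BAND_EDGES[1]:
        return "weak"
    if a < BAND_EDGES[2]:
        return "moderate"
    return "strong"
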