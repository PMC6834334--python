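"""Robust per-gene normalization of expression and cell-type-specificity calls.

Each gene's expression profile across cell types is centered on its median
M_g and scaled by its median absolute deviation MAD_g:

    e_{g,c} = (E_{g,c} - M_g) / MAD_g

which makes levels comparable between genes. A gene is then called specific
to cell type c when its absolute normalized level deviates by at least
k times the interquartile range of its own normalized profile
(|e_{g,c}| >= k * IQR(e_{g,.}), default k = 1.5 -- the classical Tukey-fence
multiplier). The IQR is computed on the signed normalized values with
linear-interpolation ("type 7") quantiles; the threshold is compared against
the absolute value.

Genes with MAD_g = 0 (constant profiles) are excluded from normalization;
genes with IQR = 0 carry no specificity signal and are never called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["NormalizedExpression", "SpecificityCalls", "normalize_expression", "call_specific_genes"]


@dataclass
class NormalizedExpression:
    """Normalized e_{g,c} values with the per-gene location/scale used."""

    data: pd.DataFrame            # genes x cell types, e values
    median: pd.Series             # M_g per retained gene
    mad: pd.Series                # MAD_g per retained gene
    excluded: list[str] = field(default_factory=list)  # genes with MAD_g = 0

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SpecificityCalls:
    """Cell-type-specific gene calls under the k x IQR rule."""

    by_cell: dict[str, set[str]]
    k: float
    iqr: pd.Series                      # per-gene IQR of e_{g,.}
    zero_iqr_genes: list[str] = field(default_factory=list)

    def genes_for(self, cell_type: str) -> set[str]:
        return set(self.by_cell.get(cell_type, set()))


def normalize_expression(expr: ExpressionMatrix) -> NormalizedExpression:
    """Center and scale each gene by its cross-cell median and MAD.

    MAD is the raw median absolute deviation (no 1.4826 consistency
    constant). Genes with MAD = 0 are excluded and reported.
    """
    if len(expr.cell_types) < 2:
        raise ValueError("need at least 2 cell-type columns to normalize")
    values = expr.data.to_numpy(dtype=float)
    med = np.median(values, axis=1)
    mad = np.median(np.abs(values - med[:, None]), axis=1)
    keep = mad > 0
    excluded = [g for g, k in zip(expr.genes, keep) if not k]
    if excluded:
        logger.info("excluding %d gene(s) with MAD=0", len(excluded))
    e = (values[keep] - med[keep, None]) / mad[keep, None]
    idx = expr.data.index[keep]
    return NormalizedExpression(
        data=pd.DataFrame(e, index=idx, columns=expr.data.columns),
        median=pd.Series(med[keep], index=idx),
        mad=pd.Series(mad[keep], index=idx),
        excluded=excluded,
    )


def call_specific_genes(norm: NormalizedExpression, k: float = 1.5) -> SpecificityCalls:
    """Call gene g specific in cell type c iff |e_{g,c}| >= k * IQR(e_{g,.}).

    Quantiles use linear interpolation between order statistics. Genes whose
    IQR is zero are never specific and are reported separately.
    """
    if k <= 0:
        raise ValueError(f"threshold multiplier k must be positive, got {k}")
    e = norm.data.to_numpy(dtype=float)
    q1, q3 = np.percentile(e, [25, 75], axis=1, method="linear")
    iqr = q3 - q1
    zero = iqr <= 0
    calls = (np.abs(e) >= k * iqr[:, None]) & ~zero[:, None]
    by_cell = {
        c: set(norm.data.index[calls[:, j]])
        for j, c in enumerate(norm.data.columns)
    }
    return SpecificityCalls(
        by_cell=by_cell,
        k=k,
        iqr=pd.Series(iqr, index=norm.data.index),
        zero_iqr_genes=list(norm.data.index[zero]),
    )
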