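"""Cross-omic Spearman correlation: raw metabolites vs clr genera.

The metabolites x genera matrix of Spearman coefficients is the object
that is subsequently biclustered; metabolites enter raw (rank correlation
is invariant to monotone scaling anyway) and genera enter clr-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AlignmentError, MetaboliteTable, ValidationError
from .preprocess import ClrMatrix

__all__ = ["CorrelationMatrix", "spearman", "cross_correlation"]


@dataclass
class CorrelationMatrix:
    """Metabolites (rows) x genera (columns) Spearman coefficients."""

    rho: pd.DataFrame
    pvals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = self.rho.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("correlation matrix contains non-finite entries")
        if np.abs(values).max(initial=0.0) > 1.0 + 1e-12:
            raise ValidationError("correlation coefficients must lie in [-1, 1]")
        if self.pvals is not None and self.pvals.shape != self.rho.shape:
            raise ValidationError("p-value matrix shape mismatch")

    @property
    def row_ids(self) -> list[str]:
        return list(self.rho.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.rho.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rho.shape


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns (rho, two-sided p) with p from the large-sample t
    approximation.  Constant input is an error, never a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman needs two equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("spearman needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def cross_correlation(
    metabolites: MetaboliteTable | pd.DataFrame,
    genera_clr: ClrMatrix | pd.DataFrame,
    with_pvalues: bool = False,
) -> CorrelationMatrix:
    """Spearman correlation of every metabolite against every clr genus.

    Both inputs must be sample-aligned (identical index, identical order).
    """
    met = metabolites.data if hasattr(metabolites, "data") else metabolites
    gen = genera_clr.data if hasattr(genera_clr, "data") else genera_clr
    if list(met.index) != list(gen.index):
        raise AlignmentError("metabolite and genus tables are not sample-aligned")
    if met.shape[0] < 3:
        raise ValidationError("need at least 3 samples for correlation")
    for df, what in ((met, "metabolite"), (gen, "genus")):
        spans = df.max(axis=0) - df.min(axis=0)
        const = list(spans.index[spans == 0])
        if const:
            raise ValidationError(f"constant {what} column(s): {const}")
    m = met.shape[1]
    rho_full, p_full = stats.spearmanr(met.to_numpy(), gen.to_numpy())
    if np.ndim(rho_full) == 0:  # scipy collapses the 1x1 cross case to scalars
        rho_full = np.array([[1.0, rho_full], [rho_full, 1.0]])
        p_full = np.array([[0.0, p_full], [p_full, 0.0]])
    rho = pd.DataFrame(rho_full[:m, m:], index=met.columns, columns=gen.columns)
    pvals = None
    if with_pvalues:
        pvals = pd.DataFrame(p_full[:m, m:], index=met.columns, columns=gen.columns)
    return CorrelationMatrix(rho=rho, pvals=pvals)
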