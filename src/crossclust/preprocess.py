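"""Prevalence filtering, relative abundance, pseudocount and clr transform.

The compositional pipeline mirrors common 16S practice: genera are filtered
on prevalence at a relative-abundance detection limit (default: present in
>= 10% of samples at >= 0.1% relative abundance), metabolites on simple
presence (> 0); a unit pseudocount is added to the retained raw counts and
the centered log-ratio (clr) transform maps each sample's composition to a
zero-sum real vector, removing closure effects before correlation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CountTable, MetaboliteTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "FilterReport",
    "ClrMatrix",
    "relative_abundance",
    "prevalence_filter",
    "data_loss_report",
    "add_pseudocount",
    "clr_transform",
]


@dataclass(frozen=True)
class FilterSpec:
    """Detection/prevalence thresholds for low-prevalence feature removal.

    detection
        Relative-abundance detection limit for genera (0.001 = 0.1%).
    prevalence
        Minimum fraction of samples in which a feature must be detected.
    metabolite_detection
        Absolute detection limit for metabolites; a metabolite counts as
        detected when its value is strictly greater than this (default 0).
    """

    detection: float = 0.001
    prevalence: float = 0.10
    metabolite_detection: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection < 1.0):
            raise ValidationError(f"detection must be in [0, 1), got {self.detection}")
        if not (0.0 < self.prevalence <= 1.0):
            raise ValidationError(f"prevalence must be in (0, 1], got {self.prevalence}")
        if self.metabolite_detection < 0:
            raise ValidationError("metabolite_detection must be >= 0")


@dataclass
class FilterReport:
    """Bookkeeping for a prevalence-filter pass.

    ``data_loss`` is, per sample, the summed relative abundance of the
    dropped features; phylum shifts (percentage points) are reported both
    after renormalizing kept features to sum to one and without.
    """

    n_features_in: int
    n_features_kept: int
    dropped_ids: list[str]
    data_loss: pd.Series | None = None
    mean_data_loss: float | None = None
    phylum_shift_renormalized_pp: dict[str, float] | None = None
    phylum_shift_raw_pp: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_features_kept + len(self.dropped_ids) != self.n_features_in:
            raise ValidationError("filter report does not conserve feature count")
        if self.data_loss is not None:
            loss = self.data_loss.to_numpy()
            if ((loss < -1e-12) | (loss > 1 + 1e-12)).any():
                raise ValidationError("per-sample data loss outside [0, 1]")

    def to_json(self) -> str:
        payload = {
            "n_features_in": self.n_features_in,
            "n_features_kept": self.n_features_kept,
            "dropped_ids": list(self.dropped_ids),
            "mean_data_loss": self.mean_data_loss,
            "data_loss": None
            if self.data_loss is None
            else {k: float(v) for k, v in self.data_loss.items()},
            "phylum_shift_renormalized_pp": self.phylum_shift_renormalized_pp,
            "phylum_shift_raw_pp": self.phylum_shift_raw_pp,
        }
        return json.dumps(payload, indent=2)


@dataclass
class ClrMatrix:
    """clr-transformed samples x features matrix; each row sums to zero."""

    data: pd.DataFrame
    pseudocount: float | None = None
    log_base: str = "e"

    def __post_init__(self) -> None:
        sums = self.data.to_numpy().sum(axis=1)
        if np.abs(sums).max(initial=0.0) > 1e-8:
            raise ValidationError("clr rows must sum to 0 within 1e-8")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


def relative_abundance(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Within-sample relative abundances; each row sums to one."""
    df = counts.data if isinstance(counts, CountTable) else counts
    totals = df.sum(axis=1).astype(float)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"sample(s) with zero total count: {list(zero)}")
    return df.div(totals, axis=0)


def _detected(table, spec: FilterSpec, axis_kind: str) -> pd.DataFrame:
    if axis_kind == "genera":
        return relative_abundance(table) >= spec.detection
    if axis_kind == "metabolites":
        df = table.data if hasattr(table, "data") else table
        return df > spec.metabolite_detection
    raise ValueError(f"axis_kind must be 'genera' or 'metabolites', got {axis_kind!r}")


def prevalence_filter(table, spec: FilterSpec, axis_kind: str):
    """Drop features detected in fewer than ``spec.prevalence`` of samples.

    A feature is kept iff its detection fraction is >= the prevalence
    threshold (boundary inclusive).  Retained cells keep their raw values;
    filtering never rescales.  Returns (filtered table, FilterReport).
    """
    detected = _detected(table, spec, axis_kind)
    frac = detected.mean(axis=0)
    keep = frac >= spec.prevalence
    kept_ids = list(frac.index[keep])
    dropped_ids = list(frac.index[~keep])
    filtered = table.select_features(kept_ids)
    if isinstance(table, CountTable):
        report = data_loss_report(table, kept_ids, taxonomy=table.taxonomy)
    else:
        report = FilterReport(
            n_features_in=table.data.shape[1],
            n_features_kept=len(kept_ids),
            dropped_ids=dropped_ids,
        )
    logger.info(
        "prevalence_filter(%s): kept %d / %d features",
        axis_kind, len(kept_ids), table.data.shape[1],
    )
    return filtered, report


def data_loss_report(
    counts_before: CountTable,
    kept_ids,
    taxonomy: dict[str, str] | None = None,
) -> FilterReport:
    """Quantify what a filter removed.

    Per-sample data loss is the summed relative abundance of the dropped
    features (equivalently 1 minus the kept-feature sum).  With a genus ->
    phylum map, the per-phylum relative-abundance shift is reported in
    percentage points, both renormalized to the kept total and raw.
    """
    all_ids = list(counts_before.data.columns)
    kept_ids = list(kept_ids)
    unknown = [f for f in kept_ids if f not in counts_before.data.columns]
    if unknown:
        raise ValidationError(f"kept_ids not present in table: {unknown}")
    dropped_ids = [f for f in all_ids if f not in set(kept_ids)]
    rel = relative_abundance(counts_before)
    loss = rel[dropped_ids].sum(axis=1) if dropped_ids else pd.Series(0.0, index=rel.index)
    report = FilterReport(
        n_features_in=len(all_ids),
        n_features_kept=len(kept_ids),
        dropped_ids=dropped_ids,
        data_loss=loss,
        mean_data_loss=float(loss.mean()),
    )
    if taxonomy is not None:
        phyla = sorted({taxonomy.get(f, "unassigned") for f in all_ids})
        kept_rel = rel[kept_ids]
        kept_tot = kept_rel.sum(axis=1)
        renorm = kept_rel.div(kept_tot, axis=0)
        shift_renorm: dict[str, float] = {}
        shift_raw: dict[str, float] = {}
        for ph in phyla:
            members_all = [f for f in all_ids if taxonomy.get(f, "unassigned") == ph]
            members_kept = [f for f in kept_ids if taxonomy.get(f, "unassigned") == ph]
            before = rel[members_all].sum(axis=1).mean()
            after_renorm = renorm[members_kept].sum(axis=1).mean() if members_kept else 0.0
            after_raw = kept_rel[members_kept].sum(axis=1).mean() if members_kept else 0.0
            shift_renorm[ph] = float((after_renorm - before) * 100.0)
            shift_raw[ph] = float((after_raw - before) * 100.0)
        report.phylum_shift_renormalized_pp = shift_renorm
        report.phylum_shift_raw_pp = shift_raw
    return report


def add_pseudocount(counts, c: float = 1.0):
    """Add a constant to every cell so the clr transform is defined.

    Returns ``(shifted, max_pp_shift)`` where ``max_pp_shift`` is the
    largest absolute change, in percentage points, that the pseudocount
    induces on any relative abundance -- the standard sanity check that a
    unit pseudocount is negligible at realistic sequencing depths.
    """
    if c <= 0:
        raise ValidationError(f"pseudocount must be positive, got {c}")
    df = counts.data if hasattr(counts, "data") else counts
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValidationError("counts must be nonnegative")
    shifted = df + c
    rel_before = df.div(df.sum(axis=1), axis=0)
    rel_after = shifted.div(shifted.sum(axis=1), axis=0)
    max_pp_shift = float((rel_after - rel_before).abs().to_numpy().max() * 100.0)
    return shifted, max_pp_shift


def clr_transform(matrix, pseudocount: float | None = None) -> ClrMatrix:
    """Centered log-ratio transform, rowwise: ln(x_j) - mean_j ln(x_j).

    Requires strictly positive entries; the result is invariant to
    per-row multiplicative scaling and each row sums to zero.
    """
    df = matrix.data if hasattr(matrix, "data") else matrix
    df = df.astype(float)
    values = df.to_numpy()
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"clr requires positive entries; found {values[i, j]!r} at "
            f"sample {df.index[i]!r}, feature {df.columns[j]!r}"
        )
    logs = np.log(values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(clr, index=df.index, columns=df.columns),
        pseudocount=pseudocount,
    )
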