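"""Tabular containers for the joint microbiome-metabolome analysis.

All tables are thin wrappers around a pandas DataFrame held in the
canonical orientation: samples as rows, features as columns.  Validation
happens at construction time and is strict -- invalid input raises, it is
never silently repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "AlignmentError",
    "CountTable",
    "MetaboliteTable",
    "BiomarkerTable",
    "SampleDesign",
    "read_table",
    "write_table",
    "read_design",
    "read_taxonomy",
    "align_samples",
]


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


class AlignmentError(ValueError):
    """Tables cannot be brought onto a common sample set."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()].tolist()))
        raise ValidationError(f"duplicate {what}: {dups}")


def _clean_index(df: pd.DataFrame) -> pd.DataFrame:
    # sample/feature IDs are matched case-sensitively after whitespace trimming
    df = df.copy()
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    df.index.name = None
    df.columns.name = None
    return df


@dataclass
class _FeatureTable:
    """Base: samples x features matrix with string IDs on both axes."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _clean_index(self.data)
        _check_unique(self.data.index, "sample IDs")
        _check_unique(self.data.columns, "feature IDs")
        self._validate_values()

    def _validate_values(self) -> None:  # pragma: no cover - overridden
        pass

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict_samples(self, sample_ids) -> "_FeatureTable":
        """Return a copy restricted to ``sample_ids`` in that order."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise AlignmentError(f"samples not present in table: {missing}")
        return type(self)(self.data.loc[list(sample_ids)])

    def select_features(self, feature_ids) -> "_FeatureTable":
        """Subset to ``feature_ids`` (in that order) without revalidation.

        Derived subsets (e.g. after prevalence filtering) may legitimately
        fall below the 2-feature floor required of fresh input tables; the
        cell values were already validated at construction.
        """
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise ValidationError(f"features not present in table: {missing}")
        out = object.__new__(type(self))
        out.data = self.data[list(feature_ids)]
        if isinstance(self, CountTable):
            out.taxonomy = self.taxonomy
        return out


@dataclass
class CountTable(_FeatureTable):
    """Samples x genera table of nonnegative integer 16S read counts."""

    taxonomy: dict[str, str] | None = None

    def _validate_values(self) -> None:
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValidationError(
                f"count table needs >= 2 samples and >= 2 features, got {self.data.shape}"
            )
        values = self.data.to_numpy()
        if not np.isfinite(values.astype(float)).all():
            raise ValidationError("count table contains non-finite values")
        frac = np.asarray(values, dtype=float)
        bad = np.argwhere(frac != np.floor(frac))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-integer count {values[i, j]!r} at sample "
                f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
            )
        neg = np.argwhere(frac < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative count at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(np.int64)

    def restrict_samples(self, sample_ids) -> "CountTable":
        t = super().restrict_samples(sample_ids)
        t.taxonomy = self.taxonomy
        return t


@dataclass
class MetaboliteTable(_FeatureTable):
    """Samples x metabolites table of nonnegative NMR-derived abundances."""

    def _validate_values(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("metabolite table contains non-finite values")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)


@dataclass
class BiomarkerTable(_FeatureTable):
    """Samples x biomarkers table; missing values are NaN (never 0)."""

    def _validate_values(self) -> None:
        self.data = self.data.astype(float)
        values = self.data.to_numpy()
        if np.isinf(values).any():
            raise ValidationError("biomarker table contains infinite values")


_VALID_FAT = {"HFD", "LFD"}
_VALID_XOS = {"yes", "no"}


@dataclass
class SampleDesign:
    """Per-sample 2x2 design: dietary fat (HFD/LFD) x XOS supplementation.

    The derived ``group`` label is the deterministic product of the two
    factors: HFD, HFD+XOS, LFD, LFD+XOS.
    """

    frame: pd.DataFrame  # index sample_id, columns fat, xos

    def __post_init__(self) -> None:
        self.frame = _clean_index(self.frame)
        _check_unique(self.frame.index, "sample IDs")
        for col in ("fat", "xos"):
            if col not in self.frame.columns:
                raise ValidationError(f"design is missing column {col!r}")
            if self.frame[col].isna().any():
                raise ValidationError(f"design column {col!r} has missing entries")
        self.frame["fat"] = self.frame["fat"].astype(str).str.strip()
        self.frame["xos"] = self.frame["xos"].astype(str).str.strip()
        bad_fat = set(self.frame["fat"]) - _VALID_FAT
        if bad_fat:
            raise ValidationError(f"fat levels must be in {_VALID_FAT}, got {bad_fat}")
        bad_xos = set(self.frame["xos"]) - _VALID_XOS
        if bad_xos:
            raise ValidationError(f"xos levels must be in {_VALID_XOS}, got {bad_xos}")
        self.frame["group"] = [
            f + ("+XOS" if x == "yes" else "")
            for f, x in zip(self.frame["fat"], self.frame["xos"])
        ]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    def samples_in_group(self, group: str) -> list[str]:
        hit = self.frame.index[self.frame["group"] == group]
        return list(hit)

    def restrict_samples(self, sample_ids) -> "SampleDesign":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise AlignmentError(f"samples not present in design: {missing}")
        return SampleDesign(self.frame.loc[list(sample_ids), ["fat", "xos"]])


_KINDS = {
    "counts": CountTable,
    "metabolites": MetaboliteTable,
    "biomarkers": BiomarkerTable,
}


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_table(
    path,
    orientation: str = "samples_as_rows",
    kind: str = "counts",
    sep: str | None = None,
):
    """Read a delimited table into its canonical samples x features form.

    The first column (or a column named ``sample_id``) is the row ID; the
    delimiter is taken from the extension (``.tsv``/``.tab``/``.txt`` -> tab,
    otherwise comma) unless ``sep`` is given.  ``orientation`` says how the
    file is laid out on disk; the returned table is always samples-as-rows.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {sorted(_KINDS)}, got {kind!r}")
    if orientation not in {"samples_as_rows", "features_as_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if orientation == "features_as_rows":
        df = df.T
    return _KINDS[kind](df)


def write_table(table, path, orientation: str = "samples_as_rows") -> None:
    """Write a table as delimited text; inverse of :func:`read_table`.

    Reals are written with 17 significant digits so that a read/write
    round-trip is exact to double precision.
    """
    if orientation not in {"samples_as_rows", "features_as_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = table.data if orientation == "samples_as_rows" else table.data.T
    df = df.rename_axis("sample_id" if orientation == "samples_as_rows" else "feature_id")
    df.to_csv(path, sep=_sep_for(path, None), float_format="%.17g")


def read_design(path, sep: str | None = None) -> SampleDesign:
    """Read a design file with columns sample_id, fat, xos."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    else:
        df = df.set_index(df.columns[0])
    return SampleDesign(df)


def read_taxonomy(path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column genus -> phylum map (TSV by default)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep if sep is not None else "\t"), header=0)
    if df.shape[1] < 2:
        raise ValidationError("taxonomy file needs two columns: genus, phylum")
    return dict(zip(df.iloc[:, 0].astype(str).str.strip(), df.iloc[:, 1].astype(str).str.strip()))


def align_samples(*tables, design: SampleDesign | None = None):
    """Restrict and reorder tables (and the design) to the common sample set.

    The canonical order is the design's order restricted to the common set
    when a design is supplied, otherwise the sorted common IDs -- so the
    result does not depend on the order in which tables are passed.

    Returns the aligned tables in input order, followed by the aligned
    design when one was given.
    """
    if not tables:
        raise ValueError("need at least one table")
    sets = [set(t.sample_ids) for t in tables]
    if design is not None:
        sets.append(set(design.sample_ids))
    common = set.intersection(*sets)
    if not common:
        raise AlignmentError("tables share no sample IDs")
    if design is not None:
        order = [s for s in design.sample_ids if s in common]
    else:
        order = sorted(common)
    out = []
    for t in tables:
        dropped = len(t.sample_ids) - len(order)
        if dropped:
            logger.info("align_samples: dropped %d sample(s) from %s", dropped, type(t).__name__)
        out.append(t.restrict_samples(order))
    if design is not None:
        dropped = len(design.sample_ids) - len(order)
        if dropped:
            logger.info("align_samples: dropped %d sample(s) from design", dropped)
        out.append(design.restrict_samples(order))
    return tuple(out)
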