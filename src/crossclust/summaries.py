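"""Bicluster-level abundance summaries and diet-group contrasts.

Per-sample bicluster summaries follow the two scales used throughout the
analysis: metabolites are summed on the raw scale, genus relative
abundances are summed within each bicluster and the k block sums are then
clr-transformed.  Group differences are reported as log2 fold changes of
group means together with two-sided Mann-Whitney U tests, starred at
p < 0.05 (*) and p < 0.01 (**).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import clr_transform
from .tables import SampleDesign, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BiclusterSummary",
    "sum_metabolites_by_bicluster",
    "sum_genera_by_bicluster",
    "log2_fold_change",
    "mann_whitney",
    "stars",
    "contrast_table",
]

DEFAULT_PAIRS = (("HFD", "HFD+XOS"), ("HFD", "LFD"))


@dataclass
class BiclusterSummary:
    """Per-sample, per-bicluster abundance summaries.

    ``metabolite_sums`` are raw-scale sums (samples x k); ``genus_clr``
    are clr values of the within-bicluster relative-abundance sums, so
    each row sums to zero.
    """

    metabolite_sums: pd.DataFrame
    genus_clr: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.metabolite_sums.to_numpy() < -1e-12).any():
            raise ValidationError("metabolite bicluster sums must be nonnegative")
        rowsum = np.abs(self.genus_clr.to_numpy().sum(axis=1)).max(initial=0.0)
        if rowsum > 1e-8:
            raise ValidationError("genus clr-of-sums rows must sum to 0")

    def mean_centered(self) -> "tuple[pd.DataFrame, pd.DataFrame]":
        """Column-wise mean-centered copies (plotting convention only)."""
        return (
            self.metabolite_sums - self.metabolite_sums.mean(axis=0),
            self.genus_clr - self.genus_clr.mean(axis=0),
        )


def _check_labels(labels, n_features: int, k: int | None) -> tuple[np.ndarray, int]:
    labels = np.asarray(labels)
    if labels.shape != (n_features,):
        raise ValidationError("one label per feature is required")
    if k is None:
        k = int(labels.max()) + 1
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= k:
        raise ValidationError(f"labels out of range [0, {k})")
    return labels, k


def sum_metabolites_by_bicluster(metabolites, row_labels, k: int | None = None) -> pd.DataFrame:
    """Sum raw metabolite abundances within each bicluster, per sample."""
    df = metabolites.data if hasattr(metabolites, "data") else metabolites
    labels, k = _check_labels(row_labels, df.shape[1], k)
    out = pd.DataFrame(
        {f"bicluster_{b}": df.loc[:, labels == b].sum(axis=1) for b in range(k)}
    )
    return out


def sum_genera_by_bicluster(
    genus_relabund: pd.DataFrame,
    col_labels,
    k: int | None = None,
    zero_fallback: bool = True,
) -> pd.DataFrame:
    """clr of within-bicluster relative-abundance sums, per sample.

    Requires every bicluster sum to be strictly positive; when a sum is
    zero and ``zero_fallback`` is enabled, half the smallest positive
    block sum is substituted before the clr (and the substitution is
    logged), otherwise a domain error is raised.
    """
    labels, k = _check_labels(col_labels, genus_relabund.shape[1], k)
    sums = pd.DataFrame(
        {f"bicluster_{b}": genus_relabund.loc[:, labels == b].sum(axis=1) for b in range(k)}
    )
    values = sums.to_numpy()
    if (values <= 0).any():
        if not zero_fallback:
            bad = np.argwhere(values <= 0)[0]
            raise ValidationError(
                f"bicluster {bad[1]} has zero relative abundance in sample "
                f"{sums.index[bad[0]]!r}"
            )
        eps = values[values > 0].min() / 2.0
        n_bad = int((values <= 0).sum())
        logger.warning(
            "sum_genera_by_bicluster: %d zero block sum(s) replaced by %.3g", n_bad, eps
        )
        sums = sums.mask(sums <= 0, eps)
    return clr_transform(sums).data


def log2_fold_change(
    values: pd.Series,
    design: SampleDesign,
    group_a: str,
    group_b: str,
) -> tuple[float, bool]:
    """log2 of the ratio of group means, a over b.

    A zero group mean is replaced by half the smallest positive value of
    the feature across all samples; the returned flag records whether the
    replacement was used.  Both means zero yields NaN (undefined).
    """
    a_ids = design.samples_in_group(group_a)
    b_ids = design.samples_in_group(group_b)
    if not a_ids or not b_ids:
        raise ValidationError(f"empty group among {group_a!r}, {group_b!r}")
    mean_a = float(values.loc[a_ids].mean())
    mean_b = float(values.loc[b_ids].mean())
    if mean_a == 0.0 and mean_b == 0.0:
        return float("nan"), False
    if mean_a < 0.0 or mean_b < 0.0:
        # a ratio of means is only meaningful on a nonnegative scale
        # (e.g. clr summaries can have negative group means)
        return float("nan"), False
    eps_used = False
    if mean_a == 0.0 or mean_b == 0.0:
        positive = values[values > 0]
        if positive.empty:
            return float("nan"), False
        eps = float(positive.min()) / 2.0
        mean_a = mean_a or eps
        mean_b = mean_b or eps
        eps_used = True
        logger.warning("log2_fold_change: zero group mean replaced by eps=%.3g", eps)
    return float(np.log2(mean_a / mean_b)), eps_used


_EXACT_MAX_N = 16


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs with a_i > b_j (ties half) and is reported as
    min(U_a, U_b).  The p-value is exact (complete enumeration of rank
    assignments) when n_a + n_b <= 16 and there are no ties, otherwise
    the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    u_a = float(res.statistic)
    u_min = min(u_a, a.size * b.size - u_a)
    return u_min, float(min(res.pvalue, 1.0))


def stars(p: float) -> str:
    """Significance stars: ** for p < 0.01, * for p < 0.05, else ''."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def contrast_table(
    features: pd.DataFrame,
    design: SampleDesign,
    pairs=DEFAULT_PAIRS,
    bicluster_of: dict[str, int] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-feature group contrasts in the layout of a results table.

    ``features`` is samples x features on the scale the contrast should
    use (relative abundance for genera, raw for metabolites, or bicluster
    summaries).  One row per feature and pair with log2 fold change,
    Mann-Whitney U and p, and significance stars; rows are ordered by
    bicluster (when a membership map is given) then feature.  ``adjust``
    switches on Benjamini-Hochberg correction within each pair before
    starring.
    """
    available = set(design.group)
    for pair in pairs:
        for g in pair:
            if g not in available:
                raise ValidationError(
                    f"group {g!r} not present; available groups: {sorted(available)}"
                )
    records = []
    for feat in features.columns:
        values = features[feat]
        constant = values.nunique() <= 1
        for group_a, group_b in pairs:
            if constant:
                fc, eps_used, u, p = 0.0, False, None, 1.0
                a_ids = design.samples_in_group(group_a)
                b_ids = design.samples_in_group(group_b)
                u = len(a_ids) * len(b_ids) / 2.0
            else:
                fc, eps_used = log2_fold_change(values, design, group_a, group_b)
                u, p = mann_whitney(
                    values.loc[design.samples_in_group(group_a)].to_numpy(),
                    values.loc[design.samples_in_group(group_b)].to_numpy(),
                )
            records.append(
                {
                    "feature": feat,
                    "bicluster": bicluster_of.get(feat) if bicluster_of else None,
                    "group_a": group_a,
                    "group_b": group_b,
                    "log2fc": fc,
                    "eps_used": eps_used,
                    "U": u,
                    "p": p,
                }
            )
    out = pd.DataFrame.from_records(records)
    if adjust:
        for pair in pairs:
            mask = (out["group_a"] == pair[0]) & (out["group_b"] == pair[1])
            out.loc[mask, "p"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    out["stars"] = out["p"].map(stars)
    if bicluster_of:
        out = out.sort_values(
            ["bicluster", "feature", "group_a", "group_b"], kind="stable"
        ).reset_index(drop=True)
    return out
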