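"""Bipartite spectral graph partitioning (Dhillon-style co-clustering).

A metabolites x genera correlation matrix A is treated as the weighted
adjacency of a bipartite graph.  The matrix is made nonnegative (by
default through the strictly monotone shift r -> (r+1)/2, so the strongest
positive correlations remain the largest weights), normalized as

    An = D1^{-1/2} A' D2^{-1/2},

with D1/D2 the diagonal row/column sum matrices, and embedded through the
singular vectors u_2..u_{l+1}, v_2..v_{l+1} of An with l = ceil(log2 k).
Rows and columns are stacked in the common space

    Z = [ D1^{-1/2} U_l ; D2^{-1/2} V_l ]

and jointly clustered with k-means, so each metabolite and each genus ends
up in exactly one of k biclusters.  The number of biclusters is selected
by scanning a grid of k and scoring the induced row and column partitions
with Silhouette and Calinski-Harabasz indices on each axis of A.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics
from sklearn.cluster import KMeans

from .correlation import CorrelationMatrix
from .tables import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DegeneracyError",
    "BiclusterModel",
    "SelectionTrace",
    "scale_normalize",
    "fit_cocluster",
    "silhouette_score",
    "calinski_harabasz",
    "select_k",
    "reorder_blockdiagonal",
]


class DegeneracyError(ValueError):
    """Row/column sums unusable for the spectral normalization."""


@dataclass
class BiclusterModel:
    """A fitted k-way co-clustering of a correlation matrix."""

    k: int
    row_ids: list[str]
    col_ids: list[str]
    row_labels: np.ndarray
    col_labels: np.ndarray
    embedding: np.ndarray          # (m + n) x l stacked row/column coordinates
    singular_values: np.ndarray
    shift: str
    seed: int
    n_init: int

    def __post_init__(self) -> None:
        for lab, n in ((self.row_labels, len(self.row_ids)), (self.col_labels, len(self.col_ids))):
            lab = np.asarray(lab)
            if lab.shape != (n,):
                raise ValidationError("label vector length mismatch")
            if lab.min(initial=0) < 0 or lab.max(initial=0) >= self.k:
                raise ValidationError("labels out of range [0, k)")
        used = set(self.row_labels) | set(self.col_labels)
        empty = sorted(set(range(self.k)) - used)
        if empty:
            logger.warning("bicluster(s) %s received no rows or columns", empty)

    @property
    def n_singular_vectors(self) -> int:
        return self.embedding.shape[1]

    def row_members(self, b: int) -> list[str]:
        return [f for f, lab in zip(self.row_ids, self.row_labels) if lab == b]

    def col_members(self, b: int) -> list[str]:
        return [f for f, lab in zip(self.col_ids, self.col_labels) if lab == b]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "shift": self.shift,
            "seed": self.seed,
            "n_init": self.n_init,
            "row_labels": {f: int(l) for f, l in zip(self.row_ids, self.row_labels)},
            "col_labels": {f: int(l) for f, l in zip(self.col_ids, self.col_labels)},
            "singular_values": [float(s) for s in self.singular_values],
        }


@dataclass
class SelectionTrace:
    """Score curves over a k grid and the data-driven choice of k.

    Scores may be NaN where a partition makes an index undefined (e.g. a
    single non-empty cluster); such k stay eligible through the remaining
    curves.  ``chosen_k`` maximizes the mean of the four min-max normalized
    curves (ties break toward smaller k).
    """

    k_grid: list[int]
    scores: pd.DataFrame  # index k; silhouette/calinski x metabolites/genera
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out.insert(0, "k", self.k_grid)
        return out


def _as_matrix(A) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(A, CorrelationMatrix):
        return A.rho.to_numpy(dtype=float), A.row_ids, A.col_ids
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(dtype=float), [str(i) for i in A.index], [str(c) for c in A.columns]
    A = np.asarray(A, dtype=float)
    return A, [str(i) for i in range(A.shape[0])], [str(j) for j in range(A.shape[1])]


def scale_normalize(A, shift: str = "half"):
    """Shift (optionally) and bi-normalize a matrix for the spectral step.

    With ``shift='half'`` the elementwise map r -> (r+1)/2 first takes a
    correlation matrix onto [0, 1]; with ``shift='none'`` the matrix is
    used as-is and every row and column sum must be strictly positive.

    Returns ``(An, d1, d2)`` where ``An = diag(d1)^{-1/2} A' diag(d2)^{-1/2}``
    and d1, d2 are the row and column sums of the shifted matrix A'.
    """
    A, _, _ = _as_matrix(A)
    if A.ndim != 2 or min(A.shape) < 2:
        raise ValidationError(f"need a 2-D matrix with both sides >= 2, got shape {A.shape}")
    if not np.isfinite(A).all():
        raise ValidationError("matrix contains non-finite entries")
    if shift == "half":
        Ap = (A + 1.0) / 2.0
    elif shift == "none":
        Ap = A
    else:
        raise ValueError(f"shift must be 'half' or 'none', got {shift!r}")
    d1 = Ap.sum(axis=1)
    d2 = Ap.sum(axis=0)
    if (d1 <= 0).any() or (d2 <= 0).any():
        raise DegeneracyError(
            "nonpositive row or column sum; use shift='half' for matrices "
            "with negative entries"
        )
    An = Ap / np.sqrt(d1)[:, None] / np.sqrt(d2)[None, :]
    return An, d1, d2


def _n_singular_vectors(k: int) -> int:
    return max(1, math.ceil(math.log2(k)))


def fit_cocluster(
    A,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    shift: str = "half",
) -> BiclusterModel:
    """Fit a k-way spectral co-clustering of a (correlation) matrix.

    Deterministic given ``(A, k, seed, n_init)``.
    """
    values, row_ids, col_ids = _as_matrix(A)
    m, n = values.shape
    if not (2 <= k <= min(m, n)):
        raise ValidationError(f"k must be in [2, min(m, n)] = [2, {min(m, n)}], got {k}")
    An, d1, d2 = scale_normalize(values, shift=shift)
    l = _n_singular_vectors(k)
    try:
        U, s, Vt = np.linalg.svd(An, full_matrices=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - numerical edge
        raise ValidationError(f"SVD failed: {exc}") from exc
    # never cut inside a run of (numerically) tied singular values: with
    # equal-constant blocks the leading value is k-fold degenerate and an
    # arbitrary slice of that subspace can collapse two blocks
    tol = 1e-8 * max(s[0], 1.0)
    while l + 1 < min(len(s), min(m, n) - 1) and s[l + 1] > s[l] - tol:
        l += 1
    # discard the leading pair; keep the next l left/right singular vectors
    Ul = U[:, 1 : l + 1]
    Vl = Vt[1 : l + 1, :].T
    Z = np.vstack([Ul / np.sqrt(d1)[:, None], Vl / np.sqrt(d2)[:, None]])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    labels = _canonical_labels(labels)
    return BiclusterModel(
        k=k,
        row_ids=row_ids,
        col_ids=col_ids,
        row_labels=labels[:m],
        col_labels=labels[m:],
        embedding=Z,
        singular_values=s[: l + 1],
        shift=shift,
        seed=seed,
        n_init=n_init,
    )


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (stable tie-break)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def silhouette_score(points, labels) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b), Euclidean distance.

    Singleton clusters contribute s = 0; a single cluster overall is an
    error (the score is undefined there, not zero).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette is undefined for a single cluster")
    if len(uniq) >= len(labels):
        # every point a singleton: all s = 0 by convention
        return 0.0
    return float(_skmetrics.silhouette_score(points, labels))


def calinski_harabasz(points, labels) -> float:
    """Calinski-Harabasz variance-ratio score, [B/(k-1)] / [W/(p-k)].

    A perfectly tight clustering (W = 0) is reported as +inf with a
    warning rather than an error.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    p, k = len(labels), len(uniq)
    if not (2 <= k < p):
        raise ValidationError(f"need 2 <= k < n_points, got k={k}, n={p}")
    centroids = {c: points[labels == c].mean(axis=0) for c in uniq}
    W = sum(((points[labels == c] - centroids[c]) ** 2).sum() for c in uniq)
    if W == 0:
        warnings.warn("zero within-cluster dispersion; CH reported as +inf")
        return float("inf")
    return float(_skmetrics.calinski_harabasz_score(points, labels))


def _axis_scores(values: np.ndarray, labels: np.ndarray, transpose: bool) -> tuple[float, float]:
    pts = values.T if transpose else values
    try:
        sil = silhouette_score(pts, labels)
    except ValidationError:
        sil = float("nan")
    try:
        ch = calinski_harabasz(pts, labels)
    except ValidationError:
        ch = float("nan")
    return sil, ch


def select_k(
    A,
    k_grid=None,
    seed: int = 0,
    n_init: int = 10,
    shift: str = "half",
) -> SelectionTrace:
    """Scan a grid of k, scoring the row and column partitions of A.

    For each k the model's metabolite (row) partition is scored in the
    space of row vectors of A and the genus (column) partition in the
    space of column vectors; the chosen k maximizes the mean of the four
    min-max normalized curves.  The full trace is returned so that the
    automatic choice can be overridden by inspection.
    """
    values, _, _ = _as_matrix(A)
    m, n = values.shape
    if k_grid is None:
        k_grid = range(2, 39)
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValidationError("empty k grid")
    kmax = min(m, n)
    truncated = [k for k in k_grid if k > kmax]
    if truncated:
        logger.warning("k grid truncated at min(m, n) = %d (dropped %s)", kmax, truncated)
        k_grid = [k for k in k_grid if k <= kmax]
    if not k_grid:
        raise ValidationError(f"no k in grid is <= min(m, n) = {kmax}")
    rows = []
    for k in k_grid:
        model = fit_cocluster(values, k=k, seed=seed, n_init=n_init, shift=shift)
        sil_m, ch_m = _axis_scores(values, model.row_labels, transpose=False)
        sil_g, ch_g = _axis_scores(values, model.col_labels, transpose=True)
        rows.append(
            {
                "silhouette_metabolites": sil_m,
                "silhouette_genera": sil_g,
                "calinski_metabolites": ch_m,
                "calinski_genera": ch_g,
            }
        )
    scores = pd.DataFrame(rows, index=pd.Index(k_grid, name="k"))
    if len(k_grid) == 1:
        return SelectionTrace(k_grid=k_grid, scores=scores, chosen_k=k_grid[0])
    finite = scores.replace([np.inf, -np.inf], np.nan)
    # CH is a variance ratio spanning orders of magnitude; compare it on
    # the log scale so min-max normalization is not dominated by spikes
    for col in ("calinski_metabolites", "calinski_genera"):
        finite[col] = np.log(finite[col].clip(lower=np.finfo(float).tiny))
    span = finite.max() - finite.min()
    span = span.replace(0.0, 1.0)  # flat curve contributes equally everywhere
    normalized = (finite - finite.min()) / span
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        combined = normalized.mean(axis=1, skipna=True)
    # ties (identical partitions at several k yield scores equal up to
    # float summation order) break toward the smallest k
    eligible = combined[combined >= combined.max() - 1e-9]
    chosen_k = int(eligible.index.min())
    return SelectionTrace(k_grid=k_grid, scores=scores, chosen_k=chosen_k)


def reorder_blockdiagonal(A, model: BiclusterModel):
    """Permute A so biclusters appear as diagonal blocks (heatmap layout).

    Rows sort by (row label, original position), columns likewise.
    Returns (permuted DataFrame, row order, column order, row block
    boundaries, column block boundaries); the boundaries are cumulative
    block sizes suitable for drawing separator lines.
    """
    values, row_ids, col_ids = _as_matrix(A)
    if values.shape != (len(model.row_ids), len(model.col_ids)):
        raise ValidationError("matrix shape does not match the fitted model")
    row_order = np.lexsort((np.arange(len(row_ids)), model.row_labels))
    col_order = np.lexsort((np.arange(len(col_ids)), model.col_labels))
    permuted = pd.DataFrame(
        values[np.ix_(row_order, col_order)],
        index=[row_ids[i] for i in row_order],
        columns=[col_ids[j] for j in col_order],
    )
    row_bounds = np.cumsum(np.bincount(model.row_labels, minlength=model.k))[:-1]
    col_bounds = np.cumsum(np.bincount(model.col_labels, minlength=model.k))[:-1]
    return permuted, row_order, col_order, list(map(int, row_bounds)), list(map(int, col_bounds))
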