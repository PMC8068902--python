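"""Downstream associations: biomarker heatmaps, PCA ordinations, CV classification.

Bicluster summaries (or individual features) are related to externally
measured biomarkers via Spearman correlation with pairwise-complete
handling of missing biomarker values; biomarker rows of the heatmap are
ordered by average-linkage hierarchical clustering of their correlation
profiles.  PCA ordinations carry 95% confidence ellipses per diet group,
and a pluggable gradient-boosted classifier quantifies how well a feature
set separates the diet factors under stratified 5-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold

from .summaries import stars as _stars
from .tables import BiomarkerTable, SampleDesign, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationHeatmap",
    "PcaResult",
    "CvReport",
    "biomarker_associations",
    "pca",
    "cv_classification",
]


@dataclass
class AssociationHeatmap:
    """Biomarkers (rows) x summaries/features (columns) Spearman heatmap."""

    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    row_order: list[str]
    linkage_method: str = "average"

    def ordered(self) -> "AssociationHeatmap":
        return AssociationHeatmap(
            rho=self.rho.loc[self.row_order],
            p=self.p.loc[self.row_order],
            stars=self.stars.loc[self.row_order],
            row_order=self.row_order,
            linkage_method=self.linkage_method,
        )


@dataclass
class PcaResult:
    """Scores, loadings, explained variance and per-group 95% ellipses."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    ellipses: dict[str, dict] = field(default_factory=dict)
    dropped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if ((evr < -1e-12) | (evr > 1 + 1e-12)).any():
            raise ValidationError("explained variance ratios must lie in [0, 1]")
        if (np.diff(evr) > 1e-12).any():
            raise ValidationError("explained variance ratios must be non-increasing")
        if evr.sum() > 1 + 1e-9:
            raise ValidationError("explained variance ratios must sum to <= 1")


@dataclass
class CvReport:
    """Stratified k-fold classification metrics and feature importances."""

    task: str
    feature_scope: str
    fold_accuracy: list[float]
    fold_f1: list[float]
    mean_accuracy: float
    mean_f1: float
    importances: pd.Series

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "feature_scope": self.feature_scope,
            "fold_accuracy": self.fold_accuracy,
            "fold_f1": self.fold_f1,
            "mean_accuracy": self.mean_accuracy,
            "mean_f1": self.mean_f1,
            "importances": {k: float(v) for k, v in self.importances.items()},
        }


def _pairwise_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan"), float("nan")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def biomarker_associations(
    columns: pd.DataFrame,
    biomarkers: BiomarkerTable | pd.DataFrame,
) -> AssociationHeatmap:
    """Spearman-correlate each biomarker against each summary column.

    Missing biomarker cells are handled pairwise-complete; biomarkers
    with fewer than 3 non-missing samples are excluded with a warning.
    Rows are ordered by average-linkage clustering on 1 - rho distance
    between biomarker correlation profiles.
    """
    bio = biomarkers.data if hasattr(biomarkers, "data") else biomarkers
    if list(bio.index) != list(columns.index):
        raise ValidationError("biomarkers and summaries are not sample-aligned")
    usable = []
    for b in bio.columns:
        if bio[b].notna().sum() < 3:
            logger.warning("biomarker %r has < 3 non-missing samples; excluded", b)
        else:
            usable.append(b)
    rho = pd.DataFrame(index=usable, columns=columns.columns, dtype=float)
    pvals = pd.DataFrame(index=usable, columns=columns.columns, dtype=float)
    for b in usable:
        x = bio[b].to_numpy(dtype=float)
        for c in columns.columns:
            r, p = _pairwise_spearman(x, columns[c].to_numpy(dtype=float))
            rho.loc[b, c] = r
            pvals.loc[b, c] = p
    star = pvals.apply(lambda col: col.map(_stars))
    row_order = list(usable)
    if len(usable) > 2:
        profiles = rho.fillna(0.0).to_numpy()
        # correlation between biomarker profiles; distance 1 - rho
        with np.errstate(invalid="ignore"):
            prof_corr = np.corrcoef(profiles)
        prof_corr = np.nan_to_num(prof_corr, nan=0.0)
        dist = 1.0 - prof_corr
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        order = leaves_list(average(squareform(dist, checks=False)))
        row_order = [usable[i] for i in order]
    return AssociationHeatmap(rho=rho, p=pvals, stars=star, row_order=row_order)


def _group_ellipse(points: np.ndarray, confidence: float = 0.95) -> dict:
    center = points.mean(axis=0)
    if points.shape[0] < 3:
        return {"center": center.tolist(), "width": 0.0, "height": 0.0, "angle_deg": 0.0}
    cov = np.cov(points, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    scale = stats.chi2.ppf(confidence, df=2)
    # eigh returns ascending order; major axis last
    width, height = 2.0 * np.sqrt(evals[::-1] * scale)
    major = evecs[:, -1]
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    return {
        "center": center.tolist(),
        "width": float(width),
        "height": float(height),
        "angle_deg": angle,
    }


def pca(
    features: pd.DataFrame,
    standardize: bool = True,
    n_components: int = 2,
    design: SampleDesign | None = None,
) -> PcaResult:
    """PCA ordination with deterministic component signs.

    Features are mean-centered (and unit-scaled when ``standardize``);
    constant features are dropped with a warning when standardizing.
    Each component's sign is fixed so its largest-magnitude loading is
    positive.  With a design, 95% score-covariance ellipses (chi-square
    2-df quantile) are computed per group on the first two components.
    """
    if features.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    if features.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 features")
    X = features.astype(float)
    dropped: list[str] = []
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dropped = list(sd.index[sd == 0])
        if dropped:
            logger.warning("pca: dropping constant feature(s) %s", dropped)
            X = X.drop(columns=dropped)
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    else:
        X = X - X.mean(axis=0)
    n_components = min(n_components, X.shape[1], X.shape[0] - 1)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X.to_numpy())
    loadings = model.components_.T.copy()
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=features.index, columns=comp_names)
    loadings_df = pd.DataFrame(loadings, index=X.columns, columns=comp_names)
    ellipses: dict[str, dict] = {}
    if design is not None and n_components >= 2:
        for group in sorted(set(design.group)):
            ids = design.samples_in_group(group)
            pts = scores_df.loc[ids, ["PC1", "PC2"]].to_numpy()
            ellipses[group] = _group_ellipse(pts)
    return PcaResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=model.explained_variance_ratio_,
        ellipses=ellipses,
        dropped_features=dropped,
    )


_TASKS = {"overall_diet": "group", "fat": "fat", "xos": "xos"}


def _default_classifier(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=100,
        max_depth=3,
        random_state=seed,
        verbosity=0,
        eval_metric="logloss",
    )


def cv_classification(
    features: pd.DataFrame,
    design: SampleDesign,
    task: str = "overall_diet",
    feature_scope: str = "all",
    classifier=None,
    folds: int = 5,
    seed: int = 0,
) -> CvReport:
    """Stratified k-fold classification of a diet factor from features.

    ``features`` is the samples x features design matrix on whatever
    scale the caller prepared (raw metabolites, clr genera, or their
    concatenation); restriction to a bicluster is done by passing only
    that bicluster's columns.  Accuracy and macro-F1 are averaged over
    folds; importances are averaged over the per-fold fitted classifiers.
    """
    if task not in _TASKS:
        raise ValidationError(f"task must be one of {sorted(_TASKS)}, got {task!r}")
    if list(features.index) != list(design.sample_ids):
        raise ValidationError("features and design are not sample-aligned")
    y_raw = design.frame[_TASKS[task]]
    classes = sorted(y_raw.unique())
    counts = y_raw.value_counts()
    if (counts < folds).any():
        small = list(counts.index[counts < folds])
        raise ValidationError(
            f"class(es) {small} have fewer than {folds} members; use fewer folds"
        )
    y = y_raw.map({c: i for i, c in enumerate(classes)}).to_numpy()
    X = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, f1s, imps = [], [], []
    for train, test in skf.split(X, y):
        clf = classifier if classifier is not None else _default_classifier(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        accs.append(float(accuracy_score(y[test], pred)))
        f1s.append(float(f1_score(y[test], pred, average="macro")))
        if hasattr(clf, "feature_importances_"):
            imps.append(np.asarray(clf.feature_importances_, dtype=float))
    importances = (
        pd.Series(np.mean(imps, axis=0), index=features.columns)
        if imps
        else pd.Series(dtype=float)
    )
    importances = importances.sort_values(ascending=False)
    return CvReport(
        task=task,
        feature_scope=feature_scope,
        fold_accuracy=accs,
        fold_f1=f1s,
        mean_accuracy=float(np.mean(accs)),
        mean_f1=float(np.mean(f1s)),
        importances=importances,
    )
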