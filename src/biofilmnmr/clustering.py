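"""PCA + K-means clustering of monosaccharide temporal profiles.

Each monosaccharide is summarized by the ratio of its integral in the
biofilm to that in the spent medium, one ratio per day (days 2–5 by
default, giving a length-4 profile per sugar).  Profiles are z-scored
column-wise (population standard deviation, the StandardScaler
convention), projected onto two principal components, and clustered with
K-means; the number of clusters is chosen by maximizing the silhouette
score over a candidate range unless overridden.

Sugars with any missing medium integral over the requested days are
dropped with a logged reason rather than imputed — a sugar undetected in
the medium has no defined partition ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .errors import ComputationError, InputError

logger = logging.getLogger(__name__)

#: Sugar units resolvable in the anomeric region of the biofilm spectra.
SUGAR_LABELS = ("Glc", "GlcA", "GlcN", "GlcNAc", "MurNAc", "Gal", "GalN", "GalNAc")

DEFAULT_DAYS = (2, 3, 4, 5)
DEFAULT_K_RANGE = (2, 3, 4, 5, 6)


@dataclass
class StandardizedMatrix:
    """A z-scored feature matrix carrying its standardization parameters."""

    values: pd.DataFrame
    mean: np.ndarray
    sd: np.ndarray

    def inverse(self) -> pd.DataFrame:
        """Undo the standardization (round-trips to the input)."""
        return self.values * self.sd + self.mean


@dataclass
class ClusterResult:
    """PCA scores, silhouette-guided k selection and labels per sugar."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    k: int
    labels: pd.Series
    silhouette_by_k: dict[int, float | None]
    seed: int
    dropped: dict[str, str] = field(default_factory=dict)


def _tidy_to_wide(table: pd.DataFrame, compartment: str) -> pd.DataFrame:
    required = {"sugar", "day", "integral"}
    if not required.issubset(table.columns):
        raise InputError(
            f"{compartment} table must have columns {sorted(required)}, "
            f"got {list(table.columns)}"
        )
    if table.duplicated(subset=["sugar", "day"]).any():
        raise InputError(f"duplicate (sugar, day) rows in {compartment} table")
    return table.pivot(index="sugar", columns="day", values="integral")


def compute_ratio_features(
    biofilm: pd.DataFrame,
    medium: pd.DataFrame,
    days: tuple[int, ...] = DEFAULT_DAYS,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Biofilm/medium integral ratios per sugar over the requested days.

    Both tables are tidy frames with columns ``sugar``, ``day``,
    ``integral`` (missing integrals as NaN or absent rows).  Returns the
    feature matrix (rows = retained sugars, columns = days) and a dict of
    dropped sugars with the reason for each drop.

    Raises
    ------
    ComputationError
        If a retained sugar has a zero medium integral (the ratio is then
        undefined); the offending cell is named.
    """
    bio = _tidy_to_wide(biofilm, "biofilm")
    med = _tidy_to_wide(medium, "medium")
    dropped: dict[str, str] = {}
    rows = {}
    for sugar in bio.index:
        missing = [
            d
            for d in days
            if d not in med.columns
            or sugar not in med.index
            or pd.isna(med.loc[sugar, d])
            or d not in bio.columns
            or pd.isna(bio.loc[sugar, d])
        ]
        if missing:
            reason = f"missing integral(s) for day(s) {missing}"
            dropped[sugar] = reason
            logger.info("dropping %s: %s", sugar, reason)
            continue
        for d in days:
            if med.loc[sugar, d] == 0:
                raise ComputationError(
                    f"medium integral is zero for sugar {sugar!r}, day {d}: ratio undefined"
                )
        rows[sugar] = [bio.loc[sugar, d] / med.loc[sugar, d] for d in days]
    feats = pd.DataFrame.from_dict(rows, orient="index", columns=list(days))
    feats.index.name = "sugar"
    feats.columns.name = "day"
    return feats, dropped


def standardize(matrix: pd.DataFrame) -> StandardizedMatrix:
    """Column-wise z-scores using the population (divide-by-n) sd."""
    if len(matrix) < 2:
        raise InputError(f"need >= 2 rows to standardize, got {len(matrix)}")
    if matrix.isna().any().any():
        raise InputError("feature matrix contains missing values; drop rows first")
    scaler = StandardScaler().fit(matrix.values)
    sd = np.sqrt(scaler.var_)
    if np.any(sd == 0):
        const = [str(c) for c, s in zip(matrix.columns, sd) if s == 0]
        raise InputError(f"constant column(s) {const}: standard deviation undefined")
    z = pd.DataFrame(
        scaler.transform(matrix.values), index=matrix.index, columns=matrix.columns
    )
    return StandardizedMatrix(values=z, mean=scaler.mean_, sd=sd)


def pca_2d(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Two-component PCA with a deterministic sign convention.

    Scores come from the SVD of the column-centered matrix; each
    component's sign is fixed so that its largest-magnitude loading is
    positive.  Returns (scores, explained-variance ratios, loadings).
    """
    if len(matrix) < 3:
        raise InputError(f"need >= 3 rows for a 2-component PCA, got {len(matrix)}")
    X = np.asarray(matrix, dtype=float)
    if not np.any(X - X.mean(axis=0)):
        raise ComputationError("rank-0 matrix: all rows identical after centering")
    n_comp = min(2, min(X.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_comp):
        i = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, i] < 0:
            pca.components_[j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return (
        pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        pca.explained_variance_ratio_.copy(),
        pd.DataFrame(pca.components_, index=comp_names, columns=matrix.columns),
    )


def cluster_scores(
    scores: pd.DataFrame,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int = 0,
    n_init: int = 50,
    force_k: int | None = None,
) -> tuple[int, pd.Series, dict[int, float | None]]:
    """K-means over candidate k with silhouette-guided selection.

    Returns (selected k, labels, silhouette per candidate k).  Silhouette
    values that are undefined (e.g. duplicate points collapsing a cluster)
    are reported as None.  ``force_k`` overrides the silhouette choice —
    the route by which prior knowledge can fix k.
    """
    n = len(scores)
    k_range = tuple(int(k) for k in k_range)
    if any(k >= n for k in k_range) or (force_k is not None and force_k >= n):
        raise InputError(f"every candidate k must be < n rows ({n}); got {k_range}")
    if any(k < 2 for k in k_range):
        raise InputError(f"candidate k must be >= 2, got {k_range}")
    X = np.asarray(scores, dtype=float)
    sil: dict[int, float | None] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        labels_by_k[k] = km.labels_
        try:
            if len(np.unique(km.labels_)) < k:
                # duplicate points collapsed a cluster: silhouette undefined
                # for this k, reported as missing
                raise ValueError("fewer distinct clusters than requested")
            sil[k] = float(silhouette_score(X, km.labels_))
        except ValueError:
            sil[k] = None
    if force_k is not None:
        if force_k not in labels_by_k:
            km = KMeans(n_clusters=force_k, n_init=n_init, random_state=seed).fit(X)
            labels_by_k[force_k] = km.labels_
        best = int(force_k)
    else:
        defined = {k: s for k, s in sil.items() if s is not None}
        if not defined:
            raise ComputationError("silhouette undefined for every candidate k")
        best = max(defined, key=defined.__getitem__)
    labels = pd.Series(labels_by_k[best], index=scores.index, name="cluster")
    return best, labels, sil


class SugarProfileClustering(BaseEstimator):
    """Standardize → 2-component PCA → silhouette-guided K-means.

    A transform-shaped estimator over a ratio feature matrix (rows =
    sugars, columns = days).  ``fit`` learns the scaler, the principal
    axes and the cluster assignment; ``transform`` projects new profiles
    onto the fitted axes.

    Attributes
    ----------
    scores_ : DataFrame
        2-D PCA scores of the training sugars.
    explained_variance_ratio_ : ndarray
    loadings_ : DataFrame
    k_ : int
        Selected number of clusters.
    labels_ : Series
        Cluster label per sugar.
    silhouette_by_k_ : dict
    """

    def __init__(
        self,
        k_range: tuple[int, ...] = DEFAULT_K_RANGE,
        force_k: int | None = None,
        n_init: int = 50,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.force_k = force_k
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.standardized_ = standardize(X)
        self.scores_, self.explained_variance_ratio_, self.loadings_ = pca_2d(
            self.standardized_.values
        )
        self.k_, self.labels_, self.silhouette_by_k_ = cluster_scores(
            self.scores_,
            k_range=self.k_range,
            seed=self.random_state,
            n_init=self.n_init,
            force_k=self.force_k,
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()

    def transform(self, X):
        X = pd.DataFrame(X)
        z = (X - self.standardized_.mean) / self.standardized_.sd
        centered = z - self.standardized_.values.mean(axis=0)
        return centered.values @ self.loadings_.values.T


def cluster_sugars(
    biofilm: pd.DataFrame,
    medium: pd.DataFrame,
    days: tuple[int, ...] = DEFAULT_DAYS,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int = 0,
    n_init: int = 50,
    force_k: int | None = None,
) -> ClusterResult:
    """End-to-end: ratio features → standardize → PCA → K-means."""
    feats, dropped = compute_ratio_features(biofilm, medium, days)
    est = SugarProfileClustering(
        k_range=k_range, force_k=force_k, n_init=n_init, random_state=seed
    ).fit(feats)
    return ClusterResult(
        scores=est.scores_,
        explained_variance_ratio=est.explained_variance_ratio_,
        loadings=est.loadings_,
        k=est.k_,
        labels=est.labels_,
        silhouette_by_k=est.silhouette_by_k_,
        seed=seed,
        dropped=dropped,
    )


def plot_scores(result: ClusterResult, path) -> None:
    """Optional 2-D scatter of the PCA scores colored by cluster.

    Requires matplotlib (the ``plot`` extra); raises ImportError otherwise.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    scatter = ax.scatter(
        result.scores["PC1"], result.scores["PC2"], c=result.labels, cmap="tab10", s=60
    )
    for name, row in result.scores.iterrows():
        ax.annotate(str(name), (row["PC1"], row["PC2"]), fontsize=8,
                    xytext=(3, 3), textcoords="offset points")
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)" if len(evr) > 1 else "PC2")
    ax.set_title(f"K-means on PCA scores (k={result.k})")
    fig.colorbar(scatter, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_variance_from_ratio_table(
    features: pd.DataFrame,
) -> float:
    """Total variance (percent) captured by the first two components of a
    standardized ratio feature matrix — the headline PCA summary for a
    user-supplied per-sugar ratio table."""
    z = standardize(features).values
    _, evr, _ = pca_2d(z)
    return float(100.0 * evr.sum())
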