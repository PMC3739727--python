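"""Chemical-space exploration: descriptor pruning, scaling, PCA with
cross-validated predictive ability, and average-linkage clustering.

Estimators follow scikit-learn conventions (``fit`` / ``transform``,
``get_params``, trailing-underscore fitted attributes) and accept pandas
DataFrames so descriptor names survive the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import KFold


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class DescriptorReducer(BaseEstimator, TransformerMixin):
    """Remove uninformative and redundant descriptor columns.

    Stage 1 drops columns with any undefined (NaN) cell and columns constant
    over all rows.  Stage 2 is a greedy scan in fixed column order: each
    retained column eliminates every later column whose absolute Pearson
    correlation with it exceeds ``corr_threshold`` (the earlier column is
    kept, making the result deterministic and the output order a subsequence
    of the input order).

    Attributes
    ----------
    kept_columns_ : list of surviving column names
    removal_log_ : DataFrame with columns (dropped, kept, reason, r)
    """

    def __init__(self, corr_threshold: float = 0.95):
        self.corr_threshold = corr_threshold

    def fit(self, X, y=None):
        X = _as_frame(X)
        if len(X) < 2:
            raise ValueError("descriptor reduction needs at least 2 rows")
        log = []
        stage1 = []
        for col in X.columns:
            v = X[col]
            if v.isna().any():
                log.append({"dropped": col, "kept": None,
                            "reason": "undefined", "r": np.nan})
            elif v.nunique() <= 1:
                log.append({"dropped": col, "kept": None,
                            "reason": "constant", "r": np.nan})
            else:
                stage1.append(col)
        corr = X[stage1].corr().abs() if stage1 else pd.DataFrame()
        kept: list[str] = []
        dropped: set[str] = set()
        for i, col in enumerate(stage1):
            if col in dropped:
                continue
            kept.append(col)
            for other in stage1[i + 1:]:
                if other in dropped:
                    continue
                r = corr.loc[col, other]
                if r > self.corr_threshold:
                    dropped.add(other)
                    log.append({"dropped": other, "kept": col,
                                "reason": "correlated", "r": float(r)})
        if len(kept) < 2:
            raise ValueError("fewer than 2 descriptors survive reduction")
        self.kept_columns_ = kept
        self.removal_log_ = pd.DataFrame(
            log, columns=["dropped", "kept", "reason", "r"])
        return self

    def transform(self, X) -> pd.DataFrame:
        return _as_frame(X)[self.kept_columns_]


class ZScaler(BaseEstimator, TransformerMixin):
    """Column-wise standardization to mean 0, sample sd 1 (ddof=1).

    Chemometric convention: equal a-priori contribution of every descriptor.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if (self.scale_ == 0).any():
            bad = list(self.scale_.index[self.scale_ == 0])
            raise ValueError(f"constant columns must be reduced first: {bad}")
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        return (X - self.mean_) / self.scale_


def divide_by_mw(matrix: pd.DataFrame, mw_column: str = "MW") -> pd.DataFrame:
    """Divide every descriptor by the row's molecular weight (size
    neutralization); the MW column itself is excluded from the output."""
    if mw_column not in matrix.columns:
        raise ValueError(f"column {mw_column!r} missing")
    mw = matrix[mw_column]
    if (mw <= 0).any():
        raise ValueError("molecular weights must be positive")
    out = matrix.drop(columns=[mw_column])
    return out.div(mw, axis=0)


class ChemometricPCA(BaseEstimator, TransformerMixin):
    """PCA with cumulative R², cross-validated cumulative Q² and per-variable
    predicted variation.

    The model eigen-decomposes the covariance of the (already z-scaled)
    matrix.  Cumulative R²_k is the explained-variance share of the first k
    eigenvalues.  Q² uses row-wise K-fold cross-validation: for component j,
    PRESS_j is the residual sum of squares of held-out rows reconstructed
    from j loadings fit without them, SS_j the in-model residual after j-1
    components, and cumulative Q²_k = 1 - prod_{j<=k} PRESS_j/SS_j.
    Per-variable predicted variation is the fraction of each variable's
    variance explained by the retained components.
    """

    def __init__(self, n_components: int = 2, cv_folds: int = 7,
                 random_state: int = 0):
        self.n_components = n_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_frame(X)
        n, p = X.shape
        k = self.n_components
        if k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} exceeds min(rows-1, cols)={min(n - 1, p)}")
        self.columns_ = list(X.columns)
        A = X.to_numpy(float)
        Ac = A - A.mean(axis=0)
        # SVD of the centered matrix <=> eigen-decomposition of the covariance
        U, svals, Vt = np.linalg.svd(Ac, full_matrices=False)
        eig = svals ** 2 / (n - 1)
        self.eigenvalues_ = eig[:k]
        self.loadings_ = pd.DataFrame(Vt[:k].T, index=self.columns_,
                                      columns=[f"PC{i+1}" for i in range(k)])
        self.scores_ = pd.DataFrame(Ac @ Vt[:k].T, index=X.index,
                                    columns=self.loadings_.columns)
        total = eig.sum()
        self.r2_cum_ = np.cumsum(eig[:k]) / total
        self.q2_cum_ = self._cross_validated_q2(Ac, k)
        # per-variable modeled variance over the retained components
        recon = self.scores_.to_numpy() @ Vt[:k]
        ss_col = (Ac ** 2).sum(axis=0)
        rss_col = ((Ac - recon) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pv = np.where(ss_col > 0, 1.0 - rss_col / ss_col, 0.0)
        self.predicted_variation_ = pd.Series(pv, index=self.columns_)
        return self

    def _cross_validated_q2(self, Ac: np.ndarray, k: int) -> np.ndarray:
        n = Ac.shape[0]
        folds = min(self.cv_folds, n)
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=self.random_state)
        press = np.zeros(k)
        for train, test in kf.split(Ac):
            Xtr = Ac[train]
            mu = Xtr.mean(axis=0)
            _, _, Vt = np.linalg.svd(Xtr - mu, full_matrices=False)
            Xte = Ac[test] - mu
            for j in range(1, k + 1):
                P = Vt[:j].T
                resid = Xte - (Xte @ P) @ P.T
                press[j - 1] += (resid ** 2).sum()
        total_ss = (Ac ** 2).sum()
        # in-model residual SS after j-1 components
        full_eig = np.linalg.svd(Ac, compute_uv=False) ** 2
        rss_after = total_ss - np.concatenate([[0.0], np.cumsum(full_eig)])
        denom = rss_after[:k]
        # once the data are fully explained nothing remains to predict;
        # the ratio saturates at 1 (Q² stops improving) instead of dividing by 0
        safe = denom > 1e-12 * max(total_ss, 1.0)
        ratios = np.where(safe, press / np.where(safe, denom, 1.0), 1.0)
        return 1.0 - np.cumprod(ratios)

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)[self.columns_]
        Ac = X.to_numpy(float) - X.to_numpy(float).mean(axis=0)
        return pd.DataFrame(Ac @ self.loadings_.to_numpy(),
                            index=X.index, columns=self.loadings_.columns)

    def summary(self) -> pd.DataFrame:
        """Eigenvalue / cumulative R² / cumulative Q² table per component."""
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues_,
            "cumulative_r2": self.r2_cum_,
            "cumulative_q2": self.q2_cum_,
        }, index=pd.Index(range(1, len(self.eigenvalues_) + 1),
                          name="component"))


def feature_select(model: ChemometricPCA, threshold: float = 0.30) -> list[str]:
    """Descriptors whose predicted variation exceeds the threshold."""
    pv = model.predicted_variation_
    selected = list(pv.index[pv > threshold])
    if not selected:
        raise ValueError(
            f"no descriptor has predicted variation > {threshold}; "
            f"lower the threshold")
    return selected


class Dendrogram:
    """Binary merge tree from average-linkage clustering."""

    def __init__(self, linkage_matrix: np.ndarray, leaf_ids: list[str]):
        self.linkage_matrix = linkage_matrix
        self.leaf_ids = list(leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage_matrix, t=k,
                                  criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{parent_height:.6g}"
            length = parent_height - node.dist
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


class AverageLinkageHCA(BaseEstimator):
    """UPGMA clustering on the Euclidean distance matrix.

    ``fit`` builds the dendrogram; ``labels_`` holds the k-group cut.
    """

    def __init__(self, n_clusters: int = 6):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = _as_frame(X)
        n = len(X)
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        dist = pdist(X.to_numpy(float), metric="euclidean")
        Z = hierarchy.linkage(dist, method="average")
        self.dendrogram_ = Dendrogram(Z, list(X.index))
        self.labels_ = self.dendrogram_.cut(self.n_clusters)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# functional wrappers

def reduce_descriptors(matrix: pd.DataFrame, corr_threshold: float = 0.95
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    red = DescriptorReducer(corr_threshold).fit(matrix)
    return red.transform(matrix), red.removal_log_


def zscale(matrix: pd.DataFrame) -> pd.DataFrame:
    return ZScaler().fit_transform(matrix)


def pca_fit(matrix: pd.DataFrame, n_components: int, cv_folds: int = 7,
            seed: int = 0) -> ChemometricPCA:
    return ChemometricPCA(n_components, cv_folds, seed).fit(matrix)


def hca_cluster(matrix: pd.DataFrame, k: int,
                cp_values: pd.Series | None = None
                ) -> tuple[Dendrogram, pd.Series, pd.Series | None]:
    """Cluster rows; optionally report the median CP-response per cluster."""
    model = AverageLinkageHCA(n_clusters=k).fit(matrix)
    labels = pd.Series(model.labels_, index=matrix.index, name="cluster")
    medians = None
    if cp_values is not None:
        joined = pd.DataFrame({"cluster": labels,
                               "cp": cp_values.reindex(labels.index)})
        medians = joined.groupby("cluster")["cp"].median()
    return model.dendrogram_, labels, medians
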