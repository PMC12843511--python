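"""Global morphological heterogeneity over time in principal-component space.

Morphometric rows are z-scaled and projected onto 20 principal components;
all quantitative distance readouts live in that PC space: mean pairwise
(inter-organoid) Euclidean distance per loop, consecutive-loop
(intra-organoid) change series with 2.5/97.5-percentile winsorisation, and
two embedding-fidelity diagnostics: the k-nearest-neighbour Jaccard index
between the high-dimensional and an embedded space, and the fraction of
nearest neighbours sharing the query point's organoid label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PCSpace",
    "fit_pc_space",
    "project_table",
    "inter_organoid_distance",
    "intra_organoid_change",
    "neighbor_preservation_jaccard",
    "same_organoid_neighbor_fraction",
]

META_COLUMNS = ("experiment_id", "well_id", "loop")
# columns a morphometrics table may carry that are not features
_NON_FEATURE_COLUMNS = set(META_COLUMNS) | {"z", "frame"}


@dataclass
class PCSpace:
    """Fitted z-scaling + PCA projection (components are orthonormal)."""

    scaler: StandardScaler
    pca: PCA
    feature_names: list

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=np.float64)
        return self.pca.transform(self.scaler.transform(x))


def _feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c not in _NON_FEATURE_COLUMNS]
    return table[cols]


def fit_pc_space(table: pd.DataFrame, n_components: int = 20) -> PCSpace:
    """Z-scale each feature and fit the top principal components.

    Constant (zero-variance) features are dropped with a warning.  When an
    analysis restricts to a subset of rows (e.g. untreated wells only), fit
    on the full table first so the numerical space is preserved, then
    subset the projected rows.
    """
    feats = _feature_frame(table)
    x = feats.to_numpy(dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError("morphometrics table contains missing values")
    # relative tolerance: a column of identical values has std ~1e-15, not 0
    keep = x.std(axis=0) > 1e-12 * np.maximum(1.0, np.abs(x).max(axis=0))
    if not keep.all():
        dropped = [n for n, k in zip(feats.columns, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    names = [n for n, k in zip(feats.columns, keep) if k]
    x = x[:, keep]
    n_components = min(n_components, x.shape[1], x.shape[0])
    scaler = StandardScaler().fit(x)
    pca = PCA(n_components=n_components, svd_solver="full").fit(
        scaler.transform(x))
    return PCSpace(scaler=scaler, pca=pca, feature_names=names)


def project_table(table: pd.DataFrame, space: PCSpace) -> pd.DataFrame:
    """Projected rows with their metadata columns retained."""
    pcs = space.transform(table)
    out = table[list(META_COLUMNS)].copy().reset_index(drop=True)
    for i in range(pcs.shape[1]):
        out[f"pc{i + 1}"] = pcs[:, i]
    return out


def _pc_matrix(projected: pd.DataFrame) -> np.ndarray:
    cols = [c for c in projected.columns if c.startswith("pc")]
    return projected[cols].to_numpy(dtype=np.float64)


def inter_organoid_distance(projected: pd.DataFrame, loop: int) -> float:
    """Mean pairwise Euclidean PC-space distance between organoids at a loop."""
    rows = projected[projected["loop"] == loop]
    if len(rows) < 2:
        raise ValueError(f"need >= 2 organoids at loop {loop}")
    return float(pdist(_pc_matrix(rows)).mean())


def inter_organoid_distance_curve(projected: pd.DataFrame) -> pd.DataFrame:
    """Per-loop mean pairwise distance (loops with < 2 organoids omitted)."""
    recs = []
    for loop, rows in projected.groupby("loop"):
        if len(rows) >= 2:
            recs.append(dict(loop=int(loop),
                             mean_pairwise_distance=float(pdist(_pc_matrix(rows)).mean()),
                             n_organoids=len(rows)))
    return pd.DataFrame(recs)


def intra_organoid_change(projected: pd.DataFrame, cap_lo: float = 2.5,
                          cap_hi: float = 97.5) -> pd.DataFrame:
    """Consecutive-loop PC displacement per organoid, winsorised, summarised.

    For each organoid, the Euclidean distance between its PC vectors at
    loops n and n+1 is computed (gaps are skipped, never bridged).  The
    pooled series is winsorised at the ``cap_lo``/``cap_hi`` percentiles,
    then mean +/- SEM per loop (indexed by the earlier loop n) is reported.
    """
    dists, loops = [], []
    for (_, _), rows in projected.groupby(["experiment_id", "well_id"]):
        rows = rows.sort_values("loop")
        lp = rows["loop"].to_numpy()
        x = _pc_matrix(rows)
        for i in range(len(lp) - 1):
            if lp[i + 1] == lp[i] + 1:
                dists.append(float(np.linalg.norm(x[i + 1] - x[i])))
                loops.append(int(lp[i]))
    if not dists:
        raise ValueError("no organoid has two consecutive accepted loops")
    d = np.asarray(dists)
    lo, hi = np.percentile(d, [cap_lo, cap_hi])
    d = np.clip(d, lo, hi)
    df = pd.DataFrame({"loop": loops, "change": d})
    out = df.groupby("loop")["change"].agg(
        mean_change="mean",
        sem_change=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n="size").reset_index()
    return out


def _knn_indices(x: np.ndarray, k: int) -> np.ndarray:
    """Deterministic k-NN (self excluded): ties broken by row index."""
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def neighbor_preservation_jaccard(high_dim: np.ndarray, embedded: np.ndarray,
                                  k: int = 30) -> np.ndarray:
    """Per-point Jaccard index of k-NN sets in two spaces (self excluded)."""
    high_dim = np.asarray(high_dim, dtype=np.float64)
    embedded = np.asarray(embedded, dtype=np.float64)
    n = high_dim.shape[0]
    if embedded.shape[0] != n:
        raise ValueError("row counts differ between spaces")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points")
    nn_h = _knn_indices(high_dim, k)
    nn_e = _knn_indices(embedded, k)
    out = np.empty(n)
    for i in range(n):
        a, b = set(nn_h[i]), set(nn_e[i])
        out[i] = len(a & b) / len(a | b)
    return out


def same_organoid_neighbor_fraction(x: np.ndarray, organoid_labels,
                                    k: int = 30) -> np.ndarray:
    """Fraction of each point's k nearest neighbours sharing its organoid."""
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(organoid_labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("labels must align with rows")
    if x.shape[0] < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points")
    nn = _knn_indices(x, k)
    return (labels[nn] == labels[:, None]).mean(axis=1)
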