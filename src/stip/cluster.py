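"""Hierarchical compatibility clustering and the pairwise similarity matrix.

Cell lines are clustered on a z-scored feature matrix (by default the
log-phase slope, AUC, signed divergence duration and FSI — the relative
divergence and CV are left out because the FSI already folds them in) with
Euclidean distance and Ward-D2 linkage.  The number of clusters is chosen
by maximizing the mean silhouette over k = 2..min(5, n-1): the cohort
typically resolves into permissive, suppressive and inert groups.

The similarity heatmap matrix is the max-normalized Euclidean complement
s_ij = 1 - d_ij / max(d): bounded in [0, 1], monotone in distance, 1 on the
diagonal and 0 for the most distant pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .fsi import FsiResult, feature_vector
from .kinetics import KineticProfile

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "build_feature_matrix",
    "ward_cluster",
    "similarity_matrix",
]

DEFAULT_FEATURES = ("logphase_slope", "auc", "signed_duration", "fsi")


@dataclass
class ClusterConfig:
    features: tuple[str, ...] = DEFAULT_FEATURES
    max_k: int = 5


@dataclass
class ClusterResult:
    linkage: np.ndarray           # scipy linkage matrix (merge order + heights)
    selected_k: int
    labels: dict[str, int]
    silhouettes: dict[int, float]

    def members(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for line, lab in self.labels.items():
            out.setdefault(lab, set()).add(line)
        return {k: frozenset(v) for k, v in out.items()}

    def partition(self) -> set[frozenset[str]]:
        return set(self.members().values())


def build_feature_matrix(profiles: list[KineticProfile],
                         fsi_results: list[FsiResult] | None = None,
                         features: tuple[str, ...] = DEFAULT_FEATURES,
                         ) -> pd.DataFrame:
    """Z-scored (sample SD) feature matrix, one row per cell line.

    Zero-variance columns are left all-zero with a warning.
    """
    fsi_by_line = {r.cell_line: r.fsi for r in (fsi_results or [])}
    rows = {}
    for p in profiles:
        fv = feature_vector(p)
        row = {}
        for f in features:
            if f == "fsi":
                if p.cell_line not in fsi_by_line:
                    raise ValueError(f"no FSI result for line {p.cell_line}")
                row[f] = fsi_by_line[p.cell_line]
            elif f in fv:
                row[f] = fv[f]
            else:
                row[f] = getattr(p, f)
        rows[p.cell_line] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(features))
    for col in df.columns:
        sd = df[col].std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"feature {col!r} has zero variance; column zeroed",
                          UserWarning, stacklevel=2)
            df[col] = 0.0
        else:
            df[col] = (df[col] - df[col].mean()) / sd
    return df


def ward_cluster(features: pd.DataFrame,
                 cfg: ClusterConfig | None = None) -> ClusterResult:
    """Agglomerative Ward-D2 clustering with silhouette-selected k."""
    cfg = cfg or ClusterConfig()
    n = len(features)
    if n < 3:
        raise ValueError("clustering needs >= 3 rows")
    X = features.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    silhouettes: dict[int, float] = {}
    best_k, best_s = 2, -np.inf
    for k in range(2, min(cfg.max_k, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        s = float(silhouette_score(X, labels, metric="euclidean"))
        silhouettes[k] = s
        if s > best_s:
            best_k, best_s = k, s
    labels = fcluster(Z, t=best_k, criterion="maxclust")
    return ClusterResult(
        linkage=Z,
        selected_k=best_k,
        labels={line: int(lab) for line, lab in zip(features.index, labels)},
        silhouettes=silhouettes,
    )


def similarity_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise similarity s_ij = 1 - d_ij / max(d), diagonal 1."""
    if len(features) < 2:
        raise ValueError("similarity needs >= 2 rows")
    d = pdist(features.to_numpy(dtype=float), metric="euclidean")
    dmax = d.max()
    s = 1.0 - (squareform(d) / dmax if dmax > 0 else squareform(d))
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=features.index, columns=features.index)
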