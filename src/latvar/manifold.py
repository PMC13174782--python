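"""Low-dimensional embedding and clustering tendency of LI profiles.

The per-participant profile of lateralisation indices across the 7 tracts x
3 metrics is embedded into two dimensions with UMAP (n_neighbors=15,
min_dist=0.1, Euclidean) for visual inspection, and the continuum-versus-
clusters question is quantified on the *original* 21-dimensional LI space
(never on the projection, which can fabricate or destroy structure) with:

* the Hopkins statistic against a uniform reference on the feature bounding
  box (plain nearest-neighbour distances; ~0.5 for unstructured data,
  approaching 1 for strongly clustered data — note that even a single
  compact unimodal cloud sits somewhat above the 0.5 uniform baseline in
  high dimension), and
* the best silhouette score over k-means fits for k in a small grid.

LI features are passed unstandardised by default (they share the bounded
[-1, 1] scale); a z-score option exists behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass(frozen=True)
class ClusterabilitySummary:
    hopkins: float
    silhouettes: dict          # k -> silhouette score
    silhouette_best_k: int
    silhouette_best: float
    k_grid: tuple
    n_ref: int
    seed: int


@dataclass(frozen=True)
class EmbeddingResult:
    coords: pd.DataFrame       # index participant_id, columns umap1/umap2
    embed_params: dict
    clusterability: ClusterabilitySummary | None = None


def _validated_matrix(li_matrix: pd.DataFrame) -> np.ndarray:
    x = np.asarray(li_matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("LI matrix contains missing cells; use a "
                         "listwise-complete matrix")
    return x


def embed_phenotypes(li_matrix: pd.DataFrame, n_neighbors: int = 15,
                     min_dist: float = 0.1, metric: str = "euclidean",
                     seed: int = 0, standardise: bool = False) -> EmbeddingResult:
    """2-D UMAP embedding of the participants x features LI matrix.

    The embedding is delegated to umap-learn with exactly the given
    parameters and a fixed, recorded seed (deterministic for a fixed backend
    version).  Requires a complete matrix and n > n_neighbors.
    """
    x = _validated_matrix(li_matrix)
    if x.shape[0] <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} participants, "
                         f"got {x.shape[0]}")
    if standardise:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    import warnings

    import umap  # deferred: numba-backed import is slow

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, metric=metric, random_state=seed)
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; that
        # trade is deliberate (reproducibility over speed)
        warnings.simplefilter("ignore", UserWarning)
        coords = reducer.fit_transform(x)
    frame = pd.DataFrame(coords, index=li_matrix.index, columns=["umap1", "umap2"])
    params = {"n_neighbors": n_neighbors, "min_dist": min_dist, "metric": metric,
              "seed": seed, "standardise": standardise,
              "backend": f"umap-learn {umap.__version__}"}
    return EmbeddingResult(coords=frame, embed_params=params)


def hopkins_statistic(x: np.ndarray, n_ref: int = 200, seed: int = 0) -> float:
    """Hopkins clustering-tendency statistic on the raw feature space.

    Compares nearest-neighbour distances from uniform reference points (on
    the per-feature bounding box) to the data against nearest-neighbour
    distances within the data.  Plain (unexponentiated) distances are used.
    """
    from sklearn.neighbors import NearestNeighbors

    x = np.asarray(x, dtype=float)
    x = x[np.lexsort(x.T[::-1])]  # canonical row order: invariant to input order
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    m = min(n_ref, n - 1)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref = rng.uniform(lo, hi, size=(n_ref, x.shape[1]))
    nn = NearestNeighbors(n_neighbors=2).fit(x)
    u = nn.kneighbors(ref, n_neighbors=1)[0][:, 0]
    sample_idx = rng.choice(n, size=m, replace=False)
    w = nn.kneighbors(x[sample_idx], n_neighbors=2)[0][:, 1]  # skip self
    return float(u.sum() / (u.sum() + w.sum()))


def clusterability(li_matrix: pd.DataFrame, k_grid=range(2, 9),
                   n_ref: int = 200, seed: int = 0) -> ClusterabilitySummary:
    """Hopkins statistic plus best k-means silhouette on the LI feature space.

    An addition to the descriptive embedding: it turns "does the cohort form
    discrete lateralisation phenotypes?" into two numbers computed on the
    original 21-D space.
    """
    x = _validated_matrix(li_matrix)
    if x.shape[0] < 10:
        raise ValueError("clusterability needs at least 10 participants")
    x = x[np.lexsort(x.T[::-1])]  # canonical row order: invariant to input order
    k_grid = tuple(int(k) for k in k_grid)
    hop = hopkins_statistic(x, n_ref=n_ref, seed=seed)
    sils = {}
    for k in k_grid:
        if k >= x.shape[0]:
            continue
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
        if len(set(labels)) < 2:
            continue
        sils[k] = float(silhouette_score(x, labels))
    if not sils:
        raise ValueError("no k in k_grid produced a valid clustering")
    best_k = max(sils, key=sils.get)
    return ClusterabilitySummary(hopkins=hop, silhouettes=sils,
                                 silhouette_best_k=best_k,
                                 silhouette_best=sils[best_k],
                                 k_grid=k_grid, n_ref=n_ref, seed=seed)


def plot_embedding(result: EmbeddingResult, path=None, ax=None):
    """Scatter plot of a 2-D embedding (one point per participant)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(result.coords["umap1"], result.coords["umap2"], s=12, alpha=0.7)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.set_title("LI profile embedding")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
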