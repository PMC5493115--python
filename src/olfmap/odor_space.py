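"""Geometry of odor representations in neural space.

Each odor is a vector of response intensities over the recorded neuron
classes (a column of the class × odor response matrix). The module computes
pairwise odor distances (cosine, Euclidean, correlation), clusters odors by
Ward's method with a fixed linkage-distance cut, extracts the glomeruli that
dominate each odor cluster, projects the odor space with PCA, and tests
group separation with one-way ANOSIM (rank-based permutation test on
Bray–Curtis dissimilarities). ``matrix_correlation`` relates two distance
matrices over the same items (e.g., anatomical vs functional distances) with
an optional label-shuffle control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

_METRICS = ("cosine", "euclidean", "correlation")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with item labels."""

    labels: list
    values: np.ndarray
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """SciPy linkage table plus leaf labels (Ward merges on given distances)."""

    linkage: np.ndarray  # (n-1, 4)
    labels: list
    method: str = "ward"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def max_height(self) -> float:
        return float(self.linkage[:, 2].max())


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a centered PCA."""

    scores: pd.DataFrame       # item × component
    loadings: pd.DataFrame     # variable × component
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(f < -1e-12) or np.any(np.diff(f) > 1e-9) or f.sum() > 1 + 1e-9:
            raise ValueError("explained fractions must be non-negative, non-increasing, sum ≤ 1")
        self.explained_variance_fraction = np.clip(f, 0.0, None)


def _frame_of(matrix) -> pd.DataFrame:
    """Accept a ResponseMatrix (duck-typed via ``.frame``) or a DataFrame."""
    frame = getattr(matrix, "frame", matrix)
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("expected a ResponseMatrix or a pandas DataFrame")
    return frame


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _pairwise(vectors: np.ndarray, labels: list, metric: str) -> DistanceMatrix:
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    d = pdist(vectors, metric=metric)
    if metric in ("cosine", "correlation") and np.any(~np.isfinite(d)):
        # zero-norm (cosine) or zero-variance (correlation) vectors: SciPy
        # yields nan; the distance is defined as 1 here.
        n_bad = int(np.sum(~np.isfinite(d)))
        logger.warning("%s distance undefined for %d pairs (degenerate vectors); set to 1",
                       metric, n_bad)
        d = np.where(np.isfinite(d), d, 1.0)
    full = squareform(d)
    return DistanceMatrix(labels=list(labels), values=full, metric=metric)


def odor_distance_matrix(matrix, metric: str = "cosine", *,
                         rectify: bool = False) -> DistanceMatrix:
    """Pairwise distances between odors (columns of a class × odor matrix).

    cosine: ``1 − u·v / (‖u‖‖v‖)``; euclidean: ``‖u − v‖``;
    correlation: ``1 − Pearson(u, v)``. With ``rectify=True`` negative
    response intensities are set to zero first (amplitude metrics on raw
    control-subtracted data may otherwise be dominated by suppression).
    """
    frame = _frame_of(matrix)
    if frame.shape[1] < 2:
        raise ValueError("need at least two odors")
    vals = frame.to_numpy(dtype=float)
    if rectify:
        vals = np.clip(vals, 0.0, None)
    return _pairwise(vals.T, list(frame.columns), metric)


def correlation_distance_rows(rows: np.ndarray, labels: list) -> DistanceMatrix:
    """1 − Pearson r between rows of a 2D array (used for voxel-map similarity)."""
    return _pairwise(np.asarray(rows, dtype=float), labels, "correlation")


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(dmat: DistanceMatrix) -> Dendrogram:
    """Ward dendrogram on a precomputed distance matrix.

    The linkage applies the Lance–Williams recurrence for Ward's criterion
    directly to the provided dissimilarities. For cosine or correlation
    distances this departs from Ward's Euclidean sum-of-squares derivation
    but follows the common practice of the numerical tools this analysis
    models itself on.
    """
    z = hierarchy.linkage(dmat.condensed(), method="ward")
    return Dendrogram(linkage=z, labels=list(dmat.labels))


def cut_dendrogram(dend: Dendrogram, threshold: float,
                   mode: str = "absolute") -> pd.Series:
    """Flat clusters = connected components below the cut height.

    ``mode="absolute"`` cuts at the given linkage distance;
    ``mode="fraction_of_max"`` at ``threshold × max merge height``. Cluster
    ids are renumbered 1, 2, … in order of first appearance along the leaf
    label list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mode == "fraction_of_max":
        height = threshold * dend.max_height
    elif mode == "absolute":
        height = threshold
    else:
        raise ValueError("mode must be 'absolute' or 'fraction_of_max'")
    raw = hierarchy.fcluster(dend.linkage, t=height, criterion="distance")
    remap: dict[int, int] = {}
    out = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out.append(remap[lab])
    return pd.Series(out, index=dend.labels, name="cluster")


def cut_dendrogram_k(dend: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into exactly ``k`` flat clusters (top-level structure).

    Unlike the fixed-height cut, this is scale-free and suited to asking
    whether the top of the tree separates known groups.
    """
    if not 1 <= k <= len(dend.labels):
        raise ValueError("k must be between 1 and the number of leaves")
    raw = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    out = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out.append(remap[lab])
    return pd.Series(out, index=dend.labels, name="cluster")


def cluster_signature_glomeruli(matrix, clusters: pd.Series,
                                rate_threshold: float = 30.0) -> dict[int, set]:
    """Glomeruli whose mean response across a cluster's odors ≥ threshold.

    ``clusters`` must be a partition of the matrix's odor columns. Row labels
    are taken from the matrix's glomerulus metadata when present, else from
    the row index.
    """
    frame = _frame_of(matrix)
    if set(clusters.index) != set(frame.columns):
        raise ValueError("clusters must partition the odor columns")
    row_meta = getattr(matrix, "row_meta", None)
    glom = (row_meta["glomerulus"] if row_meta is not None and "glomerulus" in row_meta
            else pd.Series(frame.index, index=frame.index))
    out: dict[int, set] = {}
    for cid in sorted(clusters.unique()):
        odors = clusters.index[clusters == cid]
        mean_rate = frame[odors].mean(axis=1)
        out[int(cid)] = set(glom[mean_rate >= rate_threshold])
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(matrix, items: str = "odors", *, standardize: bool = False) -> PCAResult:
    """Principal component analysis of the odor space.

    Observations are odors (columns of the class × odor matrix transposed)
    or, for temporal data, rows of a (time·odor) × class array. Variables are
    mean-centered; by default they are not standardized, so the explained
    variance fractions refer to raw response variance. Computed by singular
    value decomposition.
    """
    frame = _frame_of(matrix)
    if items == "odors":
        data = frame.to_numpy(dtype=float).T
        index = list(frame.columns)
        variables = list(frame.index)
    elif items == "rows":
        data = frame.to_numpy(dtype=float)
        index = list(frame.index)
        variables = list(frame.columns)
    else:
        raise ValueError("items must be 'odors' or 'rows'")
    if data.shape[0] < 2:
        raise ValueError("need at least two items for PCA")
    x = data - data.mean(axis=0, keepdims=True)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2 / (data.shape[0] - 1)
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=index, columns=comps)
    loadings = pd.DataFrame(vt.T, index=variables, columns=comps)
    return PCAResult(scores=scores, loadings=loadings, explained_variance_fraction=frac)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(data, group_labels, n_perm: int = 10000, seed: int | None = 0,
           *, metric: str = "braycurtis"):
    """One-way analysis of similarities (ANOSIM).

    R = (mean between-group rank distance − mean within-group rank distance)
    / (M/2), with M = n(n−1)/2 and tied distances given average ranks.
    R is near 0 under the null and approaches 1 when all between-group
    distances exceed all within-group distances.

    ``data`` is either a :class:`DistanceMatrix` over the grouped items or a
    class × odor response matrix, in which case negative intensities are
    rectified to zero and Bray–Curtis dissimilarities between odor columns
    are used. Significance is assessed by permuting the group labels; the
    p-value uses the add-one estimator ``(1 + #{R_perm ≥ R}) / (n_perm + 1)``.

    Returns ``(R, p)``.
    """
    if isinstance(data, DistanceMatrix):
        dmat = data
    else:
        frame = _frame_of(data)
        vals = np.clip(frame.to_numpy(dtype=float), 0.0, None)
        d = pdist(vals.T, metric=metric)
        dmat = DistanceMatrix(labels=list(frame.columns), values=squareform(d),
                              metric=metric)
    labels = np.asarray([group_labels[lab] if isinstance(group_labels, dict)
                         else lab for lab in
                         (dmat.labels if isinstance(group_labels, dict) else group_labels)])
    if len(labels) != dmat.n:
        raise ValueError("one group label per item required")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        tiny = groups[counts < 2].tolist()
        raise ValueError(f"every group needs ≥2 members; too small: {tiny}")

    n = dmat.n
    cond = dmat.condensed()
    ranks = stats.rankdata(cond)  # average ranks on ties
    iu, ju = np.triu_indices(n, k=1)
    codes = pd.factorize(labels)[0]
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within, n)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        w = perm[iu] == perm[ju]
        if _anosim_r(ranks, w, n) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


def anosim_pairwise(data, group_labels, n_perm: int = 10000, seed: int | None = 0,
                    *, metric: str = "braycurtis") -> pd.DataFrame:
    """Post-hoc pairwise ANOSIM with Holm (sequential Bonferroni) correction.

    Only meaningful for >2 groups; each group pair is tested on the subset of
    items belonging to the pair.
    """
    if isinstance(data, DistanceMatrix):
        dmat = data
        labels = np.asarray([group_labels[lab] for lab in dmat.labels]
                            if isinstance(group_labels, dict) else group_labels)
    else:
        frame = _frame_of(data)
        labels = np.asarray([group_labels[lab] for lab in frame.columns]
                            if isinstance(group_labels, dict) else group_labels)
        vals = np.clip(frame.to_numpy(dtype=float), 0.0, None)
        dmat = DistanceMatrix(labels=list(frame.columns),
                              values=squareform(pdist(vals.T, metric=metric)),
                              metric=metric)
    groups = sorted(set(labels.tolist()))
    rows = []
    rng = np.random.default_rng(seed)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            mask = np.isin(labels, [ga, gb])
            sub = DistanceMatrix(
                labels=[l for l, m in zip(dmat.labels, mask) if m],
                values=dmat.values[np.ix_(mask, mask)], metric=dmat.metric)
            r, p = anosim(sub, labels[mask], n_perm=n_perm,
                          seed=int(rng.integers(2**31)))
            rows.append({"group_a": ga, "group_b": gb, "R": r, "p": p})
    out = pd.DataFrame(rows)
    order = np.argsort(out["p"].to_numpy())
    k = len(out)
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * out["p"].iloc[idx])
        adj[idx] = min(1.0, running)
    out["p_holm"] = adj
    return out


# ---------------------------------------------------------------------------
# Matrix vs matrix correlation
# ---------------------------------------------------------------------------

def matrix_correlation(d1: DistanceMatrix, d2: DistanceMatrix,
                       shuffle: tuple[int, int] | None = None):
    """Pearson correlation between two distance matrices over the same items.

    r and a parametric two-sided p (t distribution, df = n_pairs − 2) are
    computed over the upper-triangle entries after aligning ``d2`` to
    ``d1``'s label order. With ``shuffle=(n_runs, seed)`` a label-permutation
    control is added: per run the items of ``d2`` are relabeled by a uniform
    random permutation and r recomputed; the mean ± sd over runs is returned
    as the third element.

    The parametric p treats the n(n−1)/2 pairs as independent, which
    distance pairs are not; it mirrors the scatterplot-style analysis this
    reproduces, and the shuffle control is the robust alternative.
    """
    if set(d1.labels) != set(d2.labels):
        raise ValueError("distance matrices must share their label set")
    order = [d2.labels.index(lab) for lab in d1.labels]
    v2 = d2.values[np.ix_(order, order)]
    iu = np.triu_indices(d1.n, k=1)
    x, y = d1.values[iu], v2[iu]
    r, p = stats.pearsonr(x, y)
    if shuffle is None:
        return float(r), float(p), None
    n_runs, seed = shuffle
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_runs):
        perm = rng.permutation(d1.n)
        rs.append(stats.pearsonr(x, v2[np.ix_(perm, perm)][iu])[0])
    rs = np.asarray(rs)
    return float(r), float(p), (float(rs.mean()), float(rs.std(ddof=1)))
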