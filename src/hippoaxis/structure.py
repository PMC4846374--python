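"""Transcriptome-structure operations: probability profiles, Jensen-Shannon
distance, complete-linkage dendrograms, classical MDS and heat-map scaling.

The clustering recipe: add a pseudocount of 1 to FPKM, take log10, normalize
each sample by its sum to obtain a probability profile over genes, compute the
pairwise Jensen-Shannon distance (base-2 logs, square root of the divergence —
the standard [0, 1] metric), and agglomerate with complete linkage.  Classical
(Torgerson) MDS embeds the same distance matrix via double centering and an
eigendecomposition.

Estimator classes follow scikit-learn conventions (samples as rows); the
module-level functions are thin wrappers operating on the pipeline's
genes-by-samples DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .datamodel import ExpressionMatrix, PopulationMatrix


def _as_frame(m) -> pd.DataFrame:
    if isinstance(m, (ExpressionMatrix, PopulationMatrix)):
        return m.data
    return m


# ---------------------------------------------------------------------------
# probability profiles


def transform_profiles(m) -> pd.DataFrame:
    """Per-sample probability profiles: log10(FPKM + 1) normalized by the sample sum.

    Input is a genes-by-samples DataFrame (or matrix container); output has
    the same shape with every column summing to 1.  An all-zero sample has no
    profile and raises, naming the sample.
    """
    df = _as_frame(m)
    logs = np.log10(df.to_numpy(dtype=float) + 1.0)
    sums = logs.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if len(zero):
        raise ValueError(f"sample {df.columns[zero[0]]!r} is all zero; no profile")
    return pd.DataFrame(logs / sums, index=df.index, columns=df.columns)


class ProfileTransform(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer version of the profile recipe.

    Operates on samples-by-genes arrays (sklearn orientation); rows of the
    output sum to 1.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        if (X < 0).any():
            raise ValueError("expression values must be non-negative")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        logs = np.log10(X + 1.0)
        sums = logs.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            bad = int(np.flatnonzero(sums[:, 0] == 0)[0])
            raise ValueError(f"sample at row {bad} is all zero; no profile")
        return logs / sums


# ---------------------------------------------------------------------------
# Jensen-Shannon distance


def js_distance(p, q) -> float:
    """Jensen-Shannon distance between two probability profiles.

    sqrt(0.5 KL(p||m) + 0.5 KL(q||m)) with m = (p + q)/2 and base-2 logs, so
    the value lies in [0, 1]; 0 log 0 is taken as 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"profile length mismatch: {p.shape} vs {q.shape}")
    return float(jensenshannon(p, q, base=2))


def js_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distances between profile columns."""
    cols = list(profiles.columns)
    arr = profiles.to_numpy(dtype=float)
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensenshannon(arr[:, i], arr[:, j], base=2)
    return pd.DataFrame(d, index=cols, columns=cols)


def _check_distance_matrix(d: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(_as_frame(d) if isinstance(d, pd.DataFrame) else d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    if (arr < 0).any():
        raise ValueError("distances must be non-negative")
    return arr


# ---------------------------------------------------------------------------
# complete-linkage agglomeration


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage format plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4): id_a, id_b, height, size
    labels: tuple[str, ...]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def clades(self) -> list[frozenset[str]]:
        """Leaf-label sets of every internal node, in merge order."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for step, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            out.append(merged)
        return out

    def children_of_root(self) -> tuple[frozenset[str], frozenset[str]]:
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        for step, (a, b, _, _) in enumerate(self.linkage):
            members[n + step] = members[int(a)] | members[int(b)]
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return members[a], members[b]

    def bipartition_of(self, clade: frozenset[str]) -> tuple[frozenset[str], frozenset[str]]:
        """The two children of the internal node whose leaf set equals ``clade``."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        node_children: dict[frozenset[str], tuple[int, int]] = {}
        for step, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            node_children[merged] = (int(a), int(b))
        if clade not in node_children:
            raise KeyError("no internal node with that leaf set")
        a, b = node_children[clade]
        return members[a], members[b]

    def to_newick(self) -> str:
        """Newick export with branch lengths = parent height - child height."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = f"{node[a]}:{h - height[a]:.10g}"
            lb = f"{node[b]}:{h - height[b]:.10g}"
            node[n + step] = f"({la},{lb})"
            height[n + step] = float(h)
        return node[n + len(self.linkage) - 1] + ";"


def complete_linkage(d: pd.DataFrame | np.ndarray, labels=None) -> Dendrogram:
    """Agglomerative clustering with complete linkage and a deterministic tie-break.

    Merge height equals the maximum pairwise distance between the merged
    groups; when several pairs share the minimal linkage distance the pair
    with the lowest (creation-order) indices merges first.
    """
    arr = _check_distance_matrix(d)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if labels is None:
        labels = (
            list(d.columns) if isinstance(d, pd.DataFrame) else [str(i) for i in range(n)]
        )
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for ia in range(len(active)):
            for ib in range(ia + 1, len(active)):
                a, b = active[ia], active[ib]
                dist = arr[np.ix_(members[a], members[b])].max()
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        new_id = n + step
        members[new_id] = members[a] + members[b]
        active = [x for x in active if x not in (a, b)] + [new_id]
        Z[step] = [a, b, dist, len(members[new_id])]
    heights = Z[:, 2]
    assert (np.diff(heights) >= -1e-12).all(), "complete linkage heights must be monotone"
    return Dendrogram(linkage=Z, labels=tuple(labels))


def agglomerative_dendrogram(d: pd.DataFrame | np.ndarray, labels=None) -> Dendrogram:
    """Complete-linkage dendrogram of a distance matrix (see :func:`complete_linkage`)."""
    return complete_linkage(d, labels=labels)


class JensenShannonHierarchy(BaseEstimator):
    """Profile transform + JSD + complete linkage as one sklearn-style estimator.

    ``fit`` expects a samples-by-genes FPKM array (or a genes-by-samples
    DataFrame with ``orient="genes"``); fitted attributes are ``profiles_``,
    ``distance_matrix_`` and ``dendrogram_``.
    """

    def __init__(self, orient: str = "samples"):
        self.orient = orient

    def fit(self, X, y=None):
        if isinstance(X, (ExpressionMatrix, PopulationMatrix)):
            df = X.data.T
        elif isinstance(X, pd.DataFrame):
            df = X.T if self.orient == "genes" else X
        else:
            df = pd.DataFrame(check_array(X))
            df.index = [str(i) for i in df.index]
        profiles = transform_profiles(df.T)  # genes x samples
        self.profiles_ = profiles
        self.distance_matrix_ = js_distance_matrix(profiles)
        self.dendrogram_ = complete_linkage(self.distance_matrix_)
        self.n_features_in_ = df.shape[1]
        return self

    def fit_predict_tree(self, X) -> Dendrogram:
        self.fit(X)
        return self.dendrogram_


# ---------------------------------------------------------------------------
# classical MDS


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling on a precomputed distance matrix.

    Double-centers -D^2/2, takes the top ``n_components`` non-negative
    eigenpairs and scales eigenvectors by the square root of their
    eigenvalues.  Output is unique up to rotation/reflection; for
    reproducibility each axis is signed so its first nonzero loading is
    positive.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        arr = _check_distance_matrix(X)
        n = arr.shape[0]
        if self.n_components >= n:
            raise ValueError("n_components must be smaller than the number of items")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (arr**2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][: self.n_components]
        vals, vecs = vals[order], vecs[:, order]
        vals = np.clip(vals, 0, None)
        coords = vecs * np.sqrt(vals)
        for k in range(coords.shape[1]):
            nz = np.flatnonzero(np.abs(coords[:, k]) > 1e-12)
            if len(nz) and coords[nz[0], k] < 0:
                coords[:, k] = -coords[:, k]
        self.embedding_ = coords
        self.eigenvalues_ = vals
        self.n_features_in_ = n
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def classical_mds(d: pd.DataFrame | np.ndarray, k: int = 2) -> pd.DataFrame:
    """Classical MDS coordinates of a distance matrix (k dimensions)."""
    mds = ClassicalMDS(n_components=k).fit(d)
    index = (
        list(d.columns) if isinstance(d, pd.DataFrame) else list(range(mds.embedding_.shape[0]))
    )
    return pd.DataFrame(
        mds.embedding_, index=index, columns=[f"MDS{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# heat-map normalization


def heatmap_normalize(values) -> pd.DataFrame:
    """Scale each gene by its maximum across samples (all-zero genes stay zero)."""
    df = _as_frame(values)
    maxima = df.max(axis=1)
    safe = maxima.replace(0, 1.0)
    return df.div(safe, axis=0)
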