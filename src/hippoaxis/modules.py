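"""Co-expression module detection via correlation dissimilarity and DIANA.

The procedure: select the 1000 most variable genes among those expressed in
every dataset (minimum population-mean FPKM >= 5), compute the gene-gene
Pearson correlation C across the population means, map it to the
dissimilarity D = 1 - (C + 1)/2 (so D in [0, 1], perfectly correlated pairs at
0, anti-correlated at 1), cluster divisively with the DIANA algorithm, and cut
the divisive tree into modules.

DIANA (DIvisive ANAlysis, Kaufman & Rousseeuw): start with one cluster; at
each step split the cluster of largest diameter by seeding a splinter group
with the object of maximal average dissimilarity to the rest and iteratively
moving over objects whose average dissimilarity to the splinter is smaller
than to the remainder.  Node heights are cluster diameters, hence
non-increasing from root to leaves.

Because the height scale of a DIANA dendrogram depends on the dissimilarity
convention, the default cut targets a requested module *count*; an
absolute-height mode is available for calibrated heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from statsmodels.stats.multitest import multipletests

from .datamodel import PopulationMatrix
from .structure import heatmap_normalize, _check_distance_matrix


# ---------------------------------------------------------------------------
# variable-gene selection


def variable_genes(
    pm: PopulationMatrix,
    n: int = 1000,
    fpkm_min: float = 5.0,
    mode: str = "min",
    scale: str = "log10",
) -> list[str]:
    """The ``n`` most variable genes across populations.

    Genes first pass an expression floor (``mode="min"``: minimum
    population-mean FPKM >= ``fpkm_min``; ``mode="max"``: maximum-based
    alternative), then are ranked by the variance of log10(FPKM + 1) across
    populations (``scale="raw"`` ranks on raw FPKM variance).  Ties break by
    gene id.
    """
    df = pm.data
    if mode == "min":
        kept = df[df.min(axis=1) >= fpkm_min]
    elif mode == "max":
        kept = df[df.max(axis=1) >= fpkm_min]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if len(kept) < n:
        raise ValueError(
            f"only {len(kept)} genes pass the FPKM_min={fpkm_min} filter; {n} requested"
        )
    if scale == "log10":
        basis = np.log10(kept + 1.0)
    elif scale == "raw":
        basis = kept
    else:
        raise ValueError(f"unknown scale {scale!r}")
    var = basis.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


class VariableGeneSelector(BaseEstimator):
    """Sklearn-style selector wrapping :func:`variable_genes`.

    ``fit`` on a :class:`PopulationMatrix`; ``selected_genes_`` holds the
    ranked selection.
    """

    def __init__(self, n: int = 1000, fpkm_min: float = 5.0, mode: str = "min",
                 scale: str = "log10"):
        self.n = n
        self.fpkm_min = fpkm_min
        self.mode = mode
        self.scale = scale

    def fit(self, X: PopulationMatrix, y=None):
        self.selected_genes_ = variable_genes(
            X, n=self.n, fpkm_min=self.fpkm_min, mode=self.mode, scale=self.scale
        )
        return self

    def transform(self, X: PopulationMatrix) -> pd.DataFrame:
        return X.data.loc[self.selected_genes_]


# ---------------------------------------------------------------------------
# correlation dissimilarity


@dataclass(frozen=True)
class CorrelationDissimilarity:
    """Gene-gene Pearson correlation C and dissimilarity D = 1 - (C + 1)/2."""

    C: pd.DataFrame
    D: pd.DataFrame
    dropped: tuple[str, ...]  # zero-variance genes removed before correlation


def correlation_dissimilarity(
    pm: PopulationMatrix | pd.DataFrame,
    genes: Sequence[str] | None = None,
) -> CorrelationDissimilarity:
    """Correlate genes across datasets and map to the [0, 1] dissimilarity.

    Needs at least two datasets (columns).  Zero-variance genes have no
    defined correlation and are dropped with a warning.
    """
    df = pm.data if isinstance(pm, PopulationMatrix) else pm
    if genes is not None:
        df = df.loc[list(genes)]
    if df.shape[1] < 2:
        raise ValueError("need at least 2 datasets to correlate across")
    sd = df.std(axis=1, ddof=1)
    zero_var = list(df.index[sd == 0])
    if zero_var:
        warnings.warn(
            f"dropping {len(zero_var)} zero-variance gene(s) before correlation",
            stacklevel=2,
        )
        df = df.drop(index=zero_var)
    if df.shape[0] < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    C = np.corrcoef(df.to_numpy(dtype=float))
    if np.isnan(C).any():
        raise ValueError("undefined correlation for a retained zero-variance gene")
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    D = 1.0 - (C + 1.0) / 2.0
    np.fill_diagonal(D, 0.0)
    idx = df.index
    return CorrelationDissimilarity(
        C=pd.DataFrame(C, index=idx, columns=idx),
        D=pd.DataFrame(D, index=idx, columns=idx),
        dropped=tuple(zero_var),
    )


# ---------------------------------------------------------------------------
# DIANA divisive clustering


@dataclass(frozen=True)
class DianaNode:
    """Node of the divisive tree; ``height`` is the cluster diameter."""

    members: tuple[int, ...]
    height: float
    children: tuple["DianaNode", "DianaNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


def _diana_split(D: np.ndarray, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One DIANA splinter step on the sub-matrix of ``members``."""
    m = len(members)
    sub = D[np.ix_(members, members)]
    # seed: object with maximal average dissimilarity to the others
    avg = sub.sum(axis=1) / (m - 1)
    # lowest index on ties (tolerance guards float summation order)
    seed = int(np.flatnonzero(avg >= avg.max() - 1e-12)[0])
    splinter = [seed]
    rest = [i for i in range(m) if i != seed]
    while len(rest) > 1:
        rest_arr = np.array(rest)
        spl_arr = np.array(splinter)
        to_rest = sub[np.ix_(rest_arr, rest_arr)].sum(axis=1) / (len(rest) - 1)
        to_spl = sub[np.ix_(rest_arr, spl_arr)].mean(axis=1)
        diff = to_rest - to_spl
        best = int(np.flatnonzero(diff >= diff.max() - 1e-12)[0])
        if diff[best] <= 0:
            break
        splinter.append(rest.pop(best))
    return members[np.array(sorted(splinter))], members[np.array(sorted(rest))]


def _diana_tree(D: np.ndarray, members: np.ndarray) -> DianaNode:
    if len(members) == 1:
        return DianaNode(members=tuple(members), height=0.0)
    sub = D[np.ix_(members, members)]
    diameter = float(sub.max())
    if diameter == 0.0:
        # indistinguishable objects: split off one at a time deterministically
        left = members[:1]
        right = members[1:]
    else:
        left, right = _diana_split(D, members)
    return DianaNode(
        members=tuple(members),
        height=diameter,
        children=(_diana_tree(D, left), _diana_tree(D, right)),
    )


def diana_cluster(D: pd.DataFrame | np.ndarray) -> DianaNode:
    """Full divisive (DIANA) tree of a dissimilarity matrix.

    Splitting order is by decreasing diameter, which a recursive construction
    reproduces exactly since a subset's diameter never exceeds its superset's.
    """
    arr = _check_distance_matrix(D)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    return _diana_tree(arr, np.arange(arr.shape[0]))


def _cut_by_height(node: DianaNode, height: float) -> list[DianaNode]:
    if node.is_leaf or node.height < height:
        return [node]
    out = []
    for child in node.children:
        out.extend(_cut_by_height(child, height))
    return out


def _cut_by_count(root: DianaNode, n_modules: int) -> list[DianaNode]:
    clusters = [root]
    while len(clusters) < n_modules:
        splittable = [c for c in clusters if not c.is_leaf]
        if not splittable:
            break
        widest = max(splittable, key=lambda c: c.height)
        clusters.remove(widest)
        clusters.extend(widest.children)
    return clusters


def _leaf_order(node: DianaNode) -> list[int]:
    if node.is_leaf:
        return list(node.members)
    order = []
    for child in node.children:
        order.extend(_leaf_order(child))
    return order


@dataclass(frozen=True)
class ModuleAssignment:
    """Gene-to-module labels with per-population module expression profiles."""

    labels: pd.Series  # gene -> module label ("M1", ...)
    cut_height: float | None
    n_modules: int
    profiles: pd.DataFrame | None  # module x population mean of max-normalized FPKM

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def partition(self) -> dict[str, list[str]]:
        return {m: self.members(m) for m in dict.fromkeys(self.labels)}


def cut_modules(
    tree: DianaNode,
    gene_ids: Sequence[str],
    height: float | None = None,
    n_modules: int | None = None,
    pm: PopulationMatrix | pd.DataFrame | None = None,
) -> ModuleAssignment:
    """Cut the divisive tree into modules.

    Exactly one of ``height`` (absolute-height mode; connected subtrees whose
    diameter falls below the cut become modules; a cut above the root yields a
    single module) or ``n_modules`` (split widest-first until the requested
    count) must be given.  If ``pm`` is provided, each module's expression
    profile is the per-population mean of its member genes' max-normalized
    FPKM.
    """
    if (height is None) == (n_modules is None):
        raise ValueError("specify exactly one of height or n_modules")
    if height is not None:
        if height < 0:
            raise ValueError("cut height must be non-negative")
        clusters = _cut_by_height(tree, height)
    else:
        if n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        clusters = _cut_by_count(tree, n_modules)

    # label modules in leaf order for determinism
    position = {g: i for i, g in enumerate(_leaf_order(tree))}
    clusters.sort(key=lambda c: min(position[m] for m in c.members))
    labels = pd.Series(index=pd.Index(gene_ids, name="gene_id"), dtype=object)
    for mi, cluster in enumerate(clusters, start=1):
        for member in cluster.members:
            labels.iloc[member] = f"M{mi}"

    profiles = None
    if pm is not None:
        df = pm.data if isinstance(pm, PopulationMatrix) else pm
        normed = heatmap_normalize(df.loc[list(labels.index)])
        profiles = normed.groupby(labels).mean()
        profiles.index.name = "module"
    return ModuleAssignment(
        labels=labels,
        cut_height=height,
        n_modules=len(clusters),
        profiles=profiles,
    )


class DianaClustering(ClusterMixin, BaseEstimator):
    """DIANA divisive clustering as a scikit-learn estimator.

    ``fit`` takes a precomputed dissimilarity matrix; fitted attributes are
    ``tree_`` and (when ``n_clusters`` or ``height`` is set) ``labels_``.
    """

    def __init__(self, n_clusters: int | None = None, height: float | None = None):
        self.n_clusters = n_clusters
        self.height = height

    def fit(self, X, y=None):
        arr = _check_distance_matrix(X)
        self.tree_ = diana_cluster(arr)
        self.n_features_in_ = arr.shape[0]
        if self.n_clusters is not None or self.height is not None:
            ids = (
                list(X.index)
                if isinstance(X, pd.DataFrame)
                else [str(i) for i in range(arr.shape[0])]
            )
            assignment = cut_modules(
                self.tree_, ids, height=self.height, n_modules=self.n_clusters
            )
            codes = {m: i for i, m in enumerate(dict.fromkeys(assignment.labels))}
            self.labels_ = np.array([codes[m] for m in assignment.labels])
        return self


# ---------------------------------------------------------------------------
# gene-set enrichment (hypergeometric, BH-adjusted)


def gene_set_test(
    module_genes: Iterable[str],
    annotation_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a module against annotation sets.

    For each set, p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set|,
    n=|module|); p-values are Benjamini-Hochberg adjusted across sets.
    Module and annotation sets must lie within the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    module = set(module_genes)
    if module - universe:
        raise ValueError("module genes outside universe")
    rows = []
    for name, genes in annotation_sets.items():
        anno = set(genes)
        if anno - universe:
            raise ValueError(f"annotation set {name!r} has genes outside universe")
        k = len(module & anno)
        N, K, n = len(universe), len(anno), len(module)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "module_size", "universe_size", "p"]
    )
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
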