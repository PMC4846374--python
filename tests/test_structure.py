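import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from hippoaxis.datamodel import aggregate_replicates
from hippoaxis.structure import (
    ClassicalMDS,
    Dendrogram,
    JensenShannonHierarchy,
    agglomerative_dendrogram,
    classical_mds,
    complete_linkage,
    heatmap_normalize,
    js_distance,
    js_distance_matrix,
    transform_profiles,
)


# ---------------------------------------------------------------------------
# profiles


def test_transform_profiles_hand_arithmetic():
    df = pd.DataFrame({"s": [9.0, 99.0]}, index=["g1", "g2"])
    prof = transform_profiles(df)
    np.testing.assert_allclose(prof["s"], [1 / 3, 2 / 3])
    df2 = pd.DataFrame({"s": [0.0, 0.0, 9.0]}, index=["a", "b", "c"])
    np.testing.assert_allclose(transform_profiles(df2)["s"], [0, 0, 1])


def test_transform_profiles_all_zero_sample_named():
    df = pd.DataFrame({"ok": [1.0], "empty": [0.0]}, index=["g"])
    with pytest.raises(ValueError, match="empty"):
        transform_profiles(df)


def test_transform_profiles_recompute_oracle():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        10.0 ** rng.normal(1, 1, size=(50, 4)),
        index=[f"g{i}" for i in range(50)],
        columns=list("abcd"),
    )
    prof = transform_profiles(df)
    np.testing.assert_allclose(prof.sum(axis=0), 1.0)
    # independent two-pass computation
    for c in df.columns:
        logs = [np.log10(v + 1) for v in df[c]]
        np.testing.assert_allclose(prof[c], np.array(logs) / sum(logs))


# ---------------------------------------------------------------------------
# Jensen-Shannon distance


def test_js_distance_identity_and_disjoint_support():
    assert js_distance([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-12)
    assert js_distance([1, 0], [0, 1]) == pytest.approx(1.0)


def test_js_distance_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        js_distance([1, 0], [0.5, 0.25, 0.25])


def test_js_distance_matrix_symmetric_zero_diagonal(default_pm):
    prof = transform_profiles(default_pm)
    d = js_distance_matrix(prof)
    arr = d.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0)
    assert ((arr >= 0) & (arr <= 1)).all()


# ---------------------------------------------------------------------------
# complete linkage


def test_forced_topology_three_points():
    d = pd.DataFrame(
        [[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]],
        index=list("ABC"),
        columns=list("ABC"),
        dtype=float,
    )
    dend = complete_linkage(d)
    clades = dend.clades()
    assert clades[0] == frozenset({"A", "B"})
    np.testing.assert_allclose(dend.merge_heights(), [0.1, 0.9])


def test_ultrametric_input_reproduced_exactly():
    # build an ultrametric from a known tree: ((a,b):h1, (c,d):h2):h3
    h1, h2, h3 = 0.2, 0.3, 0.8
    labels = list("abcd")
    d = pd.DataFrame(h3, index=labels, columns=labels, dtype=float)
    d.loc["a", "b"] = d.loc["b", "a"] = h1
    d.loc["c", "d"] = d.loc["d", "c"] = h2
    np.fill_diagonal(d.values, 0)
    dend = complete_linkage(d)
    # cophenetic distances recover the ultrametric exactly
    coph = squareform(cophenet(dend.linkage))
    np.testing.assert_allclose(coph, d.to_numpy())


def test_complete_linkage_agrees_with_scipy_cophenet():
    """Cross-check the hand-rolled agglomeration against scipy's complete linkage."""
    rng = np.random.default_rng(12)
    for _ in range(5):
        pts = rng.normal(size=(9, 3))
        dm = squareform(pdist(pts))
        ours = complete_linkage(pd.DataFrame(dm, index=map(str, range(9)), columns=map(str, range(9))))
        theirs = linkage(pdist(pts), method="complete")
        np.testing.assert_allclose(
            squareform(cophenet(ours.linkage)), squareform(cophenet(theirs))
        )


def test_merge_heights_monotone(default_pm):
    d = js_distance_matrix(transform_profiles(default_pm))
    dend = agglomerative_dendrogram(d)
    assert (np.diff(dend.merge_heights()) >= -1e-12).all()


def test_newick_export_parses_and_preserves_tips(default_pm):
    import dendropy

    d = js_distance_matrix(transform_profiles(default_pm))
    dend = agglomerative_dendrogram(d)
    tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert tips == set(d.columns)


def test_single_item_errors():
    with pytest.raises(ValueError, match="at least 2"):
        complete_linkage(np.zeros((1, 1)))


def test_jensen_shannon_hierarchy_estimator(default_sim):
    matrix, meta, manifest = default_sim
    pm = aggregate_replicates(matrix.drop_genes(manifest.spike_in_genes), meta)
    est = JensenShannonHierarchy().fit(pm)
    assert isinstance(est.dendrogram_, Dendrogram)
    assert est.distance_matrix_.shape == (8, 8)
    assert est.get_params() == {"orient": "samples"}


# ---------------------------------------------------------------------------
# classical MDS


def test_mds_equilateral_triangle():
    d = np.ones((3, 3)) - np.eye(3)
    emb = ClassicalMDS(2).fit(d).embedding_
    np.testing.assert_allclose(pdist(emb), [1, 1, 1], atol=1e-9)


def test_mds_collinear_points():
    pts = np.array([[0.0], [1.0], [3.0]])
    emb = ClassicalMDS(2).fit(squareform(pdist(pts))).embedding_
    np.testing.assert_allclose(pdist(emb), pdist(pts), atol=1e-9)
    assert np.abs(emb[:, 1]).max() < 1e-6


def test_mds_random_cloud_to_machine_precision():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(15, 2))
    emb = ClassicalMDS(2).fit(squareform(pdist(pts))).embedding_
    np.testing.assert_allclose(pdist(emb), pdist(pts), atol=1e-9)


def test_mds_agrees_with_skbio_pcoa():
    from skbio.stats.ordination import pcoa

    rng = np.random.default_rng(4)
    pts = rng.normal(size=(10, 2))
    dm = squareform(pdist(pts))
    ours = ClassicalMDS(2).fit(dm).embedding_
    theirs = pcoa(dm, number_of_dimensions=2).samples.values
    np.testing.assert_allclose(
        np.sort(pdist(ours)), np.sort(pdist(theirs)), atol=1e-8
    )


def test_mds_k_too_large_errors():
    d = np.ones((3, 3)) - np.eye(3)
    with pytest.raises(ValueError, match="n_components"):
        ClassicalMDS(3).fit(d)


def test_classical_mds_frame_wrapper(default_pm):
    d = js_distance_matrix(transform_profiles(default_pm))
    coords = classical_mds(d, k=2)
    assert list(coords.index) == list(d.columns)
    assert list(coords.columns) == ["MDS1", "MDS2"]


# ---------------------------------------------------------------------------
# heat-map normalization


def test_heatmap_normalize_examples():
    df = pd.DataFrame([[10.0, 5.0, 20.0], [0.0, 0.0, 0.0]], index=["g1", "g2"])
    out = heatmap_normalize(df)
    np.testing.assert_allclose(out.loc["g1"], [0.5, 0.25, 1.0])
    np.testing.assert_allclose(out.loc["g2"], 0.0)


def test_heatmap_normalize_scan_property():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.random((40, 6)) * 100)
    out = heatmap_normalize(df)
    np.testing.assert_allclose(out.max(axis=1), 1.0)
    assert ((out.to_numpy() >= 0) & (out.to_numpy() <= 1)).all()
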