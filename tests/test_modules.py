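import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hippoaxis.datamodel import PopulationMatrix
from hippoaxis.modules import (
    DianaClustering,
    VariableGeneSelector,
    correlation_dissimilarity,
    cut_modules,
    diana_cluster,
    gene_set_test,
    variable_genes,
)


def _pm(df):
    return PopulationMatrix(df, tuple((c, "none") for c in df.columns))


# ---------------------------------------------------------------------------
# variable genes


def test_constant_gene_ranked_last():
    df = pd.DataFrame(
        {"P1": [10.0, 10.0], "P2": [100.0, 10.0], "P3": [10.0, 10.0]},
        index=["varying", "constant"],
    )
    got = variable_genes(_pm(df), n=2)
    assert got == ["varying", "constant"]


def test_variance_ordering_ten_vs_small_fold():
    df = pd.DataFrame(
        {"P1": [10.0, 10.0], "P2": [100.0, 11.0]}, index=["big", "small"]
    )
    assert variable_genes(_pm(df), n=1) == ["big"]


def test_variable_genes_insufficient_after_filter():
    df = pd.DataFrame({"P1": [1.0, 20.0], "P2": [1.0, 30.0]}, index=["low", "ok"])
    with pytest.raises(ValueError, match="pass"):
        variable_genes(_pm(df), n=2, fpkm_min=5.0)


def test_variable_genes_matches_full_sort_oracle(default_pm):
    got = variable_genes(default_pm, n=200)
    df = default_pm.data
    kept = df[df.min(axis=1) >= 5.0]
    var = np.log10(kept + 1).var(axis=1, ddof=1)
    oracle = sorted(var.index, key=lambda g: (-var[g], g))[:200]
    assert got == oracle


def test_variable_gene_selector_estimator(default_pm):
    sel = VariableGeneSelector(n=50).fit(default_pm)
    out = sel.transform(default_pm)
    assert list(out.index) == sel.selected_genes_
    assert sel.get_params()["n"] == 50


# ---------------------------------------------------------------------------
# correlation dissimilarity


def test_perfect_and_anti_correlated_pairs():
    genes = pd.DataFrame(
        [[1.0, 2, 3, 4], [2.0, 4, 6, 8], [4.0, 3, 2, 1]],
        index=["a", "b", "anti"],
        columns=["P1", "P2", "P3", "P4"],
    )
    cd = correlation_dissimilarity(_pm(genes))
    assert cd.C.loc["a", "b"] == pytest.approx(1.0)
    assert cd.D.loc["a", "b"] == pytest.approx(0.0)
    assert cd.C.loc["a", "anti"] == pytest.approx(-1.0)
    assert cd.D.loc["a", "anti"] == pytest.approx(1.0)


def test_dissimilarity_affine_map_elementwise(default_pm):
    genes = variable_genes(default_pm, n=60)
    cd = correlation_dissimilarity(default_pm, genes=genes)
    np.testing.assert_allclose(
        cd.D.to_numpy(), 0.5 - cd.C.to_numpy() / 2, atol=1e-12
    )
    assert np.allclose(np.diag(cd.D.to_numpy()), 0)


def test_zero_variance_gene_dropped_with_warning():
    genes = pd.DataFrame(
        [[1.0, 2, 3, 4], [5.0, 5, 5, 5], [4.0, 3, 2, 1]],
        index=["a", "flat", "b"],
        columns=["P1", "P2", "P3", "P4"],
    )
    with pytest.warns(UserWarning, match="zero-variance"):
        cd = correlation_dissimilarity(_pm(genes))
    assert cd.dropped == ("flat",)
    assert list(cd.C.index) == ["a", "b"]


def test_uncorrelated_pair_dissimilarity_near_half():
    """Independent genes have E[C] ~ 0, so D concentrates around 0.5."""
    rng = np.random.default_rng(0)
    ds = []
    for _ in range(200):
        genes = pd.DataFrame(
            rng.normal(10, 2, size=(2, 8)),
            index=["u", "v"],
            columns=[f"P{i}" for i in range(8)],
        )
        cd = correlation_dissimilarity(_pm(genes))
        ds.append(cd.D.loc["u", "v"])
    # mean within Monte Carlo bounds of 0.5 (sd of r with n=8 is ~0.38)
    assert abs(np.mean(ds) - 0.5) < 3 * np.std(ds) / math.sqrt(len(ds))


# ---------------------------------------------------------------------------
# DIANA


def _toy_two_pairs():
    D = pd.DataFrame(0.9, index=list("abcd"), columns=list("abcd"))
    for x, y in [("a", "b"), ("c", "d")]:
        D.loc[x, y] = D.loc[y, x] = 0.1
    np.fill_diagonal(D.values, 0.0)
    return D


def test_diana_toy_matches_hand_trace():
    """Two tight pairs: first split separates {a,b} from {c,d} at diameter 0.9."""
    tree = diana_cluster(_toy_two_pairs())
    assert tree.height == pytest.approx(0.9)
    parts = {frozenset(c.members) for c in tree.children}
    assert parts == {frozenset({0, 1}), frozenset({2, 3})}
    for child in tree.children:
        assert child.height == pytest.approx(0.1)
        assert all(gc.is_leaf for gc in child.children)


def test_diana_two_block_first_split():
    rng = np.random.default_rng(2)
    n = 12
    D = np.full((n, n), 0.95)
    D[:6, :6] = 0.05
    D[6:, 6:] = 0.05
    D += rng.uniform(0, 0.01, (n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    tree = diana_cluster(D)
    parts = {frozenset(c.members) for c in tree.children}
    assert parts == {frozenset(range(6)), frozenset(range(6, 12))}


def test_diana_heights_non_increasing():
    tree = diana_cluster(_toy_two_pairs())

    def walk(node):
        if node.is_leaf:
            return
        for child in node.children:
            assert child.height <= node.height + 1e-12
            walk(child)

    walk(tree)


def test_diana_too_few_genes():
    with pytest.raises(ValueError, match="at least 2"):
        diana_cluster(np.zeros((1, 1)))


def test_cut_extremes():
    D = _toy_two_pairs()
    tree = diana_cluster(D)
    singles = cut_modules(tree, list(D.index), height=0.0)
    assert singles.n_modules == 4
    one = cut_modules(tree, list(D.index), height=10.0)
    assert one.n_modules == 1
    with pytest.raises(ValueError, match="exactly one"):
        cut_modules(tree, list(D.index))


def test_cut_by_count_and_profiles():
    D = _toy_two_pairs()
    tree = diana_cluster(D)
    pm = _pm(
        pd.DataFrame(
            [[10.0, 1], [8.0, 1], [1.0, 10], [1.0, 8]],
            index=list("abcd"),
            columns=["P1", "P2"],
        )
    )
    assign = cut_modules(tree, list(D.index), n_modules=2, pm=pm)
    assert assign.n_modules == 2
    assert assign.partition() == {"M1": ["a", "b"], "M2": ["c", "d"]}
    # profile = per-population mean of max-normalized expression
    np.testing.assert_allclose(assign.profiles.loc["M1"], [1.0, 0.1125])


def test_planted_modules_recovered(default_sim, default_pm):
    """Planted co-expression blocks are recovered from the divisive tree."""
    _, _, manifest = default_sim
    members = manifest.module_members()
    genes = [g for mod in sorted(members) for g in members[mod]]
    truth = {g: mod for mod, gs in members.items() for g in gs}
    cd = correlation_dissimilarity(default_pm, genes=genes)
    tree = diana_cluster(cd.D)
    assign = cut_modules(tree, list(cd.D.index), height=0.5)
    ari = adjusted_rand_score(
        [truth[g] for g in cd.D.index], [assign.labels[g] for g in cd.D.index]
    )
    assert ari >= 0.9


def test_diana_estimator_labels():
    D = _toy_two_pairs()
    est = DianaClustering(n_clusters=2).fit(D)
    assert len(set(est.labels_)) == 2
    assert est.labels_[0] == est.labels_[1]
    assert est.labels_[2] == est.labels_[3]


# ---------------------------------------------------------------------------
# gene-set test


def test_gene_set_extreme_enrichment_probability():
    universe = [f"g{i}" for i in range(20)]
    module = universe[:4]
    res = gene_set_test(module, {"S": module}, universe)
    assert res.loc[0, "p"] == pytest.approx(1 / math.comb(20, 4))


def test_gene_set_disjoint_p_one():
    universe = [f"g{i}" for i in range(10)]
    res = gene_set_test(universe[:3], {"S": universe[9:]}, universe)
    # overlap 0 is the minimum possible here, so the upper tail is 1
    assert res.loc[0, "p"] == pytest.approx(1.0)


def test_gene_set_p_uniform_on_enumeration():
    """Hypergeometric tail p matches exhaustive enumeration at small N."""
    universe = list("abcdefgh")
    module = list("abc")
    anno = set("cde")
    import itertools

    overlaps = [
        len(set(m) & anno) for m in itertools.combinations(universe, 3)
    ]
    k_obs = len(set(module) & anno)
    exhaustive = sum(1 for k in overlaps if k >= k_obs) / len(overlaps)
    res = gene_set_test(module, {"S": list(anno)}, universe)
    assert res.loc[0, "p"] == pytest.approx(exhaustive)


def test_gene_set_bh_adjustment_monotone():
    universe = [f"g{i}" for i in range(40)]
    sets = {f"S{k}": universe[k : k + 8] for k in range(0, 24, 4)}
    res = gene_set_test(universe[:8], sets, universe)
    assert (res["p_adj"].to_numpy() >= res["p"].to_numpy() - 1e-12).all()
    assert res["p_adj"].is_monotonic_increasing


def test_gene_set_validation():
    with pytest.raises(ValueError, match="universe is empty"):
        gene_set_test([], {}, [])
    with pytest.raises(ValueError, match="outside universe"):
        gene_set_test(["x"], {}, ["a"])
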