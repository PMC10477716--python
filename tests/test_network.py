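"""Co-occurrence network inference, topology, modules and associations."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from soilcnet.community import DistanceMatrix, OTUTable
from soilcnet.network import (
    CooccurrenceNetwork,
    _spearman_exact_p,
    correlation_network,
    detect_modules,
    mantel,
    module_eigengene,
    module_env_association,
    prevalence_filter,
    topology,
    treatment_subnetwork,
)


def _table(counts: np.ndarray, treatments=None) -> OTUTable:
    n_otu, n_samp = counts.shape
    otus = [f"OTU_{i}" for i in range(n_otu)]
    samples = [f"s{i}" for i in range(n_samp)]
    if treatments is None:
        treatments = ["A"] * n_samp
    return OTUTable(
        counts=pd.DataFrame(counts, index=otus, columns=samples),
        taxonomy=pd.DataFrame({"class": ["c"] * n_otu}, index=otus),
        metadata=pd.DataFrame({"treatment": treatments}, index=samples),
    )


def _graph_network(g: nx.Graph) -> CooccurrenceNetwork:
    for _, _, d in g.edges(data=True):
        d.setdefault("sign", 1)
        d.setdefault("weight_abs", 1.0)
    return CooccurrenceNetwork(graph=g, alpha=0.01)


# ------------------------------------------------------- prevalence filter


def test_prevalence_filter_is_a_strict_majority_rule():
    """With 24 samples and the 0.5 cutoff, presence in 13 samples passes
    and presence in 12 does not (strictly greater than half)."""
    counts = np.zeros((2, 24), dtype=int)
    counts[0, :13] = 1
    counts[1, :12] = 1
    filt = prevalence_filter(_table(counts), min_fraction=0.5)
    assert list(filt.counts.index) == ["OTU_0"]


def test_prevalence_filter_matches_brute_force_recount(rng):
    counts = (rng.random((40, 24)) < 0.5).astype(int) * rng.integers(1, 9, (40, 24))
    counts[0] = 1  # guarantee at least one survivor
    t = _table(counts)
    filt = prevalence_filter(t, min_fraction=0.5)
    expected = [
        o for o in t.otu_ids
        if (t.counts.loc[o] > 0).sum() / 24 > 0.5
    ]
    assert list(filt.counts.index) == expected


def test_prevalence_filter_reports_when_nothing_passes():
    counts = np.zeros((3, 24), dtype=int)
    counts[:, 0] = 1
    with pytest.raises(ValueError, match="prevalence"):
        prevalence_filter(_table(counts), min_fraction=0.5)


# ------------------------------------------------------ correlation network


def test_perfectly_monotone_pair_forms_a_positive_edge(rng):
    n = 24
    base = np.arange(1, n + 1)
    counts = rng.integers(1, 100, size=(6, n))
    counts[0] = base
    counts[1] = base * 3 + 7  # strictly monotone transform: Spearman rho = 1
    net = correlation_network(_table(counts), alpha=0.01)
    assert net.graph.has_edge("OTU_0", "OTU_1")
    d = net.graph.edges["OTU_0", "OTU_1"]
    assert d["rho"] == pytest.approx(1.0, abs=1e-12)
    assert d["sign"] == 1


def test_anti_monotone_pair_forms_a_negative_edge(rng):
    n = 24
    counts = rng.integers(1, 100, size=(6, n))
    counts[0] = np.arange(1, n + 1)
    counts[1] = np.arange(n, 0, -1)
    net = correlation_network(_table(counts), alpha=0.01)
    assert net.graph.edges["OTU_0", "OTU_1"]["sign"] == -1


def test_network_nodes_are_edge_endpoints_only(bact_network):
    deg = dict(bact_network.graph.degree())
    assert all(d >= 1 for d in deg.values())


def test_edge_p_values_respect_the_alpha_cutoff(bact_network):
    edges = bact_network.edge_table()
    assert (edges["p_adj"] < 0.01).all()
    assert (edges["rho"].abs() <= 1).all()


def test_constant_otus_are_excluded_not_fatal(rng):
    counts = rng.integers(1, 100, size=(6, 24))
    counts[2] = 5  # constant profile: correlation undefined
    counts[0] = np.arange(1, 25)
    counts[1] = np.arange(1, 25) * 2
    net = correlation_network(_table(counts), alpha=0.01)
    assert net.provenance["n_constant_excluded"] == 1
    assert "OTU_2" not in net.graph


def test_correlation_network_needs_five_samples(rng):
    counts = rng.integers(1, 10, size=(4, 4))
    with pytest.raises(ValueError, match=">= 5"):
        correlation_network(_table(counts))


def test_exact_permutation_p_for_perfect_monotone_pair_at_n6():
    """n = 6 distinct values: only the identity and the full reversal reach
    |rho| = 1, so the exact two-sided p is 2/6! = 1/360."""
    x = np.array([1.0, 2, 3, 4, 5, 6])
    y = np.array([2.0, 4, 6, 8, 10, 12])
    p = _spearman_exact_p(x, y, 1.0)
    assert p == pytest.approx(2 / 720, abs=1e-15)


def test_small_sample_networks_use_exact_enumeration(rng):
    counts = rng.integers(1, 100, size=(5, 6))
    counts[0] = np.arange(1, 7)
    counts[1] = np.arange(1, 7) * 2
    net = correlation_network(_table(counts), alpha=0.05)
    if net.graph.has_edge("OTU_0", "OTU_1"):
        p_raw = net.graph.edges["OTU_0", "OTU_1"]["p_raw"]
        assert p_raw == pytest.approx(2 / 720, abs=1e-12)


def test_bh_adjustment_matches_the_step_up_formula():
    """Reference example: (0.001, 0.02, 0.03, 0.04) -> (0.004, 0.04, 0.04,
    0.04) under the Benjamini-Hochberg step-up."""
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.001, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    np.testing.assert_allclose(adj, [0.004, 0.04, 0.04, 0.04], atol=1e-12)


# ------------------------------------------------------------ subnetworks


def test_subnetwork_of_a_uniform_treatment_equals_the_global_network(rng):
    counts = rng.integers(1, 100, size=(8, 24))
    counts[0] = np.arange(1, 25)
    counts[1] = np.arange(1, 25) * 2
    t = _table(counts, treatments=["T1"] * 12 + ["T2"] * 12)
    net = correlation_network(t, alpha=0.01)
    sub = treatment_subnetwork(net, t, "T1", min_fraction=0.5)
    assert set(sub.graph.nodes) == set(net.graph.nodes)
    assert sub.graph.number_of_edges() == net.graph.number_of_edges()


def test_silenced_module_vanishes_from_its_treatment_subnetwork(
    community, bact_network
):
    table, truth = community
    silenced = truth.extras["silenced_modules"]
    for treatment, mods in silenced.items():
        sub = treatment_subnetwork(bact_network, table, treatment, min_fraction=0.5)
        members = {o for o, m in truth.module_assignment.items() if m in mods}
        assert not (set(sub.graph.nodes) & members)


def test_subnetwork_rejects_unknown_treatments(community, bact_network):
    table, _ = community
    with pytest.raises(ValueError, match="unknown treatment"):
        treatment_subnetwork(bact_network, table, "CONTROL")


# ---------------------------------------------------------------- topology


def brute_force_clustering(g: nx.Graph) -> float:
    """Triangle-enumeration oracle for the average clustering coefficient."""
    total = 0.0
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        total += 2.0 * tri / (k * (k - 1))
    return total / g.number_of_nodes()


def test_triangle_has_unit_clustering_coefficient():
    tri = nx.complete_graph(3)
    m = topology(_graph_network(tri))
    assert m.average_clustering_coefficient == pytest.approx(1.0)
    assert m.average_degree == pytest.approx(2.0)


def test_path_graph_has_zero_clustering():
    m = topology(_graph_network(nx.path_graph(4)))
    assert m.average_clustering_coefficient == 0.0


def test_topology_matches_triangle_enumeration_on_random_graphs():
    for seed in range(10):
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        m = topology(_graph_network(g))
        assert m.average_clustering_coefficient == pytest.approx(
            brute_force_clustering(g), abs=1e-12
        )
        assert m.average_degree == pytest.approx(
            2 * g.number_of_edges() / g.number_of_nodes(), abs=1e-12
        )


def test_empty_network_reports_zero_metrics_with_warning():
    with pytest.warns(UserWarning, match="empty network"):
        m = topology(_graph_network(nx.Graph()))
    assert m.nodes == 0 and m.edges == 0
    assert m.average_clustering_coefficient == 0.0


def test_signed_edge_counts_partition_the_edges(bact_network):
    m = topology(bact_network)
    assert m.positive_edges + m.negative_edges == m.edges


# ----------------------------------------------------------------- modules


def test_disjoint_cliques_are_recovered_as_two_modules():
    g = nx.union(
        nx.relabel_nodes(nx.complete_graph(5), {i: f"a{i}" for i in range(5)}),
        nx.relabel_nodes(nx.complete_graph(5), {i: f"b{i}" for i in range(5)}),
    )
    net = _graph_network(g)
    assignment, q = detect_modules(net, seed=0)
    assert len(set(assignment.values())) == 2
    assert q > 0.3
    # All members of each clique share a module label.
    assert len({assignment[f"a{i}"] for i in range(5)}) == 1
    assert len({assignment[f"b{i}"] for i in range(5)}) == 1


def test_module_labels_are_ordered_by_size():
    g = nx.union(
        nx.relabel_nodes(nx.complete_graph(6), {i: f"a{i}" for i in range(6)}),
        nx.relabel_nodes(nx.complete_graph(3), {i: f"b{i}" for i in range(3)}),
    )
    assignment, _ = detect_modules(_graph_network(g), seed=0)
    assert assignment["a0"] == 1
    assert assignment["b0"] == 2


def test_module_detection_requires_edges():
    with pytest.raises(ValueError, match="no edges"):
        detect_modules(_graph_network(nx.empty_graph(3)))


def test_module_detection_is_seeded(bact_network):
    a, qa = detect_modules(bact_network, seed=9)
    b, qb = detect_modules(bact_network, seed=9)
    assert a == b and qa == qb


# -------------------------------------------------------------- eigengenes


def test_eigengene_of_identical_profiles_explains_all_variance(rng):
    profile = rng.random(10)
    counts = pd.DataFrame(
        np.vstack([profile * 2, profile * 5, profile * 9]),
        index=["a", "b", "c"], columns=[f"s{i}" for i in range(10)],
    )
    me = module_eigengene(counts, ["a", "b", "c"])
    assert me.variance_explained == pytest.approx(1.0, abs=1e-12)
    # Sign convention: the eigengene tracks the mean member profile.
    r = stats.pearsonr(me.values, (profile - profile.mean())).statistic
    assert r == pytest.approx(1.0, abs=1e-9)


def test_eigengene_matches_an_independent_pca(rng):
    sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
    counts = pd.DataFrame(
        rng.random((6, 12)) + 1, index=list("abcdef"),
        columns=[f"s{i}" for i in range(12)],
    )
    me = module_eigengene(counts, list("abcdef"))
    z = counts.sub(counts.mean(axis=1), axis=0).div(counts.std(axis=1, ddof=1), axis=0)
    pc1 = sklearn_pca(n_components=1).fit_transform(z.to_numpy().T)[:, 0]
    r = np.corrcoef(me.values, pc1)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)


def test_eigengene_requires_two_members(rng):
    counts = pd.DataFrame(rng.random((2, 8)), index=["a", "b"],
                          columns=[f"s{i}" for i in range(8)])
    with pytest.raises(ValueError, match=">= 2"):
        module_eigengene(counts, ["a"])


def test_zero_variance_members_are_dropped(rng):
    counts = pd.DataFrame(
        np.vstack([rng.random(8), rng.random(8), np.full(8, 3.0)]),
        index=["a", "b", "c"], columns=[f"s{i}" for i in range(8)],
    )
    me = module_eigengene(counts, ["a", "b", "c"])
    assert np.isfinite(me.values).all()


# ------------------------------------------------------------ associations


def test_association_of_a_variable_with_itself_is_perfect(rng):
    v = rng.random(24)
    eg = pd.DataFrame({"ME1": v}, index=[f"s{i}" for i in range(24)])
    env = pd.DataFrame({"BIX": v}, index=eg.index)
    res = module_env_association(eg, env, n_permutations=999, seed=0)
    assert res.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)
    assert res.loc[0, "p_perm"] == pytest.approx(1 / 1000)
    assert res.loc[0, "stars"] == "**"


def test_association_sign_flips_with_the_variable(rng):
    v = rng.random(24)
    w = rng.random(24)
    eg = pd.DataFrame({"ME1": v}, index=[f"s{i}" for i in range(24)])
    a = module_env_association(eg, pd.DataFrame({"x": w}, index=eg.index),
                               n_permutations=49, seed=0)
    b = module_env_association(eg, pd.DataFrame({"x": -w}, index=eg.index),
                               n_permutations=49, seed=0)
    assert a.loc[0, "r"] == pytest.approx(-b.loc[0, "r"], abs=1e-12)
    assert a.loc[0, "p_perm"] == b.loc[0, "p_perm"]


def test_constant_environment_variables_yield_missing_associations(rng):
    eg = pd.DataFrame({"ME1": rng.random(10)}, index=[f"s{i}" for i in range(10)])
    env = pd.DataFrame({"flat": np.ones(10)}, index=eg.index)
    res = module_env_association(eg, env, n_permutations=9, seed=0)
    assert np.isnan(res.loc[0, "r"])
    assert res.loc[0, "stars"] == ""


def test_association_requires_shared_samples(rng):
    eg = pd.DataFrame({"ME1": rng.random(5)}, index=[f"a{i}" for i in range(5)])
    env = pd.DataFrame({"x": rng.random(5)}, index=[f"b{i}" for i in range(5)])
    with pytest.raises(ValueError, match="shared samples"):
        module_env_association(eg, env)


# ----------------------------------------------------------------- Mantel


def test_mantel_of_a_matrix_with_itself_is_perfect(rng):
    pts = rng.normal(size=(8, 3))
    m = squareform(pdist(pts))
    d = DistanceMatrix([f"s{i}" for i in range(8)], m)
    r, p = mantel(d, d, n_permutations=99, seed=0)
    assert r == pytest.approx(1.0, abs=1e-12)
    assert p == pytest.approx(1 / 100)


def test_mantel_is_invariant_to_affine_distance_transforms(rng):
    pts = rng.normal(size=(8, 3))
    m = squareform(pdist(pts))
    ids = [f"s{i}" for i in range(8)]
    m2 = 2.0 * m + 3.0
    np.fill_diagonal(m2, 0.0)
    r, _ = mantel(DistanceMatrix(ids, m), DistanceMatrix(ids, m2),
                  n_permutations=49, seed=0)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_mantel_aligns_matrices_by_sample_id(rng):
    pts = rng.normal(size=(8, 3))
    m = squareform(pdist(pts))
    ids = [f"s{i}" for i in range(8)]
    perm = np.random.default_rng(1).permutation(8)
    d1 = DistanceMatrix(ids, m)
    d2 = DistanceMatrix([ids[i] for i in perm], m[np.ix_(perm, perm)])
    r, _ = mantel(d1, d2, n_permutations=49, seed=0)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_mantel_rejects_disjoint_sample_sets(rng):
    m = squareform(pdist(rng.normal(size=(5, 2))))
    d1 = DistanceMatrix([f"a{i}" for i in range(5)], m)
    d2 = DistanceMatrix([f"b{i}" for i in range(5)], m)
    with pytest.raises(ValueError, match="different sample sets"):
        mantel(d1, d2)


# ------------------------------------------------ synthetic-study behavior


def test_gmc_subnetwork_is_most_complex(community, bact_network):
    """Both planted-module silencings hit the less-amended treatments, so
    the co-incorporation (GMC) subnetwork keeps the most nodes."""
    table, _ = community
    sizes = {}
    for t in ("NPK", "GM", "GMC"):
        sub = treatment_subnetwork(bact_network, table, t, min_fraction=0.5)
        sizes[t] = sub.graph.number_of_nodes()
    assert sizes["GMC"] >= sizes["GM"]
    assert sizes["GMC"] >= sizes["NPK"]
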