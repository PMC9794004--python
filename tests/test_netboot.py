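import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dualomics import netboot
from dualomics.core_io import AbundanceTable
from dualomics.errors import ParameterError, ValidationError


def _table(x: np.ndarray, names=None) -> AbundanceTable:
    n, k = x.shape
    names = names or [f"t{j}" for j in range(k)]
    df = pd.DataFrame(x, index=[f"s{i}" for i in range(n)], columns=names)
    return AbundanceTable(df, closure=float(x.sum(axis=1).mean()))


def _net_from_weights(weights: dict, nodes) -> netboot.CooccurrenceNetwork:
    edges = pd.DataFrame(
        [{"u": u, "v": v, "rho": r, "p_value": 0.0} for (u, v), r in weights.items()]
    )
    return netboot.CooccurrenceNetwork(nodes=list(nodes), edges=edges)


# ---------------------------------------------------------------------------
# build_network
# ---------------------------------------------------------------------------


def test_build_network_matches_per_pair_scipy(rng):
    """Vectorized all-pairs construction equals brute-force per-pair
    Spearman + BH at identical thresholds (k = 6)."""
    x = rng.lognormal(size=(25, 6))
    x[:, 1] = x[:, 0] * 2 + rng.normal(scale=0.05, size=25)
    x = x / x.sum(axis=1, keepdims=True)
    table = _table(x)
    net = netboot.build_network(table, rho_min=0.3, alpha=0.3, p_adjust=True)

    pairs, rhos, ps = [], [], []
    for i in range(6):
        for j in range(i + 1, 6):
            r, p = stats.spearmanr(x[:, i], x[:, j])
            pairs.append((f"t{i}", f"t{j}"))
            rhos.append(r)
            ps.append(p)
    fdr = multipletests(ps, method="fdr_bh")[1]
    expected = {
        pair: (r, q)
        for pair, r, q in zip(pairs, rhos, fdr)
        if abs(r) > 0.3 and q < 0.3
    }
    got = {
        (u, v): (r, q)
        for u, v, r, q in zip(
            net.edges["u"], net.edges["v"], net.edges["rho"], net.edges["fdr_p"]
        )
    }
    assert set(got) == set(expected)
    for pair in expected:
        assert got[pair][0] == pytest.approx(expected[pair][0], abs=1e-12)
        assert got[pair][1] == pytest.approx(expected[pair][1], rel=1e-9)


def test_monotone_pair_retained_with_rho_one(rng):
    x = rng.lognormal(size=(20, 4))
    x[:, 1] = np.exp(x[:, 0])  # perfectly monotone in column 0
    net = netboot.build_network(_table(x), rho_min=0.3, alpha=0.05)
    pair = net.edges.set_index(["u", "v"])
    assert ("t0", "t1") in pair.index
    assert pair.loc[("t0", "t1"), "rho"] == pytest.approx(1.0)


def test_rho_exactly_at_cutoff_excluded():
    rho = np.array([[1.0, 0.30], [0.30, 1.0]])
    p = np.zeros((2, 2))
    keep, _ = netboot._threshold_edges(rho, p, rho_min=0.3, alpha=0.05, p_adjust=False)
    assert not keep.any()  # strict |rho| > 0.3


def test_constant_taxon_warned_and_edgeless(rng):
    x = rng.lognormal(size=(15, 4))
    x[:, 3] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        net = netboot.build_network(_table(x), rho_min=0.0, alpha=1.0)
    assert not ((net.edges["u"] == "t3") | (net.edges["v"] == "t3")).any()
    assert "t3" in net.nodes  # node universe is fixed


# ---------------------------------------------------------------------------
# graph metrics
# ---------------------------------------------------------------------------


def test_triangle_metrics_hand_values():
    net = _net_from_weights(
        {("a", "b"): 0.5, ("b", "c"): 0.5, ("a", "c"): 0.5}, "abc"
    )
    m = netboot.graph_metrics(net)
    assert m["global_transitivity"] == pytest.approx(1.0)
    assert np.allclose(m["nodes"]["weighted_degree"], 1.0)
    # two hops of length 0.5 vs direct 0.5: closeness = 2 / (0.5+0.5) = 2
    assert np.allclose(m["nodes"]["weighted_closeness"], 2.0)
    assert np.allclose(m["nodes"]["eigenvector_centrality"], 1 / np.sqrt(3))


def test_path_graph_zero_transitivity():
    net = _net_from_weights({("a", "b"): 0.4, ("b", "c"): 0.4}, "abc")
    assert netboot.graph_metrics(net)["global_transitivity"] == 0.0


def test_two_node_closeness_formula():
    net = _net_from_weights({("a", "b"): 0.5}, "ab")
    m = netboot.graph_metrics(net)["nodes"]
    assert np.allclose(m["weighted_closeness"], 1.0 / 0.5)


def test_metrics_match_networkx_on_random_graph(rng):
    nx = pytest.importorskip("networkx")
    names = list("abcdefg")
    weights = {}
    for i in range(7):
        for j in range(i + 1, 7):
            if rng.random() < 0.5:
                weights[(names[i], names[j])] = rng.uniform(0.3, 0.9)
    net = _net_from_weights(weights, names)
    m = netboot.graph_metrics(net)
    g = nx.Graph()
    g.add_nodes_from(names)
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=w)
    assert m["global_transitivity"] == pytest.approx(nx.transitivity(g))
    strength = dict(g.degree(weight="weight"))
    assert np.allclose(
        m["nodes"]["weighted_degree"], [strength[n] for n in names]
    )
    ev = nx.eigenvector_centrality_numpy(g, weight="weight")
    mine = m["nodes"]["eigenvector_centrality"].to_numpy()
    ref = np.array([ev[n] for n in names])
    ref = np.abs(ref) / np.linalg.norm(ref)
    assert np.allclose(mine, ref, atol=1e-8)


def test_eigenvector_invariant_to_weight_scaling():
    w1 = {("a", "b"): 0.4, ("b", "c"): 0.6, ("a", "c"): 0.5, ("c", "d"): 0.3}
    w2 = {k: v / 2 for k, v in w1.items()}
    m1 = netboot.graph_metrics(_net_from_weights(w1, "abcd"))["nodes"]
    m2 = netboot.graph_metrics(_net_from_weights(w2, "abcd"))["nodes"]
    assert np.allclose(
        m1["eigenvector_centrality"], m2["eigenvector_centrality"]
    )


def test_closeness_decreases_when_edge_weakens():
    strong = _net_from_weights({("a", "b"): 0.8, ("b", "c"): 0.5}, "abc")
    weak = _net_from_weights({("a", "b"): 0.4, ("b", "c"): 0.5}, "abc")
    cs = netboot.graph_metrics(strong)["nodes"]["weighted_closeness"]
    cw = netboot.graph_metrics(weak)["nodes"]["weighted_closeness"]
    assert cw["a"] < cs["a"] and cw["b"] < cs["b"]


def test_empty_network_zero_metrics():
    net = _net_from_weights({}, "abc")
    net.edges = pd.DataFrame(columns=["u", "v", "rho", "p_value"])
    with pytest.warns(UserWarning, match="empty"):
        m = netboot.graph_metrics(net)
    assert m["global_transitivity"] == 0.0
    assert (m["nodes"] == 0).all().all()


# ---------------------------------------------------------------------------
# core species
# ---------------------------------------------------------------------------


def test_star_center_ranked_first():
    net = _net_from_weights(
        {("hub", "a"): 0.4, ("hub", "b"): 0.4, ("hub", "c"): 0.4},
        ["hub", "a", "b", "c"],
    )
    ranks = netboot.core_species(net, top_n=2)
    assert ranks["by_degree"][0] == "hub"


def test_degree_tie_broken_by_strength_then_name():
    net = _net_from_weights(
        {("a", "x"): 0.9, ("b", "x"): 0.4, ("c", "x"): 0.4}, ["a", "b", "c", "x"]
    )
    ranks = netboot.core_species(net)
    # a, b, c all have degree 1; a has the highest strength; b before c by name
    assert ranks["by_degree"][1:] == ["a", "b", "c"]


def test_empty_ranking():
    net = _net_from_weights({}, "ab")
    net.edges = pd.DataFrame(columns=["u", "v", "rho", "p_value"])
    with pytest.warns(UserWarning):
        ranks = netboot.core_species(net, top_n=0)
    assert ranks["by_degree"] == []


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _cohort_table(rng, n=40, k=8):
    x = rng.lognormal(size=(n, k))
    x[:, 1] = x[:, 0] ** 1.2 * np.exp(rng.normal(scale=0.1, size=n))
    t = _table(x / x.sum(axis=1, keepdims=True) * 100)
    g = pd.Series(["GDM"] * (n // 2) + ["NGT"] * (n - n // 2), index=t.sample_ids)
    return t, g


def test_bootstrap_deterministic_given_seed(rng):
    t, g = _cohort_table(rng)
    s1 = netboot.bootstrap_networks(t, g, subsample_size=15, n_replicates=5, seed=9)
    s2 = netboot.bootstrap_networks(t, g, subsample_size=15, n_replicates=5, seed=9)
    pd.testing.assert_frame_equal(s1.global_metrics, s2.global_metrics)
    assert np.array_equal(s1.edge_rho["GDM"], s2.edge_rho["GDM"])


def test_single_full_group_replicate_equals_direct_build(rng):
    t, g = _cohort_table(rng)
    sub = t.subset_samples([s for s, lab in g.items() if lab == "GDM"])
    direct = netboot.build_network(sub, rho_min=0.3, alpha=0.05, p_adjust=False)
    store = netboot.bootstrap_networks(
        t, g, subsample_size=20, n_replicates=1, seed=0, p_adjust=False
    )
    expected = np.zeros(len(store.pair_index))
    lookup = {frozenset(p): i for i, p in enumerate(store.pair_index)}
    for u, v, r in zip(direct.edges["u"], direct.edges["v"], direct.edges["rho"]):
        expected[lookup[frozenset((u, v))]] = r
    assert np.allclose(store.edge_rho["GDM"][0], expected)


def test_subsample_larger_than_group_rejected(rng):
    t, g = _cohort_table(rng)
    with pytest.raises(ParameterError):
        netboot.bootstrap_networks(t, g, subsample_size=30, n_replicates=2)


def _manual_store(a_vals, b_vals, n_a=50, n_b=54, m=30):
    reps = len(a_vals)
    rows = []
    for g, vals in (("GDM", a_vals), ("NGT", b_vals)):
        for i, v in enumerate(vals):
            rows.append({"replicate": i, "group": g, "global_transitivity": v})
    node_rows = []
    for g, vals in (("GDM", a_vals), ("NGT", b_vals)):
        for i, v in enumerate(vals):
            node_rows.append(
                {
                    "replicate": i,
                    "group": g,
                    "node": "n1",
                    "weighted_degree": v,
                    "weighted_closeness": v,
                    "eigenvector_centrality": v,
                }
            )
    return netboot.BootstrapStore(
        nodes=["n1"],
        groups=("GDM", "NGT"),
        global_metrics=pd.DataFrame(rows),
        node_metrics=pd.DataFrame(node_rows),
        edge_rho={"GDM": np.zeros((reps, 0)), "NGT": np.zeros((reps, 0))},
        pair_index=[],
        group_sizes={"GDM": n_a, "NGT": n_b},
        subsample_size=m,
    )


def test_identical_distributions_p_one():
    vals = list(np.linspace(0.2, 0.8, 10))
    store = _manual_store(vals, vals)
    for method in ("ranksum", "subsampling_z"):
        comp = netboot.compare_metric_distributions(store, method=method)
        assert (comp["p_value"] == 1.0).all()


def test_disjoint_constant_distributions_extreme_p():
    """100 replicates pinned at 0.8 vs 0.2: the rank-sum on replicate values
    is astronomically small; the degenerate-variance z-test reports 0."""
    store = _manual_store([0.8] * 100, [0.2] * 100)
    comp = netboot.compare_metric_distributions(store, method="ranksum")
    assert comp.loc["global_transitivity", "p_value"] < 1e-10
    compz = netboot.compare_metric_distributions(store, method="subsampling_z")
    assert compz.loc["global_transitivity", "p_value"] == 0.0


def test_single_replicate_rejected():
    store = _manual_store([0.5], [0.4])
    with pytest.raises(ValidationError):
        netboot.compare_metric_distributions(store)


# ---------------------------------------------------------------------------
# focal edges
# ---------------------------------------------------------------------------


def _focal_store(rng):
    nodes = ["focal", "p1", "p2", "p3"]
    pair_index = [
        ("focal", "p1"),
        ("focal", "p2"),
        ("focal", "p3"),
        ("p1", "p2"),
        ("p1", "p3"),
        ("p2", "p3"),
    ]
    reps = 40
    a = np.zeros((reps, 6))
    b = np.zeros((reps, 6))
    a[:, 0] = 0.5 + rng.normal(scale=0.01, size=reps)  # focal-p1 positive in A
    b[:, 0] = -0.5 + rng.normal(scale=0.01, size=reps)  # negative in B
    a[:, 1] = rng.normal(scale=0.02, size=reps)  # focal-p2 noise in both
    b[:, 1] = rng.normal(scale=0.02, size=reps)
    # focal-p3 never connected anywhere
    gm = pd.DataFrame(
        [
            {"replicate": i, "group": g, "global_transitivity": 0.1}
            for g in ("GDM", "NGT")
            for i in range(reps)
        ]
    )
    return netboot.BootstrapStore(
        nodes=nodes,
        groups=("GDM", "NGT"),
        global_metrics=gm,
        node_metrics=pd.DataFrame(
            columns=["replicate", "group", "node"] + list(netboot.NODE_METRICS)
        ),
        edge_rho={"GDM": a, "NGT": b},
        pair_index=pair_index,
        group_sizes={"GDM": 50, "NGT": 54},
        subsample_size=30,
    )


def test_focal_edges_rank_separated_partner_first(rng):
    store = _focal_store(rng)
    out = netboot.focal_edge_comparison(store, "focal", top_n=10)
    assert out.index[0] == "p1"
    assert out.loc["p1", "sign_a"] == 1 and out.loc["p1", "sign_b"] == -1
    assert "p3" not in out.index  # never connected -> excluded
    assert len(out) <= 10
    capped = netboot.focal_edge_comparison(store, "focal", top_n=1)
    assert len(capped) == 1
    with pytest.raises(ValidationError):
        netboot.focal_edge_comparison(store, "nope")
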