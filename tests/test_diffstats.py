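from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualomics import diffstats
from dualomics.core_io import AbundanceTable
from dualomics.errors import ParameterError, ValidationError

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def exact_ranksum_p(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating all ways the
    pooled ranks can be split between the groups (tie-free data only)."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1
    ra = ranks[: len(a)]
    u_obs = ra.sum() - len(a) * (len(a) + 1) / 2
    n1n0 = len(a) * len(b)
    u_star = min(u_obs, n1n0 - u_obs)
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), len(a)):
        u = sum(sorted(range(1, len(pooled) + 1))[i] for i in comb) - len(a) * (
            len(a) + 1
        ) / 2
        total += 1
        if u <= u_star or u >= n1n0 - u_star:
            count += 1
    return count / total


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def _frame(a, b):
    data = pd.DataFrame({"f": np.concatenate([a, b])})
    data.index = [f"s{i}" for i in range(len(a) + len(b))]
    groups = pd.Series(
        ["GDM"] * len(a) + ["NGT"] * len(b), index=data.index
    )
    return data, groups


# ---------------------------------------------------------------------------
# wilcoxon_bh
# ---------------------------------------------------------------------------


def test_identical_groups_p_one():
    data, groups = _frame([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
    res = diffstats.wilcoxon_bh(data, groups)
    assert res["p_value"].iloc[0] == pytest.approx(1.0)


def test_fully_separated_small_groups_exact_p():
    # A = (1,2,3) vs B = (4,5,6): 2 of the C(6,3) = 20 splits are as extreme
    data, groups = _frame([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    res = diffstats.wilcoxon_bh(data, groups)
    assert res["p_value"].iloc[0] == pytest.approx(0.1)


def test_constant_feature_flagged_with_p_one():
    data, groups = _frame([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    with pytest.warns(UserWarning, match="constant"):
        res = diffstats.wilcoxon_bh(data, groups)
    assert res["constant"].iloc[0]
    assert res["p_value"].iloc[0] == 1.0


def test_fold_change_follows_case_over_control():
    data, groups = _frame([4.0, 6.0], [1.0, 1.0])
    res = diffstats.wilcoxon_bh(data, groups)
    assert res["mean_a"].iloc[0] == pytest.approx(5.0)
    assert res["fold_change"].iloc[0] == pytest.approx(5.0)


@settings(deadline=None, max_examples=40)
@given(
    st.integers(3, 8),
    st.integers(3, 8),
    st.integers(0, 10_000),
)
def test_exact_p_matches_enumeration_oracle(n1, n2, seed):
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(n1 + n2, dtype=float))  # tie-free
    a, b = vals[:n1], vals[n1:]
    data, groups = _frame(a, b)
    res = diffstats.wilcoxon_bh(data, groups)
    assert res["p_value"].iloc[0] == pytest.approx(exact_ranksum_p(a, b))


def test_bh_hand_example_all_adjusted_to_largest():
    # p = (.01, .02, .03, .04): step-up gives .04 for every feature
    adj = bh_stepup([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)


@settings(deadline=None, max_examples=40)
@given(st.integers(1, 100), st.integers(0, 10_000))
def test_bh_matches_stepup_definition(m, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=m)
    from statsmodels.stats.multitest import multipletests

    assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_stepup(p))


# ---------------------------------------------------------------------------
# FDR threshold
# ---------------------------------------------------------------------------


def test_fdr_threshold_strict_inequality():
    res = pd.DataFrame({"fdr_p": [0.19, 0.20, 0.21]}, index=list("abc"))
    kept = diffstats.apply_fdr_threshold(res, 0.2)
    assert list(kept.index) == ["a"]
    assert len(diffstats.apply_fdr_threshold(res, 1.0)) == 3
    assert diffstats.apply_fdr_threshold(res.iloc[:0], 0.2).empty
    with pytest.raises(ParameterError):
        diffstats.apply_fdr_threshold(res, 0.0)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def test_diversity_hand_values():
    t = AbundanceTable(
        pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]],
            index=["S1", "S2"],
            columns=["a", "b", "c"],
        ),
        closure=1.0,
    )
    d = diffstats.diversity(t)
    assert d.loc["S1", "richness"] == 2
    assert d.loc["S1", "shannon"] == pytest.approx(np.log(2))


def test_diversity_uniform_is_log_k():
    k = 7
    t = AbundanceTable(
        pd.DataFrame([[1.0 / k] * k], index=["S1"]), closure=1.0
    )
    assert diffstats.diversity(t).loc["S1", "shannon"] == pytest.approx(np.log(k))


def test_richness_monotone_in_threshold():
    t = AbundanceTable(
        pd.DataFrame([[0.6, 0.3, 0.1]], index=["S1"]), closure=1.0
    )
    r = [
        diffstats.diversity(t, thr).loc["S1", "richness"]
        for thr in (0.0, 0.05, 0.2, 0.5, 0.9)
    ]
    assert r == sorted(r, reverse=True)
    assert r[-1] == 0  # threshold above the maximum abundance


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def _cluster_table(rng, sep=1.0):
    a = rng.uniform(0, 0.02, size=(4, 6)) + np.array([sep, 0, 0, 0, 0, 0])
    b = rng.uniform(0, 0.02, size=(4, 6)) + np.array([0, 0, 0, 0, 0, sep])
    x = np.vstack([a, b])
    x = x / x.sum(axis=1, keepdims=True)
    t = AbundanceTable(
        pd.DataFrame(x, index=[f"s{i}" for i in range(8)]), closure=1.0
    )
    g = pd.Series(["A"] * 4 + ["B"] * 4, index=t.sample_ids)
    return t, g


def test_anosim_separated_clusters_r_one(rng):
    t, g = _cluster_table(rng)
    res = diffstats.anosim(t, g, n_permutations=499, seed=0)
    assert res["r_statistic"] == pytest.approx(1.0)
    assert res["p_value"] < 0.05


def test_anosim_matches_skbio_r_statistic(rng):
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    from scipy.spatial.distance import pdist, squareform

    x = rng.dirichlet(np.ones(5), size=10)
    t = AbundanceTable(
        pd.DataFrame(x, index=[f"s{i}" for i in range(10)]), closure=1.0
    )
    g = pd.Series(["A"] * 5 + ["B"] * 5, index=t.sample_ids)
    mine = diffstats.anosim(t, g, n_permutations=9, seed=0)
    dm = skbio_stats.DistanceMatrix(
        squareform(pdist(x, metric="braycurtis")), ids=t.sample_ids
    )
    ref = skbio_stats.anosim(dm, g.to_numpy(), permutations=9)
    assert mine["r_statistic"] == pytest.approx(ref["test statistic"], abs=1e-12)


def test_anosim_null_p_values_roughly_uniform(rng):
    """Shuffled labels on unstructured data: permutation p-values should not
    concentrate at small values (KS test against uniform, loose level)."""
    from scipy import stats as sps

    pvals = []
    for i in range(60):
        x = rng.dirichlet(np.ones(6), size=12)
        t = AbundanceTable(
            pd.DataFrame(x, index=[f"s{j}" for j in range(12)]), closure=1.0
        )
        g = pd.Series(
            rng.permutation(["A"] * 6 + ["B"] * 6), index=t.sample_ids
        )
        pvals.append(diffstats.anosim(t, g, n_permutations=49, seed=i)["p_value"])
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_anosim_singleton_group_rejected(rng):
    t, g = _cluster_table(rng)
    g.iloc[:] = ["A"] + ["B"] * 7
    with pytest.raises(ValidationError):
        diffstats.anosim(t, g)


# ---------------------------------------------------------------------------
# taxon ratio
# ---------------------------------------------------------------------------


def test_taxon_ratio_basic_and_zero_handling():
    t = AbundanceTable(
        pd.DataFrame(
            {"Prevotella": [0.2, 0.0, 0.3], "Bacteroides": [0.1, 0.5, 0.0]},
            index=["S1", "S2", "S3"],
        ),
        closure=0.3,
    )
    r = diffstats.taxon_ratio(t, "Prevotella", "Bacteroides", pseudocount=1e-6)
    assert r.loc["S1", "ratio"] == pytest.approx(2.0)
    assert r.loc["S2", "ratio"] == pytest.approx(0.0, abs=1e-5)
    assert r.loc["S3", "zero_denominator"]
    assert np.isfinite(r.loc["S3", "ratio"]) and r.loc["S3", "ratio"] > 1e4
    with pytest.raises(ValidationError):
        diffstats.taxon_ratio(t, "Prevotella", "Alistipes")
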