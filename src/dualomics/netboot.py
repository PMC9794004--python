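"""Microbial co-occurrence networks and bootstrapped between-group comparison.

Networks are built on the top-k most abundant species: Spearman correlation
over all taxon pairs, an edge retained when the (optionally BH-adjusted)
p-value falls below alpha AND |rho| strictly exceeds rho_min.  Negative
correlations are kept as signed edge attributes; all metric computations use
|rho| as the weight and 1 - |rho| as the path length.

Group structure is compared by rebuilding networks on repeated random
subsamples (default 30 samples per group, 100 replicates, drawn without
replacement -- with-replacement duplicates would corrupt rank correlations)
and rank-sum testing the resulting metric distributions, plus per-partner
edge-weight distributions around a focal species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from dualomics import diffstats
from dualomics.core_io import AbundanceTable
from dualomics.errors import ParameterError, ValidationError

GLOBAL_METRICS = ("global_transitivity",)
NODE_METRICS = ("weighted_degree", "weighted_closeness", "eigenvector_centrality")


@dataclass
class CooccurrenceNetwork:
    """Undirected signed-weight network over a fixed node universe.

    ``edges`` has columns ``u``, ``v``, ``rho``, ``p_value`` and (when BH was
    applied) ``fdr_p``.  Isolated nodes remain in ``nodes`` so that metric
    distributions stay comparable across replicates.
    """

    nodes: list[str]
    edges: pd.DataFrame
    group: str | None = None
    rho_min: float = 0.3
    alpha: float = 0.05
    p_adjusted: bool = True

    def adjacency(self, signed: bool = False) -> np.ndarray:
        """Dense weight matrix (|rho|, or signed rho when requested)."""
        k = len(self.nodes)
        pos = {n: i for i, n in enumerate(self.nodes)}
        w = np.zeros((k, k))
        for u, v, rho in zip(self.edges["u"], self.edges["v"], self.edges["rho"]):
            val = rho if signed else abs(rho)
            w[pos[u], pos[v]] = val
            w[pos[v], pos[u]] = val
        return w


@dataclass
class BootstrapStore:
    """All per-replicate outputs of the bootstrapped network comparison."""

    nodes: list[str]
    groups: tuple[str, str]
    global_metrics: pd.DataFrame  # columns: replicate, group, global_transitivity
    node_metrics: pd.DataFrame  # long: replicate, group, node, <metrics>
    #: per group: (n_replicates x n_pairs) signed rho, 0 where no edge survived
    edge_rho: dict[str, np.ndarray] = field(default_factory=dict)
    pair_index: list[tuple[str, str]] = field(default_factory=list)
    group_sizes: dict[str, int] = field(default_factory=dict)
    subsample_size: int = 0


# ---------------------------------------------------------------------------
# Correlation machinery (vectorized over all pairs)
# ---------------------------------------------------------------------------


def _spearman_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided p (t approximation, ties via
    midranks), matching the standard per-pair computation."""
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    sd = ranks.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    return rho, p


def _threshold_edges(
    rho: np.ndarray, p: np.ndarray, rho_min: float, alpha: float, p_adjust: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean retained-edge matrix and the (possibly adjusted) pair p-values.

    Returns (keep, p_used) where both are condensed over the upper triangle.
    """
    iu = np.triu_indices(rho.shape[0], k=1)
    rho_pairs = rho[iu]
    p_pairs = p[iu]
    valid = ~np.isnan(rho_pairs)
    p_used = np.full_like(p_pairs, np.nan)
    if p_adjust:
        if valid.any():
            p_used[valid] = multipletests(p_pairs[valid], method="fdr_bh")[1]
    else:
        p_used[valid] = p_pairs[valid]
    keep = valid & (np.abs(rho_pairs) > rho_min) & (p_used < alpha)
    return keep, p_used


def build_network(
    table: AbundanceTable,
    rho_min: float = 0.3,
    alpha: float = 0.05,
    p_adjust: bool = True,
    group: str | None = None,
) -> CooccurrenceNetwork:
    """Spearman co-occurrence network over all taxon pairs of the table.

    An edge survives when |rho| > rho_min (strict) and its BH-adjusted
    (or raw, ``p_adjust=False``) p-value is below alpha.  Constant taxa yield
    undefined correlations and contribute no edges (warned).
    """
    if table.n_taxa < 3:
        raise ParameterError("need at least 3 taxa to build a network")
    if table.n_samples < 5:
        raise ParameterError("need at least 5 samples to build a network")
    x = table.data.to_numpy(dtype=float)
    rho, p = _spearman_matrix(x)
    if np.isnan(rho).any():
        warnings.warn("constant taxa produced undefined correlations", stacklevel=2)
    keep, p_used = _threshold_edges(rho, p, rho_min, alpha, p_adjust)
    iu = np.triu_indices(table.n_taxa, k=1)
    names = np.asarray(table.taxon_ids)
    edges = pd.DataFrame(
        {
            "u": names[iu[0][keep]],
            "v": names[iu[1][keep]],
            "rho": rho[iu][keep],
            "p_value": p[iu][keep],
        }
    )
    if p_adjust:
        edges["fdr_p"] = p_used[keep]
    return CooccurrenceNetwork(
        nodes=list(table.taxon_ids),
        edges=edges,
        group=group,
        rho_min=rho_min,
        alpha=alpha,
        p_adjusted=p_adjust,
    )


# ---------------------------------------------------------------------------
# Graph metrics (weight = |rho|, length = 1 - |rho|)
# ---------------------------------------------------------------------------


def _metrics_from_weights(w: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """(transitivity, strength, closeness, eigenvector) from a dense |rho|
    weight matrix with zero diagonal."""
    k = w.shape[0]
    a = (w > 0).astype(float)
    deg = a.sum(axis=1)
    triads = float(np.sum(deg * (deg - 1)))
    if triads > 0:
        closed = float(np.trace(a @ a @ a))
        transitivity = closed / triads
    else:
        transitivity = 0.0
    strength = w.sum(axis=1)
    # shortest paths on lengths 1 - |rho|
    lengths = np.where(w > 0, 1.0 - w, np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    closeness = np.zeros(k)
    for i in range(k):
        d = dist[i]
        reach = np.isfinite(d) & (np.arange(k) != i)
        if reach.any():
            closeness[i] = reach.sum() / d[reach].sum()
    if a.sum() > 0:
        evals, evecs = np.linalg.eigh(w)
        vec = evecs[:, -1]
        if vec.sum() < 0:
            vec = -vec
        vec = np.clip(vec, 0.0, None)
        norm = np.linalg.norm(vec)
        eigen = vec / norm if norm > 0 else vec
    else:
        eigen = np.zeros(k)
    return transitivity, strength, closeness, eigen


def graph_metrics(net: CooccurrenceNetwork) -> dict:
    """Global transitivity plus per-node strength, closeness, eigenvector.

    Transitivity is the unweighted global clustering coefficient
    (3 x triangles / connected triples) on retained edges; node metrics use
    |rho| weights.  An empty edge set yields all-zero metrics with a warning.
    """
    w = net.adjacency(signed=False)
    if not (w > 0).any():
        warnings.warn("empty edge set: all metrics zero", stacklevel=2)
    transitivity, strength, closeness, eigen = _metrics_from_weights(w)
    node_df = pd.DataFrame(
        {
            "degree": (w > 0).sum(axis=1),
            "weighted_degree": strength,
            "weighted_closeness": closeness,
            "eigenvector_centrality": eigen,
        },
        index=pd.Index(net.nodes, name="node"),
    )
    return {"global_transitivity": transitivity, "nodes": node_df}


def core_species(net: CooccurrenceNetwork, top_n: int | None = None) -> dict:
    """Node rankings: by unweighted degree (ties: strength, then name), and
    separately by weighted degree and weighted closeness."""
    m = graph_metrics(net)["nodes"]
    by_degree = sorted(
        net.nodes,
        key=lambda v: (-m.loc[v, "degree"], -m.loc[v, "weighted_degree"], v),
    )
    by_strength = sorted(
        net.nodes, key=lambda v: (-m.loc[v, "weighted_degree"], v)
    )
    by_closeness = sorted(
        net.nodes, key=lambda v: (-m.loc[v, "weighted_closeness"], v)
    )
    if top_n is not None:
        by_degree = by_degree[:top_n]
        by_strength = by_strength[:top_n]
        by_closeness = by_closeness[:top_n]
    return {
        "by_degree": by_degree,
        "by_weighted_degree": by_strength,
        "by_weighted_closeness": by_closeness,
        "metrics": m,
    }


# ---------------------------------------------------------------------------
# Bootstrap comparison
# ---------------------------------------------------------------------------


def bootstrap_networks(
    table: AbundanceTable,
    groups: pd.Series,
    subsample_size: int = 30,
    n_replicates: int = 100,
    rho_min: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
    p_adjust: bool = False,
    with_replacement: bool = False,
    group_labels: tuple[str, str] = ("GDM", "NGT"),
) -> BootstrapStore:
    """Replicate networks on random subsamples of each group.

    Each replicate draws ``subsample_size`` samples per group (without
    replacement by default), rebuilds the network with identical thresholds
    (raw-p edge test by default inside replicates), and records the global
    transitivity, all node metrics, and every pair's retained signed rho
    (0 when the edge did not survive).  Deterministic given ``seed``.
    """
    groups = groups.reindex(table.sample_ids)
    x = table.data.to_numpy(dtype=float)
    names = np.asarray(table.taxon_ids)
    k = len(names)
    iu = np.triu_indices(k, k=1)
    pair_index = [(names[i], names[j]) for i, j in zip(*iu)]
    rng = np.random.default_rng(seed)

    glob_rows = []
    node_rows = {g: [] for g in group_labels}
    edge_rho: dict[str, np.ndarray] = {}
    for g in group_labels:
        idx = np.flatnonzero((groups == g).to_numpy())
        if subsample_size > len(idx) and not with_replacement:
            raise ParameterError(
                f"subsample_size {subsample_size} exceeds group {g} size {len(idx)}"
            )
        rhos = np.zeros((n_replicates, len(pair_index)))
        for rep in range(n_replicates):
            sub = rng.choice(idx, size=subsample_size, replace=with_replacement)
            rho, p = _spearman_matrix(x[sub])
            keep, _ = _threshold_edges(rho, p, rho_min, alpha, p_adjust)
            rho_pairs = np.where(keep, np.nan_to_num(rho[iu]), 0.0)
            rhos[rep] = rho_pairs
            w = np.zeros((k, k))
            w[iu] = np.abs(rho_pairs)
            w = w + w.T
            transitivity, strength, closeness, eigen = _metrics_from_weights(w)
            glob_rows.append(
                {"replicate": rep, "group": g, "global_transitivity": transitivity}
            )
            node_rows[g].append((rep, strength, closeness, eigen))
        edge_rho[g] = rhos

    node_frames = []
    for g in group_labels:
        for rep, strength, closeness, eigen in node_rows[g]:
            node_frames.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "group": g,
                        "node": names,
                        "weighted_degree": strength,
                        "weighted_closeness": closeness,
                        "eigenvector_centrality": eigen,
                    }
                )
            )
    return BootstrapStore(
        nodes=list(names),
        groups=group_labels,
        global_metrics=pd.DataFrame(glob_rows),
        node_metrics=pd.concat(node_frames, ignore_index=True),
        edge_rho=edge_rho,
        pair_index=pair_index,
        group_sizes={
            g: int((groups == g).sum()) for g in group_labels
        },
        subsample_size=subsample_size,
    )


def _subsampling_z_p(
    a: np.ndarray, b: np.ndarray, n_a: int, n_b: int, m: int
) -> float:
    """Two-sided p for a group difference of a subsampled statistic.

    Replicates within a group resample one cohort, so their spread estimates
    the sampling variability of the statistic at subsample size ``m`` around
    the cohort value, sigma^2 * (1/m - 1/n_g) for mean-like statistics.  The
    cohort values themselves fluctuate with variance sigma^2 / n_g, so the
    replicate variance is extrapolated by the factor m / (n_g - m) before the
    two cohort values are compared; this keeps the test calibrated where a
    naive rank-sum over the (mutually dependent) replicates is not.
    """
    delta = a.mean() - b.mean()
    var = 0.0
    for vals, n_g in ((a, n_a), (b, n_b)):
        if n_g <= m:
            continue  # degenerate: subsample equals the cohort
        var += vals.var(ddof=1) * m / (n_g - m)
    if var == 0:
        return 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def compare_metric_distributions(
    store: BootstrapStore,
    method: str = "subsampling_z",
    node_mode: str = "replicate_mean",
) -> pd.DataFrame:
    """Between-group comparison of the replicate metric distributions.

    Global transitivity is compared on per-replicate values.  Node metrics
    are aggregated per replicate (mean over nodes) by default, or pooled over
    nodes x replicates with ``node_mode="pooled"``.

    ``method="subsampling_z"`` (default) extrapolates the replicate spread to
    cohort-level uncertainty before comparing the two groups, which keeps the
    comparison calibrated despite the dependence among replicates of one
    cohort.  ``method="ranksum"`` is the classical two-sided rank-sum test on
    the raw replicate values; it treats dependent replicates as independent
    observations and is strongly anticonservative, but is provided because it
    is the conventional display statistic for bootstrap network comparisons.
    BH is applied across the compared metrics.
    """
    if node_mode not in ("replicate_mean", "pooled"):
        raise ParameterError(f"unknown node_mode {node_mode!r}")
    if method not in ("subsampling_z", "ranksum"):
        raise ParameterError(f"unknown method {method!r}")
    g_a, g_b = store.groups
    gm = store.global_metrics
    n_rep = gm.groupby("group")["replicate"].nunique()
    if (n_rep < 2).any():
        raise ValidationError("need >=2 replicates per group")
    cols = {}
    for metric in GLOBAL_METRICS:
        cols[metric] = gm.pivot(index="replicate", columns="group", values=metric)
    nm = store.node_metrics
    for metric in NODE_METRICS:
        if node_mode == "replicate_mean":
            agg = nm.groupby(["replicate", "group"])[metric].mean().reset_index()
            cols[metric] = agg.pivot(
                index="replicate", columns="group", values=metric
            )
        else:
            cols[metric] = None  # handled below
    rows = []
    for metric in GLOBAL_METRICS + NODE_METRICS:
        if cols.get(metric) is not None:
            a = cols[metric][g_a].to_numpy()
            b = cols[metric][g_b].to_numpy()
        else:
            a = nm.loc[nm["group"] == g_a, metric].to_numpy()
            b = nm.loc[nm["group"] == g_b, metric].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        elif method == "ranksum":
            p = diffstats._rank_sum_p(a, b)
        else:
            p = _subsampling_z_p(
                a,
                b,
                store.group_sizes.get(g_a, store.subsample_size),
                store.group_sizes.get(g_b, store.subsample_size),
                store.subsample_size,
            )
        rows.append(
            {
                "feature": metric,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "fold_change": a.mean() / b.mean() if b.mean() != 0 else np.nan,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["fdr_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out.attrs["group_a"], out.attrs["group_b"] = g_a, g_b
    out.attrs["method"] = method
    return out


def permutation_metric_comparison(
    table: AbundanceTable,
    groups: pd.Series,
    rho_min: float = 0.3,
    alpha: float = 0.05,
    p_adjust: bool = False,
    n_permutations: int = 299,
    seed: int = 0,
    group_labels: tuple[str, str] = ("GDM", "NGT"),
) -> pd.DataFrame:
    """Label-permutation test for between-group network metric differences.

    The statistic per metric is the difference between the two full-group
    networks (node metrics averaged over nodes); its null distribution is
    obtained by shuffling the group labels over samples and rebuilding both
    networks, which makes the test exactly calibrated at the cohort level.
    p = (1 + #{|permuted delta| >= |observed delta|}) / (1 + B), two-sided.
    """
    groups = groups.reindex(table.sample_ids)
    g_a, g_b = group_labels
    x = table.data.to_numpy(dtype=float)
    k = table.n_taxa
    iu = np.triu_indices(k, k=1)
    labels = groups.to_numpy()

    def _metric_vector(idx: np.ndarray) -> np.ndarray:
        rho, p = _spearman_matrix(x[idx])
        keep, _ = _threshold_edges(rho, p, rho_min, alpha, p_adjust)
        w = np.zeros((k, k))
        w[iu] = np.where(keep, np.abs(np.nan_to_num(rho[iu])), 0.0)
        w = w + w.T
        transitivity, strength, closeness, eigen = _metrics_from_weights(w)
        return np.array(
            [transitivity, strength.mean(), closeness.mean(), eigen.mean()]
        )

    def _delta(lab: np.ndarray) -> np.ndarray:
        return _metric_vector(np.flatnonzero(lab == g_a)) - _metric_vector(
            np.flatnonzero(lab == g_b)
        )

    obs = _delta(labels)
    rng = np.random.default_rng(seed)
    count = np.zeros_like(obs)
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        count += np.abs(_delta(perm)) >= np.abs(obs)
    pvals = (1 + count) / (1 + n_permutations)
    out = pd.DataFrame(
        {
            "delta": obs,
            "p_value": pvals,
            "fdr_p": multipletests(pvals, method="fdr_bh")[1],
        },
        index=pd.Index(GLOBAL_METRICS + NODE_METRICS, name="feature"),
    )
    out.attrs["group_a"], out.attrs["group_b"] = g_a, g_b
    return out


def compare_node_metric(
    store: BootstrapStore, node: str, metric: str = "weighted_degree"
) -> dict:
    """Rank-sum test of one node's replicate metric values between groups
    (the focal-species comparison of the bootstrap analysis)."""
    if node not in store.nodes:
        raise ValidationError(f"node {node!r} not in bootstrap store")
    nm = store.node_metrics
    g_a, g_b = store.groups
    sel = nm[nm["node"] == node]
    a = sel.loc[sel["group"] == g_a, metric].to_numpy()
    b = sel.loc[sel["group"] == g_b, metric].to_numpy()
    p = 1.0 if np.ptp(np.concatenate([a, b])) == 0 else diffstats._rank_sum_p(a, b)
    return {"node": node, "metric": metric, "mean_a": float(a.mean()),
            "mean_b": float(b.mean()), "p_value": float(p)}


def focal_edge_comparison(
    store: BootstrapStore, focal_species: str, top_n: int = 10
) -> pd.DataFrame:
    """Partner-wise comparison of replicate edge weights around one species.

    For every partner of the focal species, the per-replicate signed rho
    values (0 when the edge was absent in a replicate) are rank-sum tested
    between groups; partners never connected in either group are excluded
    (p = 1 by construction).  BH runs across the tested partners and the
    ``top_n`` most significant rows are returned with group-wise medians.
    """
    if focal_species not in store.nodes:
        raise ValidationError(f"focal species {focal_species!r} not in store")
    g_a, g_b = store.groups
    cols = [
        (j, (u if v == focal_species else v))
        for j, (u, v) in enumerate(store.pair_index)
        if focal_species in (u, v)
    ]
    rows = []
    for j, partner in cols:
        a = store.edge_rho[g_a][:, j]
        b = store.edge_rho[g_b][:, j]
        if not (a.any() or b.any()):
            continue
        p = 1.0 if np.ptp(np.concatenate([a, b])) == 0 else diffstats._rank_sum_p(a, b)
        rows.append(
            {
                "partner": partner,
                "median_rho_a": float(np.median(a)),
                "median_rho_b": float(np.median(b)),
                "sign_a": int(np.sign(np.median(a))),
                "sign_b": int(np.sign(np.median(b))),
                "p_value": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "partner",
                "median_rho_a",
                "median_rho_b",
                "sign_a",
                "sign_b",
                "p_value",
                "fdr_p",
            ]
        ).set_index("partner")
    out = pd.DataFrame(rows).set_index("partner")
    out["fdr_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(["p_value", "partner"]).head(top_n)
    out.attrs["group_a"], out.attrs["group_b"] = g_a, g_b
    return out
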