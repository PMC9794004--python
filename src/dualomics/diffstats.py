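"""Rank-based two-group comparisons, FDR control, diversity, ANOSIM, ratios.

Every two-group comparison in the workflow is a two-sided Wilcoxon rank-sum
(Mann-Whitney) test with Benjamini-Hochberg adjustment across the features of
one analysis table (one FDR family per table).  Fold changes follow the
case/control convention: mean(group_a) / mean(group_b) with group_a the
disease group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from dualomics.core_io import AbundanceTable
from dualomics.errors import ParameterError, ValidationError

#: Largest per-group size for which the exact rank-sum null is enumerated
#: (ties always force the normal approximation with tie correction).
EXACT_MAX_N = 12


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact when small and tie-free, else normal
    approximation with tie and continuity correction."""
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def wilcoxon_bh(
    data: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "GDM",
    group_b: str = "NGT",
) -> pd.DataFrame:
    """Per-feature two-sided rank-sum tests with BH adjustment.

    Parameters
    ----------
    data:
        Samples x features frame.
    groups:
        Group label per sample, aligned on the sample index.
    group_a, group_b:
        Which labels form the comparison; fold change is
        mean(group_a)/mean(group_b).

    Returns
    -------
    DataFrame indexed by feature with ``mean_a``, ``mean_b``,
    ``fold_change``, ``p_value``, ``fdr_p`` and a ``constant`` flag for
    features flat in both groups (reported with p = 1).
    """
    groups = groups.reindex(data.index)
    mask_a = (groups == group_a).to_numpy()
    mask_b = (groups == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError(
            f"need >=2 samples per group; got {mask_a.sum()} {group_a}, "
            f"{mask_b.sum()} {group_b}"
        )
    x = data.to_numpy(dtype=float)
    pvals = np.empty(data.shape[1])
    constant = np.zeros(data.shape[1], dtype=bool)
    for j in range(data.shape[1]):
        a, b = x[mask_a, j], x[mask_b, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            raise ValidationError(
                f"feature {data.columns[j]!r} has no values in one group"
            )
        if np.ptp(np.concatenate([a, b])) == 0:
            constant[j] = True
            pvals[j] = 1.0
        else:
            pvals[j] = _rank_sum_p(a, b)
    if constant.any():
        warnings.warn(
            f"{constant.sum()} constant feature(s) reported with p = 1",
            stacklevel=2,
        )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    mean_a = np.nanmean(x[mask_a], axis=0)
    mean_b = np.nanmean(x[mask_b], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_a / mean_b
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "p_value": pvals,
            "fdr_p": fdr,
            "constant": constant,
        },
        index=pd.Index(data.columns, name="feature"),
    )
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out


def apply_fdr_threshold(results: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Features with ``fdr_p`` strictly below ``cutoff``.

    The workflow uses two levels: 0.2 for discovery screens and 0.05 for
    confirmatory comparisons.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ParameterError(f"FDR cutoff must be in (0, 1], got {cutoff}")
    if "fdr_p" not in results.columns:
        raise ValidationError("results lack an 'fdr_p' column")
    return results[results["fdr_p"] < cutoff]


def diversity(
    table: AbundanceTable, detection_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-sample richness and Shannon index (nats).

    Richness counts taxa with abundance strictly above the detection
    threshold; the Shannon index is computed on the composition re-closed
    over those detected taxa.  All-zero samples get richness 0 and Shannon 0.
    """
    x = table.data.to_numpy(dtype=float)
    detected = x > detection_threshold
    richness = detected.sum(axis=1)
    shannon = np.zeros(len(richness))
    for i in range(x.shape[0]):
        q = x[i, detected[i]]
        if q.size == 0 or q.sum() == 0:
            warnings.warn(
                f"sample {table.sample_ids[i]!r} has no detected taxa",
                stacklevel=2,
            )
            continue
        q = q / q.sum()
        shannon[i] = -np.sum(q * np.log(q))
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def anosim(
    table: AbundanceTable,
    groups: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Analysis of similarities on Bray-Curtis dissimilarities.

    R = (mean rank of between-group dissimilarities - mean rank of
    within-group dissimilarities) / (n(n-1)/4), the standard normalization
    that confines R to [-1, 1]; the permutation p-value is
    (1 + #{permuted R >= observed}) / (1 + B).
    """
    groups = groups.reindex(table.sample_ids)
    labels, counts = np.unique(groups.to_numpy(), return_counts=True)
    if len(labels) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        raise ValidationError("ANOSIM groups must each have >=2 samples")
    dm = pdist(table.data.to_numpy(dtype=float), metric="braycurtis")
    ranks = stats.rankdata(dm)
    n = table.n_samples
    m = n * (n - 1) / 2
    grp = groups.to_numpy()
    iu = np.triu_indices(n, k=1)
    within = grp[iu[0]] == grp[iu[1]]

    def _r(within_mask: np.ndarray) -> float:
        return (ranks[~within_mask].mean() - ranks[within_mask].mean()) / (m / 2)

    r_obs = _r(within)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(grp)
        w = perm[iu[0]] == perm[iu[1]]
        if _r(w) >= r_obs:
            count += 1
    return {
        "r_statistic": float(r_obs),
        "p_value": (1 + count) / (1 + n_permutations),
        "n_permutations": n_permutations,
    }


def taxon_ratio(
    table: AbundanceTable,
    numerator_taxon: str,
    denominator_taxon: str,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-sample abundance ratio of two taxa (e.g. Prevotella/Bacteroides).

    Zeros on either side are replaced by a pseudocount (default: half the
    smallest positive value of the table) before division; samples whose
    denominator was zero are flagged.
    """
    for t in (numerator_taxon, denominator_taxon):
        if t not in table.data.columns:
            raise ValidationError(f"taxon {t!r} not in table")
    num = table.data[numerator_taxon].to_numpy(dtype=float).copy()
    den = table.data[denominator_taxon].to_numpy(dtype=float).copy()
    if pseudocount is None:
        pos = table.data.to_numpy()[table.data.to_numpy() > 0]
        pseudocount = 0.5 * pos.min() if pos.size else 1e-6
    zero_den = den == 0
    num[num == 0] = pseudocount
    den[zero_den] = pseudocount
    return pd.DataFrame(
        {"ratio": num / den, "zero_denominator": zero_den},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
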