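"""Pathway activity scoring from annotated metabolite abundances.

A pathway's activity score for a sample is the sum of the sample's
mean-normalized abundances over the measured metabolites mapped to the
pathway, divided by the pathway's total compound count K_p.  Dividing by K_p
rather than by the number of measured metabolites penalizes poorly covered
pathways; unmeasured compounds contribute zero.  Per-metabolite mean
normalization puts metabolites with different instrument response on a common
scale before summing.  Scores are compared between groups with the same
rank-sum/BH machinery as any other feature table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from dualomics import diffstats
from dualomics.core_io import MetaboliteTable
from dualomics.errors import ValidationError


def normalize_metabolites(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each metabolite by its mean across samples (mean becomes 1).

    Metabolites with zero mean carry no signal and are dropped with a
    warning; an all-zero table is rejected.
    """
    means = table.data.mean(axis=0)
    keep = means > 0
    if not keep.any():
        raise ValidationError("all metabolites have zero mean")
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-zero metabolite(s)",
            stacklevel=2,
        )
    data = table.data.loc[:, keep].div(means[keep], axis=1)
    return MetaboliteTable(
        data,
        pathway_map={m: p for m, p in table.pathway_map.items() if keep.get(m, True)},
        pathway_sizes=dict(table.pathway_sizes),
    )


def pathway_activity(normalized: MetaboliteTable) -> pd.DataFrame:
    """Samples x pathways activity-score matrix AS(s, p) = sum(x~) / K_p.

    Only pathways with at least one measured metabolite appear.  The frame
    carries ``k_detected`` and ``K_total`` per pathway in ``attrs``.
    """
    measured = set(normalized.metabolite_ids)
    pathway_members: dict[str, list[str]] = {}
    for met, paths in normalized.pathway_map.items():
        if met not in measured:
            continue
        for p in paths:
            pathway_members.setdefault(p, []).append(met)
    if not pathway_members:
        raise ValidationError("no measured metabolite maps to any pathway")
    missing_sizes = sorted(
        p for p in pathway_members if p not in normalized.pathway_sizes
    )
    if missing_sizes:
        raise ValidationError(
            f"no total compound count (K_p) for pathway(s): {missing_sizes}"
        )
    scores = {}
    k_detected = {}
    for p, mets in sorted(pathway_members.items()):
        k_total = normalized.pathway_sizes[p]
        scores[p] = normalized.data[mets].sum(axis=1) / k_total
        k_detected[p] = len(mets)
    out = pd.DataFrame(scores)
    out.index.name = "sample_id"
    out.attrs["k_detected"] = k_detected
    out.attrs["K_total"] = {
        p: normalized.pathway_sizes[p] for p in pathway_members
    }
    return out


def compare_pathway_scores(
    scores: pd.DataFrame,
    groups: pd.Series,
    fdr_cutoff: float = 0.2,
    group_a: str = "GDM",
    group_b: str = "NGT",
) -> pd.DataFrame:
    """Rank-sum/BH comparison of pathway scores; flags FDR < ``fdr_cutoff``."""
    res = diffstats.wilcoxon_bh(scores, groups, group_a=group_a, group_b=group_b)
    res["significant"] = res["fdr_p"] < fdr_cutoff
    return res


def score_pathways(
    table: MetaboliteTable,
) -> pd.DataFrame:
    """Convenience: normalization followed by pathway activity scoring."""
    return pathway_activity(normalize_metabolites(table))
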