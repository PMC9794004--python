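"""Random-forest pathway-score regression and Shapley attribution of species.

A pathway's activity score is regressed on the relative abundances of the
top-abundance species with a standard random forest, and each species'
contribution to each sample's predicted score is quantified by a Monte-Carlo
permutation estimate of its Shapley value: the average marginal change in the
model prediction when the species' observed value enters, over random feature
orderings, with absent features filled in from a random background row.
Attributions are normalized post hoc so the efficiency identity

    sum_j phi_j(s) = f(x_s) - baseline

holds exactly, with the baseline the mean prediction over the background set.
Species-level attributions are then compared between groups with the usual
rank-sum/BH machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from dualomics import diffstats
from dualomics.errors import ParameterError, ValidationError


@dataclass
class ForestModel:
    """A fitted random-forest regressor plus its training context."""

    model: RandomForestRegressor
    feature_names: list[str]
    n_trees: int
    mtry: int
    seed: int
    oob_r2: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)


def fit_forest(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int = 500,
    mtry: int | None = None,
    min_leaf: int = 5,
    seed: int = 0,
) -> ForestModel:
    """Random-forest regression of a response on species abundances.

    Per-tree bootstrap of samples, greedy variance-reduction splits over
    ``mtry`` randomly chosen features (default floor(p/3)), leaves of at
    least ``min_leaf`` samples.  Out-of-bag R^2 is reported; the fit is
    deterministic given ``seed``.
    """
    if X.shape[0] < 10:
        raise ValidationError("need at least 10 samples to fit a forest")
    if X.isna().any().any():
        raise ValidationError("X contains missing values")
    yv = y.reindex(X.index).to_numpy(dtype=float)
    if np.ptp(yv) == 0:
        raise ValidationError("constant response")
    p = X.shape[1]
    if mtry is None:
        mtry = max(1, p // 3)
    if not 1 <= mtry <= p:
        raise ParameterError(f"mtry must be in [1, {p}], got {mtry}")
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_leaf,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X.to_numpy(dtype=float), yv)
    return ForestModel(
        model=rf,
        feature_names=list(X.columns),
        n_trees=n_trees,
        mtry=mtry,
        seed=seed,
        oob_r2=float(rf.oob_score_),
    )


def shapley_values(
    model: ForestModel,
    X: pd.DataFrame,
    background_X: pd.DataFrame | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo permutation Shapley values for every sample of ``X``.

    For each explained sample and each random feature ordering, one random
    background row supplies the values of not-yet-introduced features; the
    marginal prediction changes along the ordering estimate the per-feature
    contributions.  After averaging, the residual of the efficiency identity
    is spread uniformly over features so it holds exactly.  The per-sample
    baseline (mean prediction over the full background set) is stored in
    ``attrs["baseline"]``; predictions in ``attrs["prediction"]``.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    if background_X is None:
        raise ValidationError("a non-empty background set is required")
    bg = background_X[model.feature_names].to_numpy(dtype=float)
    if bg.shape[0] == 0:
        raise ValidationError("background set is empty")
    x = X[model.feature_names].to_numpy(dtype=float)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    baseline = float(model.predict(bg).mean())
    fx = model.predict(x)

    phi = np.zeros((n, p))
    for s in range(n):
        orderings = np.argsort(rng.random((n_permutations, p)), axis=1)
        bg_rows = bg[rng.integers(0, bg.shape[0], size=n_permutations)]
        # build the (P * (p+1)) prediction batch: row t of a permutation is
        # the background row with the first t ordered features set from x
        batch = np.repeat(bg_rows, p + 1, axis=0)
        for perm in range(n_permutations):
            base = perm * (p + 1)
            order = orderings[perm]
            for t in range(1, p + 1):
                rows = slice(base + t, base + p + 1)
                batch[rows, order[t - 1]] = x[s, order[t - 1]]
        preds = model.predict(batch).reshape(n_permutations, p + 1)
        contrib = np.diff(preds, axis=1)  # contribution of order[t] at step t
        for perm in range(n_permutations):
            phi[s, orderings[perm]] += contrib[perm]
        phi[s] /= n_permutations
        residual = (fx[s] - baseline) - phi[s].sum()
        phi[s] += residual / p
    out = pd.DataFrame(phi, index=X.index, columns=model.feature_names)
    out.attrs["baseline"] = baseline
    out.attrs["prediction"] = pd.Series(fx, index=X.index)
    return out


def compare_shapley_by_group(
    attributions: pd.DataFrame,
    groups: pd.Series,
    species_filter: list[str] | None = None,
    group_a: str = "GDM",
    group_b: str = "NGT",
) -> pd.DataFrame:
    """Rank-sum/BH comparison of per-sample Shapley values between groups.

    ``species_filter`` restricts the tested family, typically to the species
    already flagged as differentially abundant.
    """
    data = attributions
    if species_filter is not None:
        present = [s for s in species_filter if s in data.columns]
        if not present:
            raise ValidationError("no filtered species present in attributions")
        data = data[present]
    return diffstats.wilcoxon_bh(data, groups, group_a=group_a, group_b=group_b)
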