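"""Greedy log-ratio balance selection linking microbial signatures to outcomes.

A balance over disjoint taxon sets (N, D) assigns each sample the scalar
log-contrast

    B(s) = sqrt(k1*k2 / (k1+k2)) * (mean_{i in N} ln x_si - mean_{j in D} ln x_sj)

with k1 = |N|, k2 = |D|.  B is invariant to per-sample rescaling of the
composition, so it is a legitimate compositional signature.  The search is a
greedy forward algorithm in the style of the `selbal` method: start from the
best single numerator/denominator pair under the discrimination criterion
(rank-AUC of the balance against a binary response; R^2 of a linear fit for a
continuous response), then repeatedly add the taxon/side that most improves
the criterion.  Repeated (stratified) k-fold cross-validation re-runs the full
search per training fold, accumulating per-taxon selection frequencies and an
honest cross-validated criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from dualomics.core_io import AbundanceTable
from dualomics.errors import ParameterError, ValidationError

#: minimal criterion gain for the greedy search to accept another taxon
IMPROVEMENT_TOL = 1e-4
#: logistic-coefficient cap guarding against perfect separation
COEF_CAP = 30.0


@dataclass
class Balance:
    """A fitted balance: taxon sets plus association-model coefficients."""

    numerator: list[str]
    denominator: list[str]
    intercept: float = 0.0
    slope: float = 0.0
    criterion: float = np.nan


@dataclass
class BalanceCV:
    """Cross-validation summary of the balance search."""

    global_balance: Balance
    response_type: str
    criterion_name: str
    apparent_criterion: float
    cv_criterion: float
    cv_criterion_sd: float
    freq_numerator: pd.Series = field(default_factory=pd.Series)
    freq_denominator: pd.Series = field(default_factory=pd.Series)
    n_fits: int = 0
    cv_mse: float = np.nan

    @property
    def selection_frequency(self) -> pd.Series:
        return (self.freq_numerator + self.freq_denominator).sort_values(
            ascending=False
        )


# ---------------------------------------------------------------------------
# Zero handling and scoring
# ---------------------------------------------------------------------------


def replace_zeros(table: AbundanceTable, delta: float | None = None) -> AbundanceTable:
    """Replace zeros by ``delta`` (default: half the smallest positive value
    in the table) and re-close every sample, yielding a strictly positive
    composition fit for log-ratio analysis."""
    x = table.data.to_numpy(dtype=float).copy()
    if (x.sum(axis=1) == 0).any():
        raise ValidationError("all-zero sample cannot be made positive")
    if delta is None:
        delta = 0.5 * x[x > 0].min()
    x[x == 0] = delta
    x = table.closure * x / x.sum(axis=1, keepdims=True)
    return AbundanceTable(
        pd.DataFrame(x, index=table.data.index, columns=table.data.columns),
        closure=table.closure,
        rank=table.rank,
    )


def balance_score(
    table: AbundanceTable, numerator: list[str], denominator: list[str]
) -> pd.Series:
    """Per-sample balance score (natural log) for the given taxon sets."""
    num, den = list(numerator), list(denominator)
    if set(num) & set(den):
        raise ValidationError("numerator and denominator overlap")
    if not num or not den:
        raise ValidationError("both balance sides must be non-empty")
    missing = [t for t in num + den if t not in table.data.columns]
    if missing:
        raise ValidationError(f"taxa not in table: {missing}")
    vals = table.data[num + den].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValidationError("balance requires strictly positive abundances")
    logs = np.log(vals)
    k1, k2 = len(num), len(den)
    coef = np.sqrt(k1 * k2 / (k1 + k2))
    b = coef * (logs[:, :k1].mean(axis=1) - logs[:, k1:].mean(axis=1))
    return pd.Series(b, index=table.data.index, name="balance")


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula, ties counted half."""
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    r = stats.rankdata(scores)
    u1 = r[y].sum() - n1 * (n1 + 1) / 2
    return float(u1 / (n1 * n0))


def _criterion_matrix(scores: np.ndarray, y: np.ndarray, binary: bool) -> np.ndarray:
    """Criterion for each row of a (n_candidates x n_samples) score matrix.

    Binary: orientation-free rank-AUC max(a, 1-a); continuous: squared
    Pearson correlation with the response.
    """
    if binary:
        yb = np.asarray(y, dtype=bool)
        n1, n0 = int(yb.sum()), int((~yb).sum())
        r = np.apply_along_axis(stats.rankdata, 1, scores)
        u1 = r[:, yb].sum(axis=1) - n1 * (n1 + 1) / 2
        auc = u1 / (n1 * n0)
        return np.maximum(auc, 1.0 - auc)
    yc = y - y.mean()
    sc = scores - scores.mean(axis=1, keepdims=True)
    denom = np.sqrt((sc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ yc) / denom
    return np.nan_to_num(r) ** 2


def _fit_logistic(b: np.ndarray, y: np.ndarray, max_iter: int = 25) -> tuple[float, float]:
    """IRLS logistic fit of y on b; coefficients capped to avoid blow-up
    under perfect separation."""
    x = np.column_stack([np.ones_like(b), b])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-9, None)
        z = eta + (y - mu) / w
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            break
        beta_new = np.clip(beta_new, -COEF_CAP, COEF_CAP)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return float(beta[0]), float(beta[1])


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------


def _balance_from_indices(logs: np.ndarray, num: list[int], den: list[int]) -> np.ndarray:
    k1, k2 = len(num), len(den)
    coef = np.sqrt(k1 * k2 / (k1 + k2))
    return coef * (logs[:, num].mean(axis=1) - logs[:, den].mean(axis=1))


def _greedy_search(
    logs: np.ndarray,
    y: np.ndarray,
    names: list[str],
    binary: bool,
    max_size: int,
    tol: float = IMPROVEMENT_TOL,
) -> tuple[list[int], list[int], float]:
    """Forward selection of (numerator, denominator) index sets."""
    n, k = logs.shape
    order = np.argsort(names)  # lexicographic tie-break
    # all unordered pairs, lexicographically ordered for determinism
    ii, jj = np.triu_indices(k, k=1)
    pair_scores = (logs[:, ii] - logs[:, jj]).T * np.sqrt(0.5)
    crit = _criterion_matrix(pair_scores, y, binary)
    best = np.flatnonzero(crit >= crit.max() - 1e-12)
    # deterministic among exact ties: smallest (name_i, name_j)
    best_idx = min(
        best, key=lambda m: tuple(sorted((names[ii[m]], names[jj[m]])))
    )
    num, den = [int(ii[best_idx])], [int(jj[best_idx])]
    # orient so the balance associates positively with the response
    b = _balance_from_indices(logs, num, den)
    yy = np.asarray(y, dtype=float)
    if np.corrcoef(b, yy)[0, 1] < 0:
        num, den = den, num
    best_crit = float(crit[best_idx])

    while len(num) + len(den) < max_size:
        candidates = [t for t in order if t not in num and t not in den]
        if not candidates:
            break
        cand_scores = []
        cand_moves = []
        for t in candidates:
            cand_scores.append(_balance_from_indices(logs, num + [int(t)], den))
            cand_moves.append((int(t), "num"))
            cand_scores.append(_balance_from_indices(logs, num, den + [int(t)]))
            cand_moves.append((int(t), "den"))
        crit = _criterion_matrix(np.asarray(cand_scores), y, binary)
        m = np.flatnonzero(crit >= crit.max() - 1e-12)
        pick = min(m, key=lambda q: (names[cand_moves[q][0]], cand_moves[q][1]))
        if crit[pick] <= best_crit + tol:
            break
        t, side = cand_moves[pick]
        (num if side == "num" else den).append(t)
        best_crit = float(crit[pick])
    return num, den, best_crit


def _fit_global(
    logs: np.ndarray, y: np.ndarray, names: list[str], binary: bool, max_size: int
) -> Balance:
    num, den, crit = _greedy_search(logs, y, names, binary, max_size)
    b = _balance_from_indices(logs, num, den)
    if binary:
        intercept, slope = _fit_logistic(b, np.asarray(y, dtype=float))
    else:
        slope, intercept = np.polyfit(b, y, 1)
    return Balance(
        numerator=[names[i] for i in num],
        denominator=[names[i] for i in den],
        intercept=float(intercept),
        slope=float(slope),
        criterion=crit,
    )


def fit_balance(
    table: AbundanceTable,
    response: pd.Series,
    response_type: str = "binary",
    max_size: int = 8,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int = 0,
) -> BalanceCV:
    """Greedy balance search with repeated cross-validation.

    Parameters
    ----------
    response:
        Binary labels (any two values; the lexicographically larger one is
        the positive class unless boolean) or a continuous outcome, aligned
        on the sample index.
    response_type:
        "binary" (criterion: rank-AUC) or "continuous" (criterion: R^2).
    max_size:
        Maximum total number of taxa across both balance sides.
    cv_folds, cv_repeats:
        Repeated (stratified, for binary) k-fold CV; the full greedy search
        re-runs on every training fold.
    """
    if response_type not in ("binary", "continuous"):
        raise ParameterError(f"unknown response_type {response_type!r}")
    if max_size < 2:
        raise ParameterError("max_size must be at least 2")
    if cv_repeats < 1 or cv_folds < 2:
        raise ParameterError("need cv_repeats >= 1 and cv_folds >= 2")
    binary = response_type == "binary"
    response = response.reindex(table.sample_ids)
    if response.isna().any():
        raise ValidationError("response missing for some samples")
    vals = table.data.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValidationError(
            "table must be strictly positive; apply replace_zeros first"
        )
    logs = np.log(vals)
    names = list(table.taxon_ids)
    if binary:
        classes = sorted(set(response))
        if len(classes) != 2:
            raise ValidationError(f"binary response needs 2 classes, got {classes}")
        y = (response == classes[-1]).to_numpy().astype(float)
        if response.dtype == bool:
            y = response.to_numpy().astype(float)
    else:
        y = response.to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValidationError("continuous response has zero variance")

    global_balance = _fit_global(logs, y, names, binary, max_size)

    count_num = pd.Series(0.0, index=names)
    count_den = pd.Series(0.0, index=names)
    cv_vals = []
    cv_mse = []
    n_fits = 0
    for rep in range(cv_repeats):
        rs = np.random.default_rng((seed, rep)).integers(2**31 - 1)
        if binary:
            splitter = StratifiedKFold(
                n_splits=cv_folds, shuffle=True, random_state=int(rs)
            )
            splits = splitter.split(logs, y)
        else:
            splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=int(rs))
            splits = splitter.split(logs)
        fold_aucs = []
        pred = np.empty_like(y)
        for train, test in splits:
            num, den, _ = _greedy_search(
                logs[train], y[train], names, binary, max_size
            )
            n_fits += 1
            for i in num:
                count_num[names[i]] += 1
            for i in den:
                count_den[names[i]] += 1
            b_train = _balance_from_indices(logs[train], num, den)
            b_test = _balance_from_indices(logs[test], num, den)
            if binary:
                # AUC is evaluated within each fold: balances differ between
                # folds, so their raw scores are not comparable across folds
                _, slope = _fit_logistic(b_train, y[train])
                oriented = np.sign(slope if slope != 0 else 1.0) * b_test
                fold_aucs.append(rank_auc(oriented, y[test].astype(bool)))
            else:
                slope, intercept = np.polyfit(b_train, y[train], 1)
                pred[test] = intercept + slope * b_test
        if binary:
            cv_vals.append(float(np.mean(fold_aucs)))
        else:
            sse = float(((y - pred) ** 2).sum())
            sst = float(((y - y.mean()) ** 2).sum())
            cv_vals.append(1.0 - sse / sst)
            cv_mse.append(sse / len(y))

    return BalanceCV(
        global_balance=global_balance,
        response_type=response_type,
        criterion_name="auc" if binary else "r2",
        apparent_criterion=global_balance.criterion,
        cv_criterion=float(np.mean(cv_vals)),
        cv_criterion_sd=float(np.std(cv_vals)),
        freq_numerator=count_num / n_fits,
        freq_denominator=count_den / n_fits,
        n_fits=n_fits,
        cv_mse=float(np.mean(cv_mse)) if cv_mse else np.nan,
    )


def balance_report(cv: BalanceCV, top_n: int = 20) -> pd.DataFrame:
    """Ranked selection-frequency table with side annotation.

    The side of a taxon is the one it was selected into more often across CV
    fits; taxa never selected are omitted.  The global balance composition
    and criterion values ride along in ``attrs``.
    """
    if cv.n_fits == 0:
        raise ValidationError("balance CV was not run")
    freq = cv.selection_frequency
    freq = freq[freq > 0].head(top_n)
    side = [
        "numerator"
        if cv.freq_numerator[t] >= cv.freq_denominator[t]
        else "denominator"
        for t in freq.index
    ]
    out = pd.DataFrame(
        {"frequency": freq.values, "side": side},
        index=pd.Index(freq.index, name="taxon"),
    )
    out.attrs["global_numerator"] = cv.global_balance.numerator
    out.attrs["global_denominator"] = cv.global_balance.denominator
    out.attrs["apparent_" + cv.criterion_name] = cv.apparent_criterion
    out.attrs["cv_" + cv.criterion_name] = cv.cv_criterion
    return out
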