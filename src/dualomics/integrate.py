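"""Cross-omics association: sparse PLS and Spearman association heatmaps.

The sPLS here is the regression-mode variant with a per-component
retained-variable count (the ``keepX``/``keepY`` idiom): each component is the
dominant singular pair of the current X-Y cross-covariance, computed by
alternating power iteration with soft-thresholding of the loading vectors to
the requested number of largest-magnitude entries, followed by regression-mode
deflation of both blocks on the X-score.  The display surface for heatmaps is
the similarity matrix sim(i, j) = sum_h corr(X_i, t_h) * corr(Y_j, t_h) over
components h with X-scores t_h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dualomics.errors import ParameterError, ValidationError


@dataclass
class AssociationMatrix:
    """Rows x columns association surface with optional rank-test p-values."""

    values: pd.DataFrame
    p_value: pd.DataFrame | None = None
    fdr_p: pd.DataFrame | None = None


@dataclass
class SplsModel:
    n_components: int
    keep_x: int
    keep_y: int
    x_loadings: pd.DataFrame = field(default_factory=pd.DataFrame)  # p x H
    y_loadings: pd.DataFrame = field(default_factory=pd.DataFrame)  # q x H
    x_scores: np.ndarray | None = None  # n x H
    y_scores: np.ndarray | None = None
    _x0: np.ndarray | None = None  # standardized blocks kept for similarity
    _y0: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.x_scores is not None


def _standardize(x: np.ndarray, names, what: str) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        bad = [names[i] for i in np.flatnonzero(zero)]
        raise ValidationError(f"zero-variance {what} column(s): {bad}")
    return (x - mu) / sd


def _soft_keep(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold to the `keep` largest-magnitude entries, L2-renormalized."""
    if keep >= len(v):
        lam = 0.0
    else:
        lam = np.sort(np.abs(v))[::-1][keep]
    out = np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)
    norm = np.linalg.norm(out)
    if norm == 0:
        # fall back to the single largest entry
        out = np.zeros_like(v)
        j = int(np.argmax(np.abs(v)))
        out[j] = np.sign(v[j])
        norm = 1.0
    return out / norm


def spls_fit(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_components: int = 2,
    keep_x: int = 10,
    keep_y: int = 5,
    scale: bool = True,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> SplsModel:
    """Fit a regression-mode sparse PLS of Y on X.

    Blocks are column-centered and unit-variance scaled (``scale=True``).
    Per component, the loading pair is initialized from the SVD of the
    cross-covariance and refined by alternating multiplication with
    soft-thresholding; the sign is fixed so the largest-magnitude X-loading
    entry is positive, making the fit deterministic.
    """
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must have the same samples")
    n, p = X.shape
    q = Y.shape[1]
    if not 1 <= n_components <= min(p, q, n - 1):
        raise ParameterError(
            f"n_components must be in [1, min(p, q, n-1)] = "
            f"[1, {min(p, q, n - 1)}], got {n_components}"
        )
    keep_x = min(keep_x, p)
    keep_y = min(keep_y, q)
    x = X.to_numpy(dtype=float)
    y = Y.to_numpy(dtype=float)
    if scale:
        x = _standardize(x, list(X.columns), "X")
        y = _standardize(y, list(Y.columns), "Y")
    else:
        x = x - x.mean(axis=0)
        y = y - y.mean(axis=0)
    x0, y0 = x.copy(), y.copy()

    U = np.zeros((p, n_components))
    V = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    W = np.zeros((n, n_components))
    for h in range(n_components):
        m = x.T @ y
        uu, _, vvt = np.linalg.svd(m, full_matrices=False)
        u, v = uu[:, 0], vvt[0]
        for _ in range(max_iter):
            u_new = _soft_keep(m @ v, keep_x)
            v_new = _soft_keep(m.T @ u_new, keep_y)
            if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
                u, v = u_new, v_new
                break
            u, v = u_new, v_new
        j = int(np.argmax(np.abs(u)))
        if u[j] < 0:
            u, v = -u, -v
        t = x @ u
        w = y @ v
        denom = float(t @ t)
        if denom > 0:
            x = x - np.outer(t, (t @ x) / denom)
            y = y - np.outer(t, (t @ y) / denom)
        U[:, h], V[:, h], T[:, h], W[:, h] = u, v, t, w
    return SplsModel(
        n_components=n_components,
        keep_x=keep_x,
        keep_y=keep_y,
        x_loadings=pd.DataFrame(
            U, index=X.columns, columns=[f"comp{h + 1}" for h in range(n_components)]
        ),
        y_loadings=pd.DataFrame(
            V, index=Y.columns, columns=[f"comp{h + 1}" for h in range(n_components)]
        ),
        x_scores=T,
        y_scores=W,
        _x0=x0,
        _y0=y0,
    )


def spls_similarity(model: SplsModel) -> AssociationMatrix:
    """Variable-pair similarity surface of a fitted sPLS model.

    sim(i, j) = sum over components h of corr(X_i, t_h) * corr(Y_j, t_h),
    clipped to [-1, 1]; this is the heatmap shown for species-pathway and
    species-metabolite association displays.
    """
    if not model.fitted:
        raise ValidationError("sPLS model is not fitted")

    def _cors(block: np.ndarray) -> np.ndarray:
        out = np.zeros((block.shape[1], model.n_components))
        for h in range(model.n_components):
            t = model.x_scores[:, h]
            ts = t.std()
            if ts == 0:
                continue
            tc = (t - t.mean()) / ts
            bc = block - block.mean(axis=0)
            bs = block.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[:, h] = (bc.T @ tc) / (len(t) * np.where(bs == 0, np.nan, bs))
        return np.nan_to_num(out)

    cx = _cors(model._x0)
    cy = _cors(model._y0)
    sim = np.clip(cx @ cy.T, -1.0, 1.0)
    return AssociationMatrix(
        values=pd.DataFrame(
            sim, index=model.x_loadings.index, columns=model.y_loadings.index
        )
    )


def spearman_heatmap(A: pd.DataFrame, B: pd.DataFrame) -> AssociationMatrix:
    """All cross-pair Spearman correlations with BH over the full matrix.

    Missing values are handled pairwise-complete; pairs with fewer than 3
    complete observations get a missing rho (flagged by NaN).  Typically A is
    restricted beforehand to features that passed the differential screen.
    """
    if not A.index.equals(B.index):
        raise ValidationError("A and B must share an aligned sample index")
    a = A.to_numpy(dtype=float)
    b = B.to_numpy(dtype=float)
    pa, pb = a.shape[1], b.shape[1]
    rho = np.full((pa, pb), np.nan)
    pval = np.full((pa, pb), np.nan)
    if not (np.isnan(a).any() or np.isnan(b).any()):
        n = a.shape[0]
        ra = np.apply_along_axis(stats.rankdata, 0, a)
        rb = np.apply_along_axis(stats.rankdata, 0, b)
        za = ra - ra.mean(axis=0)
        zb = rb - rb.mean(axis=0)
        sa = np.sqrt((za**2).sum(axis=0))
        sb = np.sqrt((zb**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (za.T @ zb) / np.outer(sa, sb)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pval[np.isclose(np.abs(rho), 1.0)] = 0.0
    else:
        for i in range(pa):
            for j in range(pb):
                ok = ~(np.isnan(a[:, i]) | np.isnan(b[:, j]))
                if ok.sum() < 3:
                    continue
                r, p = stats.spearmanr(a[ok, i], b[ok, j])
                rho[i, j], pval[i, j] = r, p
    flat = pval.ravel()
    fdr = np.full_like(flat, np.nan)
    ok = ~np.isnan(flat)
    if ok.any():
        fdr[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    fdr = fdr.reshape(pval.shape)
    idx, cols = A.columns, B.columns
    return AssociationMatrix(
        values=pd.DataFrame(rho, index=idx, columns=cols),
        p_value=pd.DataFrame(pval, index=idx, columns=cols),
        fdr_p=pd.DataFrame(fdr, index=idx, columns=cols),
    )
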