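"""NIPALS principal components with missing values, used for imputation.

Nonlinear iterative partial least squares computes principal components one
at a time by alternating regressions of scores on loadings and loadings on
scores; because each update is a sum over *observed* entries only, the
algorithm tolerates missing cells.  Missing values are then replaced by the
low-rank reconstruction on the standardized scale and back-transformed;
observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NipalsConfig", "NipalsConvergenceError", "nipals_components", "nipals_impute"]


@dataclass(frozen=True)
class NipalsConfig:
    """Reconstruction rank and convergence control for NIPALS imputation."""

    n_factors: int = 2
    tol: float = 1e-9
    max_iter: int = 20000
    #: outer refit passes: column means/SDs are re-estimated from the
    #: completed matrix until the imputed cells stabilize
    max_refit: int = 100

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


class NipalsConvergenceError(RuntimeError):
    def __init__(self, component: int, delta: float, tol: float, max_iter: int):
        self.delta = delta
        super().__init__(
            f"NIPALS component {component} did not converge in {max_iter} "
            f"iterations (last score change {delta:.3e}, tol {tol:.1e})")


def nipals_components(X: np.ndarray, n_factors: int, tol: float = 1e-9,
                      max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Scores T (n x k) and loadings P (p x k) of centered data with NaNs.

    ``X`` is assumed column-centered (and typically scaled); missing entries
    are NaN and are simply skipped in every inner product.  Loadings are
    unit-norm; components come out in decreasing variance order as usual for
    NIPALS (dominant eigendirection first).
    """
    X = np.array(X, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if (obs.sum(axis=0) == 0).any():
        raise ValueError("all-missing column")
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("all-missing row")
    O = obs.astype(float)
    R = np.where(obs, X, 0.0)
    T = np.zeros((n, n_factors))
    P = np.zeros((p, n_factors))
    k = min(n_factors, n - 1 if n > 1 else 1, p)
    for h in range(k):
        # start from the column with the largest remaining variance
        j0 = int(np.argmax((R * R).sum(axis=0)))
        t = R[:, j0].copy()
        if not np.any(t):
            break
        sse_prev = np.inf
        sse_tot = float((R * R).sum())
        for it in range(max_iter):
            # loadings: per-column regression of residual on scores,
            # observed entries only (O carries the missingness pattern)
            denom = O.T @ (t * t)
            denom[denom == 0] = np.inf
            pvec = (R.T @ t) / denom
            nrm = np.linalg.norm(pvec)
            if nrm == 0:
                break
            pvec /= nrm
            # scores: per-row regression of residual on loadings
            denom_r = O @ (pvec * pvec)
            denom_r[denom_r == 0] = np.inf
            t_new = (R @ pvec) / denom_r
            delta = float(np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300))
            t = t_new
            if delta < tol:
                break
            # objective: residual SSQ of the rank-1 fit.  Under (near-)tied
            # eigenvalues the component direction wanders inside the tied
            # subspace while the fit itself is converged; the reconstruction
            # is all the imputation uses, so a stable objective is
            # convergence.
            fit = O * np.outer(t, pvec)
            sse = float(((R - fit) * (R - fit)).sum())
            if abs(sse_prev - sse) <= tol * max(sse_tot, 1e-300):
                break
            sse_prev = sse
        else:
            raise NipalsConvergenceError(h + 1, delta, tol, max_iter)
        T[:, h] = t
        P[:, h] = pvec
        R = R - O * np.outer(t, pvec)
    return T, P


def nipals_impute(matrix: pd.DataFrame | np.ndarray,
                  cfg: NipalsConfig = NipalsConfig()) -> pd.DataFrame | np.ndarray:
    """Fill missing cells with the rank-``n_factors`` NIPALS reconstruction.

    Columns are standardized, components fitted with the missing entries
    skipped, and only the missing cells are replaced by the reconstruction
    mapped back to the original scale.  Because standardization statistics
    themselves depend on the fill, the fill is iterated to its fixed point:
    means/SDs are re-estimated from the completed matrix and the components
    refitted until imputed cells stop moving.  At the fixed point an exactly
    rank-``n_factors`` matrix is recovered exactly.  A complete matrix is
    returned unchanged.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.array(matrix, dtype=float)
    obs = ~np.isnan(X)
    if obs.all():
        return matrix.copy() if is_df else X
    if (obs.sum(axis=0) == 0).any():
        bad = list(np.nonzero(obs.sum(axis=0) == 0)[0])
        raise ValueError(f"all-missing column(s) at positions {bad}")
    if (obs.sum(axis=1) == 0).any():
        bad = list(np.nonzero(obs.sum(axis=1) == 0)[0])
        raise ValueError(f"all-missing row(s) at positions {bad}")

    k = min(cfg.n_factors, X.shape[0] - 1, X.shape[1])
    miss = ~obs
    # initial fill: observed column means
    fill = np.broadcast_to(np.nanmean(X, axis=0), X.shape)[miss]
    scale_ref = np.nanstd(X, axis=0, ddof=1).max() or 1.0
    for _ in range(cfg.max_refit):
        Xc = X.copy()
        Xc[miss] = fill
        mu = Xc.mean(axis=0)
        sd = Xc.std(axis=0, ddof=1)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = np.where(obs, (X - mu) / sd_safe, np.nan)
        T, P = nipals_components(Z, k, tol=cfg.tol, max_iter=cfg.max_iter)
        Xhat = (T @ P.T) * sd_safe + mu
        new_fill = Xhat[miss]
        delta = float(np.max(np.abs(new_fill - fill)))
        fill = new_fill
        if delta < max(cfg.tol, 1e-12) * scale_ref:
            break
    out = np.where(obs, X, 0.0)
    out[miss] = fill
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out
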