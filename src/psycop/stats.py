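"""Factorial inference for the 2x2 treatment design.

Univariate two-way ANOVA with type-2 sums of squares, Wilks-lambda MANOVA
with Rao's F approximation, simple-effects (M)ANOVAs within a fixed level of
the second factor, and Benjamini-Hochberg FDR adjustment.

The type-2 decomposition is computed by nested model comparison on
sum-to-zero (effect) coded design matrices: each main effect is adjusted for
the other main effect, the interaction for both mains; the error SSP comes
from the full model.  The hypothesis/error SSP matrices are exposed because
the per-term canonical discriminant analysis is built directly on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TERMS",
    "AnovaResult",
    "ManovaResult",
    "encode_design",
    "factorial_ssp",
    "two_way_anova_type2",
    "manova_wilks",
    "wilks_to_F",
    "simple_effects",
    "simple_effects_manova",
    "fdr_adjust",
]

TERMS = ("S", "A", "SxA")


def encode_design(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero codes (+1 treated / -1 placebo) for the two factors.

    The design frame has two columns (factor S then factor A); any level
    named ``placebo`` (case-insensitive) codes -1, the other level +1.
    """
    if design.shape[1] < 2:
        raise ValueError("design needs two factor columns")

    def code(col: pd.Series) -> np.ndarray:
        levels = sorted(col.astype(str).unique())
        if len(levels) > 2:
            raise ValueError(f"factor {col.name!r} has more than two levels: {levels}")
        ref = next((l for l in levels if l.lower() in ("placebo", "plc", "control", "0")),
                   levels[0])
        return np.where(col.astype(str) == ref, -1.0, 1.0)

    return code(design.iloc[:, 0]), code(design.iloc[:, 1])


def _resid_ssp(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return R.T @ R


def factorial_ssp(Y: np.ndarray, xs: np.ndarray, xa: np.ndarray,
                  ) -> tuple[dict[str, np.ndarray], np.ndarray, int]:
    """Type-2 hypothesis SSP per term plus the shared error SSP.

    Returns ``(H, E, df_error)`` where ``H`` maps each of S, A, SxA to its
    p x p hypothesis matrix (each term has 1 hypothesis df in a 2x2 design)
    and ``E`` is the residual SSP of the full model.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    one = np.ones(n)
    m_s = np.column_stack([one, xs])
    m_a = np.column_stack([one, xa])
    m_sa = np.column_stack([one, xs, xa])
    m_full = np.column_stack([one, xs, xa, xs * xa])

    E = _resid_ssp(Y, m_full)
    H = {
        "S": _resid_ssp(Y, m_a) - _resid_ssp(Y, m_sa),
        "A": _resid_ssp(Y, m_s) - _resid_ssp(Y, m_sa),
        "SxA": _resid_ssp(Y, m_sa) - E,
    }
    # numerical guard: hypothesis SSPs are differences and must stay PSD
    for k, h in H.items():
        H[k] = (h + h.T) / 2.0
    return H, (E + E.T) / 2.0, n - 4


@dataclass
class AnovaResult:
    """Per-term univariate two-way ANOVA (type-2 SS)."""

    table: pd.DataFrame  # index: term; columns F, df1, df2, p (p_adj added later)
    n_used: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _drop_missing(y: np.ndarray, xs: np.ndarray, xa: np.ndarray):
    ok = ~np.isnan(y) if y.ndim == 1 else ~np.isnan(y).any(axis=1)
    return y[ok], xs[ok], xa[ok]


def _check_cells(xs: np.ndarray, xa: np.ndarray) -> None:
    for s in (-1.0, 1.0):
        for a in (-1.0, 1.0):
            if not np.any((xs == s) & (xa == a)):
                raise ValueError(f"empty design cell (S={s:+.0f}, A={a:+.0f}) after "
                                 "removing missing values")


def two_way_anova_type2(y, design: pd.DataFrame) -> AnovaResult:
    """Type-2 two-way ANOVA of one variable against the 2x2 design.

    Mice with a missing value are dropped for this variable only (listwise
    per variable).  Raises if any design cell empties out or the residual
    variance is zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    xs, xa = encode_design(design)
    y, xs, xa = _drop_missing(y, xs, xa)
    _check_cells(xs, xa)
    H, E, df_e = factorial_ssp(y, xs, xa)
    sse = float(E[0, 0])
    tot = float(np.sum((y - y.mean()) ** 2))
    if df_e <= 0 or sse <= 1e-12 * max(tot, 1.0):
        raise ValueError("zero residual variance; F undefined")
    rows = {}
    for term in TERMS:
        ssh = float(H[term][0, 0])
        F = (ssh / 1.0) / (sse / df_e)
        rows[term] = {"F": F, "df1": 1, "df2": df_e,
                      "p": float(sps.f.sf(F, 1, df_e))}
    return AnovaResult(pd.DataFrame(rows).T[["F", "df1", "df2", "p"]], n_used=len(y))


def wilks_to_F(lmbda: float, p: int, q: int, v: int) -> tuple[float, float, float]:
    """Rao's F approximation of Wilks lambda.

    ``p`` responses, ``q`` hypothesis df, ``v`` error df.  Returns
    ``(F, df1, df2)``; exact for q <= 2 or p <= 2.
    """
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        t = 1.0
    u = (p * q - 2.0) / 4.0
    r = v - (p - q + 1.0) / 2.0
    df1 = p * q
    df2 = r * t - 2.0 * u
    lam_t = lmbda ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return float(F), float(df1), float(df2)


@dataclass
class ManovaResult:
    """Wilks-lambda MANOVA of one model term."""

    term: str
    wilks: float
    F: float
    df1: float
    df2: float
    p: float
    H: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    df_hyp: int = 1
    df_error: int = 0


def manova_wilks(Y: pd.DataFrame | np.ndarray, design: pd.DataFrame,
                 ) -> dict[str, ManovaResult]:
    """Two-way Wilks-lambda MANOVA, one result per term (S, A, SxA).

    Requires a complete (imputed) matrix with ``n > p + 4`` so the error SSP
    is invertible.
    """
    Y = np.asarray(Y, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("MANOVA requires a complete matrix; impute first")
    n, p = Y.shape
    xs, xa = encode_design(design)
    _check_cells(xs, xa)
    H, E, df_e = factorial_ssp(Y, xs, xa)
    if n <= p + 4:
        raise ValueError(f"n={n} too small for p={p} responses in a 4-cell design")
    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0:
        raise ValueError("singular error SSP; reduce the variable set")
    out = {}
    for term in TERMS:
        sign_he, logdet_HE = np.linalg.slogdet(H[term] + E)
        lam = float(np.exp(logdet_E - logdet_HE))
        lam = min(lam, 1.0)
        F, df1, df2 = wilks_to_F(lam, p, 1, df_e)
        out[term] = ManovaResult(term=term, wilks=lam, F=F, df1=df1, df2=df2,
                                 p=float(sps.f.sf(F, df1, df2)),
                                 H=H[term], E=E, df_hyp=1, df_error=df_e)
    return out


def simple_effects(y, design: pd.DataFrame, within_factor: str = "A",
                   ) -> pd.DataFrame:
    """One-way ANOVA of factor S within each level of factor A.

    Reported when the interaction is significant; labels follow the
    convention ``P-S`` (S effect in placebo-A mice) and ``A-S`` (S effect in
    treated-A mice).  Univariate, listwise missing removal within the level.
    """
    y = np.asarray(y, dtype=float).ravel()
    xs, xa = encode_design(design)
    if within_factor not in ("A", "S"):
        raise ValueError("within_factor must be 'A' or 'S'")
    x_fix, x_test = (xa, xs) if within_factor == "A" else (xs, xa)
    rows = {}
    for level, label in ((-1.0, f"P-{'S' if within_factor == 'A' else 'A'}"),
                         (1.0, f"{'A' if within_factor == 'A' else 'S'}-"
                               f"{'S' if within_factor == 'A' else 'A'}")):
        m = x_fix == level
        yy, tt = y[m], x_test[m]
        ok = ~np.isnan(yy)
        yy, tt = yy[ok], tt[ok]
        if len(np.unique(tt)) < 2:
            raise ValueError(f"only one level of the tested factor within level {level:+.0f}")
        n = len(yy)
        one = np.ones(n)
        sse = float(_resid_ssp(yy[:, None], np.column_stack([one, tt]))[0, 0])
        ss0 = float(_resid_ssp(yy[:, None], one[:, None])[0, 0])
        df_e = n - 2
        if df_e <= 0 or sse <= 1e-12 * max(ss0, 1.0):
            raise ValueError("zero residual variance in simple-effects subset")
        F = (ss0 - sse) / (sse / df_e)
        rows[label] = {"F": F, "df1": 1, "df2": df_e,
                       "p": float(sps.f.sf(F, 1, df_e)), "n": n}
    return pd.DataFrame(rows).T[["F", "df1", "df2", "p", "n"]]


def simple_effects_manova(Y, design: pd.DataFrame, within_factor: str = "A",
                          ) -> dict[str, ManovaResult]:
    """One-way Wilks MANOVA of S within each level of A (multivariate analog)."""
    Y = np.asarray(Y, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("MANOVA requires a complete matrix; impute first")
    xs, xa = encode_design(design)
    x_fix, x_test = (xa, xs) if within_factor == "A" else (xs, xa)
    p = Y.shape[1]
    out = {}
    for level, label in ((-1.0, "P-S"), (1.0, "A-S")):
        m = x_fix == level
        YY, tt = Y[m], x_test[m]
        n = YY.shape[0]
        one = np.ones(n)
        E = _resid_ssp(YY, np.column_stack([one, tt]))
        T = _resid_ssp(YY, one[:, None])
        H = T - E
        df_e = n - 2
        sign, logdet_E = np.linalg.slogdet(E)
        if sign <= 0 or n <= p + 2:
            raise ValueError(f"singular error SSP in simple-effects level {label}")
        _, logdet_HE = np.linalg.slogdet(H + E)
        lam = min(float(np.exp(logdet_E - logdet_HE)), 1.0)
        F, df1, df2 = wilks_to_F(lam, p, 1, df_e)
        out[label] = ManovaResult(term=label, wilks=lam, F=F, df1=df1, df2=df2,
                                  p=float(sps.f.sf(F, df1, df2)),
                                  H=(H + H.T) / 2, E=(E + E.T) / 2,
                                  df_hyp=1, df_error=df_e)
    return out


def fdr_adjust(pvals, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(p_adjusted, significant)`` where significance is declared at
    adjusted p <= q.  NaN entries pass through as NaN / not significant.
    """
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    sig = np.zeros_like(p, dtype=bool)
    if ok.any():
        rej, p_adj, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok] = p_adj
        sig[ok] = adj[ok] <= q
    return adj, sig
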