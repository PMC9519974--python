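"""Canonical discriminant analysis of the behavioral profile.

CDA finds linear combinations of the variables that maximize between-group
relative to within-group scatter — the generalized eigenproblem
``H v = lambda E v`` with hypothesis scatter H and error scatter E.  Two
flavors are provided: the collapsed 4-group analysis (H = between-group
scatter) and the per-term analysis of the bifactorial model, where each
term's type-2 hypothesis SSP is tested against the shared error SSP, plus
simple-effect CDAs within each level of the second factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .stats import encode_design, factorial_ssp

__all__ = ["CdaResult", "Ellipse", "cda_groups", "cda_terms", "data_ellipse"]


@dataclass(frozen=True)
class Ellipse:
    """Gaussian concentration data ellipse (center, semi-axes, angle in rad)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    coverage: float


@dataclass
class CdaResult:
    """Eigen-structure, coefficients and scores of one discriminant analysis."""

    eigenvalues: np.ndarray
    percents: np.ndarray              # 100*lambda_i / sum(lambda) over retained
    canonical_correlations: np.ndarray
    raw_coef: pd.DataFrame            # variables x components
    std_coef: pd.DataFrame            # raw scaled by pooled within-group SD
    scores: pd.DataFrame              # mice x components, centered data @ raw_coef
    group_means: pd.DataFrame         # groups x components
    ellipses: dict[str, Ellipse] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _component_frame(values: np.ndarray, index, k: int, prefix="Can") -> pd.DataFrame:
    return pd.DataFrame(values, index=index, columns=[f"{prefix}{i+1}" for i in range(k)])


def _solve(H: np.ndarray, E: np.ndarray, k: int, df_within: int,
           X: pd.DataFrame, groups: pd.Series, coverage: float | None = 0.75,
           ) -> CdaResult:
    """Shared eigen machinery for all CDA flavors.

    ``k`` components are retained; raw coefficients are normalized so that
    the within-group (error) covariance of the scores is the identity, and
    the sign is fixed so the largest-|coefficient| variable of each
    component is positive.
    """
    p = H.shape[0]
    try:
        w, V = linalg.eigh(H, E)
    except linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular within-group scatter; reduce variables") from exc
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # eigh(H, E) returns v with v' E v = 1; rescale to unit within-covariance
    V = V * np.sqrt(df_within)
    # deterministic sign: largest-magnitude coefficient positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]

    tot = lam.sum()
    percents = 100.0 * lam / tot if tot > 0 else np.zeros_like(lam)
    canr = np.sqrt(lam / (1.0 + lam))

    Xc = X - X.mean(axis=0)
    scores = Xc.to_numpy() @ V
    raw = _component_frame(V, X.columns, k)
    within_sd = np.sqrt(np.diag(E) / df_within)
    std = raw.mul(within_sd, axis=0)
    sc = _component_frame(scores, X.index, k)
    gm = sc.groupby(groups.loc[X.index].to_numpy()).mean()
    gm.index.name = "group"

    ellipses: dict[str, Ellipse] = {}
    if coverage is not None and k >= 2:
        for g, sub in sc.groupby(groups.loc[X.index].to_numpy()):
            if len(sub) >= 3:
                ellipses[str(g)] = data_ellipse(sub.iloc[:, :2].to_numpy(), coverage)
    return CdaResult(eigenvalues=lam, percents=percents,
                     canonical_correlations=canr, raw_coef=raw, std_coef=std,
                     scores=sc, group_means=gm, ellipses=ellipses)


def cda_groups(X: pd.DataFrame, groups: pd.Series, coverage: float = 0.75) -> CdaResult:
    """Canonical discriminant analysis of g group labels (collapsed design).

    Between-group scatter against pooled within-group scatter; retains
    ``min(g - 1, p)`` components.  Requires a complete matrix with more mice
    than variables plus groups.
    """
    X = X.astype(float)
    if X.isna().any().any():
        raise ValueError("CDA requires a complete matrix; impute first")
    g = groups.loc[X.index]
    labels = g.unique()
    n, p = X.shape
    ng = len(labels)
    if ng < 2:
        raise ValueError("need at least two groups")
    if n <= p + ng:
        raise ValueError(f"n={n} too small for p={p} variables and {ng} groups")
    grand = X.mean(axis=0).to_numpy()
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in labels:
        sub = X[g == lab].to_numpy()
        m = sub.mean(axis=0)
        d = sub - m
        W += d.T @ d
        B += len(sub) * np.outer(m - grand, m - grand)
    k = min(ng - 1, p)
    return _solve(B, W, k, n - ng, X, g, coverage)


def cda_terms(X: pd.DataFrame, design: pd.DataFrame, coverage: float = 0.75,
              ) -> dict[str, CdaResult]:
    """Per-term CDA of the bifactorial model plus simple-effect CDAs.

    For each term (S, A, SxA) the generalized eigenproblem of the term's
    type-2 hypothesis SSP against the shared full-model error SSP is solved
    (one component each, the hypothesis df of a 2x2 term).  ``P-S`` and
    ``A-S`` are the spironolactone-effect CDAs within the placebo- and
    treated-aripiprazole subsets.
    """
    X = X.astype(float)
    if X.isna().any().any():
        raise ValueError("CDA requires a complete matrix; impute first")
    d = design.loc[X.index]
    xs, xa = encode_design(d)
    n, p = X.shape
    if n <= p + 4:
        raise ValueError(f"n={n} too small for p={p} variables in a 4-cell design")
    H, E, df_e = factorial_ssp(X.to_numpy(), xs, xa)
    cell = pd.Series(
        [f"{s}/{a}" for s, a in zip(d.iloc[:, 0].astype(str), d.iloc[:, 1].astype(str))],
        index=X.index)
    out: dict[str, CdaResult] = {}
    for term in ("S", "A", "SxA"):
        out[term] = _solve(H[term], E, 1, df_e, X, cell, coverage=None)

    for level, label in ((-1.0, "P-S"), (1.0, "A-S")):
        m = xa == level
        sub = X.iloc[m]
        slab = pd.Series(d.iloc[m, 0].astype(str).to_numpy(), index=sub.index)
        if sub.shape[0] > p + 2 and slab.nunique() == 2:
            out[label] = cda_groups(sub, slab, coverage)
    return out


def data_ellipse(scores: np.ndarray, coverage: float = 0.75) -> Ellipse:
    """Gaussian concentration ellipse covering ``coverage`` of a 2-D cloud.

    Center = mean, axes = sqrt(eigenvalues of the covariance times the
    chi-square(2) quantile of the coverage), angle = orientation of the
    leading eigenvector.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    w, v = np.linalg.eigh(cov)
    if np.any(w <= 0):
        raise ValueError("degenerate covariance; ellipse undefined")
    q = sps.chi2.ppf(coverage, df=2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    angle = float(np.arctan2(v[1, 0], v[0, 0]))
    return Ellipse(center=(float(center[0]), float(center[1])),
                   semi_axes=(float(np.sqrt(w[0] * q)), float(np.sqrt(w[1] * q))),
                   angle=angle, coverage=coverage)
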