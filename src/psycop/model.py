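"""Model/results interface tying the whole profiling pipeline together.

:class:`BehavioralProfile` is constructed from a mice x variables matrix and
the 2x2 factorial design (or directly from a :class:`~psycop.simulate.Cohort`
via :meth:`BehavioralProfile.from_cohort`, which scores the raw event
streams first).  ``fit()`` runs the full analysis — per-variable type-2
two-way ANOVAs with BH-FDR adjustment, NIPALS imputation of the matrix,
Wilks-lambda MANOVA per term with gated simple effects, the collapsed
4-group canonical discriminant analysis and the per-term CDAs, the
placebo-centered Z-score profile and its Manhattan-distance clustering —
and returns a :class:`ProfileResults` with a ``summary()`` table and
plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats as fstats
from .cda import CdaResult, cda_groups, cda_terms
from .nipals import NipalsConfig, nipals_impute
from .scoring import DEFAULT_RDOC_MAP, SprtConfig, zscore_profile
from .report import ClusterResult, cluster_groups, significance_stars

__all__ = ["BehavioralProfile", "ProfileResults"]


class BehavioralProfile:
    """Factorial behavioral-profile model for a mice x variables matrix.

    Parameters
    ----------
    variables : DataFrame
        One row per mouse, one column per behavioral variable; NaN marks a
        missing measurement.
    design : DataFrame
        Two columns (factor S, factor A) indexed like ``variables``; each
        factor has a placebo level and a treatment level.
    rdoc_map : mapping, optional
        Variable -> RDoC domain; defaults to the built-in battery map.
        Every variable must be mapped.
    reference_cell : tuple
        The design cell the Z-profile is centered on (the double placebo).
    """

    def __init__(self, variables: pd.DataFrame, design: pd.DataFrame,
                 rdoc_map: Mapping[str, str] | None = None,
                 reference_cell: tuple[str, str] = ("placebo", "placebo")):
        if not variables.index.isin(design.index).all():
            extra = [t for t in variables.index if t not in design.index]
            raise ValueError(f"mice missing from design: {extra[:10]}")
        self.variables = variables.astype(float)
        self.design = design.loc[variables.index]
        self.rdoc_map = dict(DEFAULT_RDOC_MAP if rdoc_map is None else rdoc_map)
        unmapped = [v for v in variables.columns if v not in self.rdoc_map]
        if unmapped:
            raise ValueError(f"variables without an RDoC domain: {unmapped}")
        self.reference_cell = reference_cell

    @classmethod
    def from_cohort(cls, cohort, sprt: SprtConfig = SprtConfig(),
                    rdoc_map: Mapping[str, str] | None = None,
                    ) -> "BehavioralProfile":
        """Score a raw cohort (event streams, trials, startle) and build the model."""
        matrix, _ = cohort.variable_matrix(sprt=sprt, rdoc_map=rdoc_map)
        return cls(matrix, cohort.design, rdoc_map=rdoc_map)

    def fit(self, nipals: NipalsConfig = NipalsConfig(), fdr_q: float = 0.1,
            simple_effects_gate: bool = True) -> "ProfileResults":
        """Run the full factorial profiling analysis.

        Univariate tests use per-variable listwise removal of missing mice;
        multivariate tests and the CDAs run on the NIPALS-completed matrix.
        Simple effects (S within each A level) are computed for variables /
        the multivariate model whose interaction survives FDR at ``fdr_q``
        (always computed when ``simple_effects_gate`` is False).
        """
        X, d = self.variables, self.design

        rows = []
        for var in X.columns:
            res = fstats.two_way_anova_type2(X[var].to_numpy(), d)
            for term in fstats.TERMS:
                r = res.table.loc[term]
                rows.append({"variable": var, "term": term, "F": r["F"],
                             "df1": int(r["df1"]), "df2": int(r["df2"]),
                             "p": r["p"], "n_used": res.n_used})
        anova = pd.DataFrame(rows)
        # FDR family: all variables within each term
        anova["p_adj"] = np.nan
        anova["significant"] = False
        for term in fstats.TERMS:
            m = anova["term"] == term
            adj, sig = fstats.fdr_adjust(anova.loc[m, "p"].to_numpy(), q=fdr_q)
            anova.loc[m, "p_adj"] = adj
            anova.loc[m, "significant"] = sig
        anova["stars"] = [significance_stars(p) for p in anova["p_adj"]]

        imputed = nipals_impute(X, nipals)
        manova = fstats.manova_wilks(imputed.to_numpy(), d)
        mp = np.array([manova[t].p for t in fstats.TERMS])
        m_adj, m_sig = fstats.fdr_adjust(mp, q=fdr_q)
        manova_table = pd.DataFrame({
            "term": list(fstats.TERMS),
            "wilks": [manova[t].wilks for t in fstats.TERMS],
            "F": [manova[t].F for t in fstats.TERMS],
            "df1": [manova[t].df1 for t in fstats.TERMS],
            "df2": [manova[t].df2 for t in fstats.TERMS],
            "p": mp, "p_adj": m_adj, "significant": m_sig,
        }).set_index("term")

        se_rows = []
        for var in X.columns:
            inter = anova[(anova["variable"] == var) & (anova["term"] == "SxA")]
            if not simple_effects_gate or bool(inter["significant"].iloc[0]):
                try:
                    se = fstats.simple_effects(X[var].to_numpy(), d, "A")
                except ValueError:
                    continue
                for label, r in se.iterrows():
                    se_rows.append({"variable": var, "contrast": label, "F": r["F"],
                                    "df1": int(r["df1"]), "df2": int(r["df2"]),
                                    "p": r["p"], "n": int(r["n"])})
        simple = pd.DataFrame(se_rows,
                              columns=["variable", "contrast", "F", "df1", "df2", "p", "n"])

        manova_simple = {}
        if not simple_effects_gate or bool(manova_table.at["SxA", "significant"]):
            manova_simple = fstats.simple_effects_manova(imputed.to_numpy(), d, "A")

        groups = pd.Series(
            d.iloc[:, 0].astype(str) + "/" + d.iloc[:, 1].astype(str),
            index=d.index, name="group")
        cda = cda_groups(imputed, groups)
        per_term = cda_terms(imputed, d)

        zprof = zscore_profile(X, d, self.reference_cell)
        # RDoC-blocked column order for display
        order = sorted(zprof.columns,
                       key=lambda v: (list(dict.fromkeys(self.rdoc_map.values()))
                                      .index(self.rdoc_map[v]), v))
        zprof = zprof[order]
        cluster = cluster_groups(zprof)

        return ProfileResults(
            model=self, anova=anova, manova=manova_table, manova_terms=manova,
            manova_simple=manova_simple, simple_effects=simple, imputed=imputed,
            cda=cda, cda_per_term=per_term, zprofile=zprof, cluster=cluster,
            fdr_q=fdr_q)


@dataclass
class ProfileResults:
    """Fitted behavioral profile: statistics tables, CDA structure, Z-profiles."""

    model: BehavioralProfile
    anova: pd.DataFrame
    manova: pd.DataFrame
    manova_terms: dict
    manova_simple: dict
    simple_effects: pd.DataFrame
    imputed: pd.DataFrame
    cda: CdaResult
    cda_per_term: dict[str, CdaResult]
    zprofile: pd.DataFrame
    cluster: ClusterResult
    fdr_q: float = 0.1

    def summary(self) -> str:
        """Human-readable report of the multivariate and per-variable tests."""
        lines = []
        n, p = self.model.variables.shape
        lines.append("Behavioral profile: two-way factorial analysis")
        lines.append(f"  mice: {n}   variables: {p}   FDR level: {self.fdr_q}")
        lines.append("")
        lines.append("Wilks-lambda MANOVA (NIPALS-imputed matrix)")
        for term, r in self.manova.iterrows():
            lines.append(
                f"  {term:>4}: lambda={r['wilks']:.4f}  "
                f"F({r['df1']:.0f}, {r['df2']:.0f}) = {r['F']:.2f}  "
                f"p={r['p']:.3g}  p_adj={r['p_adj']:.3g} "
                f"{significance_stars(r['p_adj'])}")
        for label, r in self.manova_simple.items():
            lines.append(
                f"  {label:>4}: lambda={r.wilks:.4f}  "
                f"F({r.df1:.0f}, {r.df2:.0f}) = {r.F:.2f}  p={r.p:.3g}")
        lines.append("")
        k = self.cda.n_components
        pct = ", ".join(f"Can{i+1} {self.cda.percents[i]:.1f}%" for i in range(k))
        lines.append(f"Canonical discriminant analysis (4 groups): {pct}")
        lines.append("")
        lines.append("Univariate two-way ANOVAs (type-2 SS), FDR-adjusted")
        hdr = f"  {'variable':<9}{'term':<6}{'F':>9}{'df':>10}{'p_adj':>11}  sig"
        lines.append(hdr)
        for _, r in self.anova.iterrows():
            lines.append(
                f"  {r['variable']:<9}{r['term']:<6}{r['F']:>9.2f}"
                f"{f'({r.df1},{r.df2})':>10}{r['p_adj']:>11.3g}  {r['stars']}")
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_dimension(self, ax=None):
        """Dimension plot of the first two canonical components with 75% ellipses."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        sc = self.cda.scores
        groups = pd.Series(
            self.model.design.iloc[:, 0].astype(str) + "/"
            + self.model.design.iloc[:, 1].astype(str), index=self.model.design.index)
        for g, sub in sc.groupby(groups.loc[sc.index].to_numpy()):
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=12, label=str(g))
            ell = self.cda.ellipses.get(str(g))
            if ell is not None:
                ax.add_patch(MplEllipse(ell.center, 2 * ell.semi_axes[0],
                                        2 * ell.semi_axes[1],
                                        angle=np.degrees(ell.angle),
                                        fill=False, lw=1.2))
        ax.set_xlabel(f"Can1 ({self.cda.percents[0]:.1f}%)")
        if self.cda.n_components > 1:
            ax.set_ylabel(f"Can2 ({self.cda.percents[1]:.1f}%)")
        ax.legend(fontsize=8)
        return ax

    def plot_heatmap(self, ax=None):
        """Placebo-centered group-mean Z-score heatmap, RDoC-blocked columns."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        z = self.zprofile.iloc[self.cluster.leaf_order]
        vmax = np.nanmax(np.abs(z.to_numpy())) or 1.0
        im = ax.imshow(z.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       aspect="auto")
        ax.set_xticks(range(z.shape[1]), z.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(z.shape[0]), z.index, fontsize=8)
        ax.figure.colorbar(im, ax=ax, label="group mean Z (vs placebo)")
        return ax

    def to_report(self) -> dict:
        from .report import build_report
        return build_report(self)
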