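"""Profile report assembly: clustering, significance stars, serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ClusterResult", "cluster_groups", "significance_stars",
           "build_report", "save_report", "validate_report"]

_SCHEMA_PATH = Path(__file__).resolve().parents[2] / "docs" / "report.schema.json"


def significance_stars(p_adj: float) -> str:
    """Star code at the conventional 0.05 / 0.01 / 0.001 thresholds."""
    if p_adj is None or np.isnan(p_adj):
        return ""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "n.s."


@dataclass
class ClusterResult:
    """Hierarchical clustering of group Z-profiles."""

    linkage: np.ndarray
    leaf_order: list[int]
    labels: list[str]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def cluster_groups(z_matrix: pd.DataFrame, method: str = "complete") -> ClusterResult:
    """Agglomerative clustering of group profiles on Manhattan (L1) distance.

    Complete linkage by default (the usual heatmap-package default); leaf
    order is scipy's deterministic dendrogram order.  Any missing value in
    the profile matrix is an error.
    """
    if z_matrix.shape[0] < 2:
        raise ValueError("need at least two group profiles to cluster")
    X = z_matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("Z-profile matrix contains missing values")
    D = pdist(X, metric="cityblock")
    Z = hierarchy.linkage(D, method=method)
    order = list(hierarchy.leaves_list(Z))
    return ClusterResult(linkage=Z, leaf_order=order,
                         labels=[str(i) for i in z_matrix.index])


def _round(x, nd=10):
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return None
        return float(round(float(x), nd))
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


def _frame_records(df: pd.DataFrame) -> list[dict]:
    return [{k: _round(v) for k, v in rec.items()}
            for rec in df.reset_index().to_dict(orient="records")]


def build_report(results) -> dict:
    """Assemble the machine-readable profile report from fitted results.

    Contains the placebo-centered Z matrix in RDoC-blocked column order, the
    group dendrogram, the CDA dimension-plot data (scores, 75% ellipses,
    coefficient vectors) and the statistics tables with significance stars.
    The same inputs always serialize to identical bytes.
    """
    r = results
    mice_stats = set(r.model.variables.index)
    mice_cda = set(r.cda.scores.index)
    if mice_stats != mice_cda:
        raise ValueError(f"mouse-set mismatch between inputs: "
                         f"{sorted(mice_stats ^ mice_cda)[:10]}")
    cda = {
        "eigenvalues": [_round(v) for v in r.cda.eigenvalues],
        "percents": [_round(v) for v in r.cda.percents],
        "canonical_correlations": [_round(v) for v in r.cda.canonical_correlations],
        "raw_coefficients": _frame_records(r.cda.raw_coef),
        "std_coefficients": _frame_records(r.cda.std_coef),
        "scores": _frame_records(r.cda.scores),
        "group_means": _frame_records(r.cda.group_means),
        "ellipses": {g: {"center": [_round(c) for c in e.center],
                         "semi_axes": [_round(a) for a in e.semi_axes],
                         "angle": _round(e.angle), "coverage": e.coverage}
                     for g, e in r.cda.ellipses.items()},
    }
    per_term = {
        term: {
            "eigenvalues": [_round(v) for v in res.eigenvalues],
            "std_coefficients": _frame_records(res.std_coef),
        } for term, res in r.cda_per_term.items()
    }
    report = {
        "fdr_q": r.fdr_q,
        "rdoc_map": dict(sorted(r.model.rdoc_map.items())),
        "zprofile": {
            "columns": list(r.zprofile.columns),
            "rows": list(map(str, r.zprofile.index)),
            "values": [[_round(v) for v in row] for row in r.zprofile.to_numpy()],
        },
        "clustering": {
            "linkage": [[_round(v) for v in row] for row in r.cluster.linkage],
            "leaf_order": list(map(int, r.cluster.leaf_order)),
            "labels": r.cluster.labels,
        },
        "anova": _frame_records(r.anova),
        "manova": _frame_records(r.manova),
        "manova_simple": {
            label: {"wilks": _round(m.wilks), "F": _round(m.F),
                    "df1": _round(m.df1), "df2": _round(m.df2), "p": _round(m.p)}
            for label, m in r.manova_simple.items()},
        "simple_effects": _frame_records(r.simple_effects),
        "cda": cda,
        "cda_per_term": per_term,
    }
    return report


def _check(node, schema, path="$"):
    """Minimal structural validator for the subset of JSON Schema the
    published report schema uses (type/required/properties/items/enum/
    additionalProperties, numeric bounds)."""
    errors = []
    typ = schema.get("type")
    if typ is not None:
        types = typ if isinstance(typ, list) else [typ]
        pymap = {"object": dict, "array": list, "string": str,
                 "integer": int, "number": (int, float), "null": type(None),
                 "boolean": bool}
        if not any(isinstance(node, pymap[t]) for t in types) or (
                isinstance(node, bool) and "boolean" not in types):
            errors.append(f"{path}: expected {typ}, got {type(node).__name__}")
            return errors
    if "enum" in schema and node not in schema["enum"]:
        errors.append(f"{path}: {node!r} not in {schema['enum']}")
    if isinstance(node, (int, float)) and not isinstance(node, bool):
        if "minimum" in schema and node < schema["minimum"]:
            errors.append(f"{path}: {node} below minimum")
        if "exclusiveMinimum" in schema and node <= schema["exclusiveMinimum"]:
            errors.append(f"{path}: {node} not above exclusiveMinimum")
        if "maximum" in schema and node > schema["maximum"]:
            errors.append(f"{path}: {node} above maximum")
    if isinstance(node, dict):
        for key in schema.get("required", []):
            if key not in node:
                errors.append(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, val in node.items():
            if key in props:
                errors += _check(val, props[key], f"{path}.{key}")
            elif isinstance(extra, dict):
                errors += _check(val, extra, f"{path}.{key}")
    if isinstance(node, list):
        if "minItems" in schema and len(node) < schema["minItems"]:
            errors.append(f"{path}: fewer than {schema['minItems']} items")
        if "maxItems" in schema and len(node) > schema["maxItems"]:
            errors.append(f"{path}: more than {schema['maxItems']} items")
        item_schema = schema.get("items")
        if isinstance(item_schema, dict):
            for i, val in enumerate(node):
                errors += _check(val, item_schema, f"{path}[{i}]")
    return errors


def validate_report(report: dict) -> list[str]:
    """Check a report against the published JSON schema; returns problems."""
    schema = json.loads(_SCHEMA_PATH.read_text(encoding="utf-8"))
    return _check(report, schema)


def save_report(report: dict, directory, figures=None) -> Path:
    """Write report.json (+ CSV exports) into ``directory``; returns the path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    path = d / "report.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n",
                    encoding="utf-8")
    z = report["zprofile"]
    pd.DataFrame(z["values"], index=z["rows"], columns=z["columns"]
                 ).to_csv(d / "zprofile.csv", index_label="group")
    pd.DataFrame(report["anova"]).to_csv(d / "anova.csv", index=False)
    coef = pd.DataFrame(report["cda"]["std_coefficients"])
    coef.to_csv(d / "cda_coefficients.csv", index=False)
    return path
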