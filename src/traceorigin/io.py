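"""Serialization: fingerprint libraries to JSON, dendrograms to Newick.

The library file is a single human-inspectable JSON document; all matrices
are stored row-major alongside their element/site label arrays, and floats
survive the round trip at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import Dendrogram
from .datamodel import ElementPanel
from .discriminant import (DiscriminantFit, FingerprintLibrary, StepRecord,
                           StepwiseTrace)
from .preprocess import Scaler

__all__ = ["write_library", "read_library", "export_newick"]

FORMAT = "traceorigin-library"
FORMAT_VERSION = 1


def _fit_to_dict(fit: DiscriminantFit) -> dict:
    return {
        "elements": fit.elements,
        "site_order": fit.site_order,
        "coefficients": fit.coefficients.tolist(),
        "constants": fit.constants.tolist(),
        "std_coefficients": fit.std_coefficients.tolist(),
        "eigenvalues": fit.eigenvalues.tolist(),
        "canonical_correlations": fit.canonical_correlations.tolist(),
        "variance_shares": fit.variance_shares.tolist(),
        "residual_wilks": fit.residual_wilks.tolist(),
        "bartlett_chi2": fit.bartlett_chi2.tolist(),
        "bartlett_df": fit.bartlett_df.tolist(),
        "bartlett_p": fit.bartlett_p.tolist(),
        "centroids": fit.centroids.tolist(),
        "pooled_within_cov": fit.pooled_within_cov.tolist(),
        "group_sizes": fit.group_sizes,
        "retained": fit.retained,
        "N": fit.N,
        "k": fit.k,
    }


def _fit_from_dict(d: dict) -> DiscriminantFit:
    arr = lambda key: np.asarray(d[key], dtype=float)
    return DiscriminantFit(
        elements=list(d["elements"]), site_order=list(d["site_order"]),
        coefficients=arr("coefficients"), constants=arr("constants"),
        std_coefficients=arr("std_coefficients"),
        eigenvalues=arr("eigenvalues"),
        canonical_correlations=arr("canonical_correlations"),
        variance_shares=arr("variance_shares"),
        residual_wilks=arr("residual_wilks"),
        bartlett_chi2=arr("bartlett_chi2"),
        bartlett_df=np.asarray(d["bartlett_df"], dtype=int),
        bartlett_p=arr("bartlett_p"), centroids=arr("centroids"),
        pooled_within_cov=arr("pooled_within_cov"),
        group_sizes={str(k): int(v) for k, v in d["group_sizes"].items()},
        retained=int(d["retained"]), N=int(d["N"]), k=int(d["k"]),
    )


def write_library(lib: FingerprintLibrary, path: str | Path) -> None:
    doc = {
        "format": FORMAT,
        "version": FORMAT_VERSION,
        "panel": {"elements": list(lib.panel.elements),
                  "calcium_symbol": lib.panel.calcium_symbol},
        "scaler": {"elements": lib.scaler.elements,
                   "mean": lib.scaler.mean.tolist(),
                   "std": lib.scaler.std.tolist()},
        "trace": {
            "criterion": lib.trace.criterion,
            "f_enter": lib.trace.f_enter,
            "f_remove": lib.trace.f_remove,
            "flagged_empty": lib.trace.flagged_empty,
            "selected": list(lib.trace.selected),
            "steps": [{"step": s.step, "action": s.action,
                       "element": s.element,
                       "criterion_value": s.criterion_value,
                       "partial_f": s.partial_f} for s in lib.trace.steps],
        },
        "fit": _fit_to_dict(lib.fit),
        "config": lib.config,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_library(path: str | Path) -> FingerprintLibrary:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt library file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT:
        raise ValueError(f"{path} is not a {FORMAT} file")
    try:
        panel = ElementPanel(elements=tuple(doc["panel"]["elements"]),
                             calcium_symbol=doc["panel"]["calcium_symbol"])
        sc = doc["scaler"]
        scaler = Scaler(mean=pd.Series(sc["mean"], index=sc["elements"]),
                        std=pd.Series(sc["std"], index=sc["elements"]))
        tr = doc["trace"]
        trace = StepwiseTrace(
            steps=[StepRecord(int(s["step"]), s["action"], s["element"],
                              float(s["criterion_value"]), float(s["partial_f"]))
                   for s in tr["steps"]],
            selected=list(tr["selected"]), criterion=tr["criterion"],
            f_enter=float(tr["f_enter"]), f_remove=float(tr["f_remove"]),
            flagged_empty=bool(tr["flagged_empty"]),
        )
        fit = _fit_from_dict(doc["fit"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"incomplete library file {path}: {exc}") from exc
    return FingerprintLibrary(panel=panel, scaler=scaler, trace=trace,
                              fit=fit, config=doc.get("config", {}))


_NEWICK_UNSAFE = set(" ()[]{}:;,'\"\t\n")


def _quote(label: str) -> str:
    if set(label) & _NEWICK_UNSAFE:
        return "'" + label.replace("'", "''") + "'"
    return label


def export_newick(tree: Dendrogram) -> str:
    """Newick text for a merge tree.

    Node elevations are half the merge height (so two leaves merged at
    height h sit at the tips of branches of length h/2, and the tree is
    ultrametric); branch length = parent elevation - child elevation.
    """
    n = tree.n_leaves
    if n < 2:
        raise ValueError("need at least 2 leaves to export a tree")
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for j, row in enumerate(tree.merges):
        node = n + j
        heights[node] = float(row[2]) / 2.0
        children[node] = (int(row[0]), int(row[1]))

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - heights[node]
        if node < n:
            return f"{_quote(tree.labels[node])}:{bl:.10g}"
        left, right = children[node]
        h = heights[node]
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = n + len(tree.merges) - 1
    left, right = children[root]
    h = heights[root]
    return f"({render(left, h)},{render(right, h)});"
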