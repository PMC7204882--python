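"""Domain types and tabular I/O for trace-element fingerprinting studies.

The central object is a :class:`SampleTable`: one row per bird, carrying
capture metadata (site, age class, season, context) and a panel of element
concentrations in a single consistent unit (e.g. µg/g dry bone).  Calcium is
always part of the panel because downstream preprocessing expresses every
other element as a ratio to Ca, cancelling variation in the bone's
mineral-to-collagen content.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ELEMENTS",
    "AGE_CLASSES",
    "SEASONS",
    "CONTEXTS",
    "METADATA_COLUMNS",
    "ElementPanel",
    "SampleTable",
    "RunConfig",
    "SchemaError",
    "read_sample_table",
    "write_sample_table",
]

#: The 21-element bone panel measured by ICP-MS/ICP-OES surveys of starling
#: tarsometatarsus; Ca is the normalizer, the other 20 feed the analysis.
DEFAULT_ELEMENTS: tuple[str, ...] = (
    "Al", "Ag", "Ba", "Ca", "Cd", "Co", "Cr", "Cu", "Mo", "Mn", "Pb",
    "S", "Sc", "Se", "Sn", "Sr", "V", "Zn", "Mg", "Na", "K",
)

AGE_CLASSES = ("juvenile", "adult_lt1y", "adult_1plus")
SEASONS = ("summer", "fall")
CONTEXTS = ("vineyard_orchard", "dairy_feedlot", "library", "unknown")
METADATA_COLUMNS = ("bird_id", "site", "age_class", "season", "context")


class SchemaError(ValueError):
    """A table does not match the declared schema (missing/extra columns,
    wrong categorical levels, duplicate identifiers)."""


@dataclass(frozen=True)
class ElementPanel:
    """Ordered element panel with a designated normalizer element.

    Parameters
    ----------
    elements
        Ordered element symbols, including the normalizer (21 by default).
    calcium_symbol
        The element used as the per-bird normalizer (``"Ca"`` by default).
    """

    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    calcium_symbol: str = "Ca"

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        if self.calcium_symbol not in self.elements:
            raise SchemaError(
                f"normalizer {self.calcium_symbol!r} is not in the panel"
            )
        if len(set(self.elements)) != len(self.elements):
            raise SchemaError("duplicate element symbols in panel")

    @property
    def analysis_elements(self) -> tuple[str, ...]:
        """Panel minus the normalizer — what downstream analyses see."""
        return tuple(e for e in self.elements if e != self.calcium_symbol)


@dataclass
class SampleTable:
    """Bird-by-element concentration table with capture metadata.

    ``data`` holds one row per bird with columns ``bird_id, site, age_class,
    season, context`` followed by one column per panel element.  Invariants
    (unique bird_id, complete panel, non-negative concentrations, strictly
    positive Ca) are enforced at construction.
    """

    data: pd.DataFrame
    panel: ElementPanel = field(default_factory=ElementPanel)

    def __post_init__(self) -> None:
        df = self.data
        missing_meta = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing_meta:
            raise SchemaError(f"missing metadata columns: {missing_meta}")
        missing_elem = [e for e in self.panel.elements if e not in df.columns]
        if missing_elem:
            raise SchemaError(f"missing element columns: {missing_elem}")
        df = df.loc[:, list(METADATA_COLUMNS) + list(self.panel.elements)].copy()
        df = df.reset_index(drop=True)
        df["bird_id"] = df["bird_id"].astype(str)
        if df["bird_id"].duplicated().any():
            dups = df.loc[df["bird_id"].duplicated(), "bird_id"].tolist()
            raise SchemaError(f"duplicate bird_id values: {sorted(set(dups))}")
        for col, levels in (
            ("age_class", AGE_CLASSES),
            ("season", SEASONS),
            ("context", CONTEXTS),
        ):
            bad = set(df[col].astype(str)) - set(levels)
            if bad:
                raise SchemaError(f"invalid {col} values: {sorted(bad)}")
        elems = list(self.panel.elements)
        conc = df[elems].apply(pd.to_numeric, errors="coerce")
        bad_rows = conc.isna().any(axis=1)
        if bad_rows.any():
            rid = df.loc[bad_rows, "bird_id"].iloc[0]
            raise ValueError(f"non-numeric concentration for bird {rid!r}")
        neg = (conc < 0).any(axis=1)
        if neg.any():
            rid = df.loc[neg, "bird_id"].iloc[0]
            raise ValueError(f"negative concentration for bird {rid!r}")
        ca = conc[self.panel.calcium_symbol]
        if (ca <= 0).any():
            rid = df.loc[ca <= 0, "bird_id"].iloc[0]
            raise ValueError(
                f"{self.panel.calcium_symbol} must be strictly positive "
                f"(bird {rid!r})"
            )
        df[elems] = conc.astype(float)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def bird_ids(self) -> pd.Series:
        return self.data["bird_id"]

    @property
    def metadata(self) -> pd.DataFrame:
        return self.data[list(METADATA_COLUMNS)]

    @property
    def concentrations(self) -> pd.DataFrame:
        """Element concentrations indexed by bird_id, in panel order."""
        return self.data.set_index("bird_id")[list(self.panel.elements)]

    def subset(self, mask: Iterable[bool]) -> "SampleTable":
        return SampleTable(self.data.loc[np.asarray(list(mask))], self.panel)


@dataclass
class RunConfig:
    """Run-level knobs shared across the pipeline.

    ``f_enter``/``f_remove`` are the partial-F thresholds of the stepwise
    selector (SPSS-style defaults 3.84 / 2.71); ``immigrant_alpha`` sets the
    chi-square cut used to flag birds too far from every library centroid.
    """

    seed: int = 0
    f_enter: float = 3.84
    f_remove: float = 2.71
    selection_criterion: str = "mahalanobis_closest_pair"
    eigenvalue_retention_threshold: float = 1.0
    immigrant_alpha: float = 0.05
    cluster_linkage: str = "ward.D"
    cluster_metric: str = "euclidean"
    support_linkage: str = "average"
    support_metric: str = "correlation"
    bootstrap_scales: tuple[float, ...] = (
        0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4,
    )
    bootstrap_B: int = 1000
    problem_zscore_mode: str = "library"  # or "pooled"
    regions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.f_enter > self.f_remove:
            raise ValueError("f_enter must exceed f_remove")
        if not 0.0 < self.immigrant_alpha < 1.0:
            raise ValueError("immigrant_alpha must lie in (0, 1)")
        self.bootstrap_scales = tuple(float(r) for r in self.bootstrap_scales)
        if any(r <= 0 for r in self.bootstrap_scales):
            raise ValueError("bootstrap scales must all be positive")
        if self.selection_criterion not in ("wilks", "mahalanobis_closest_pair"):
            raise ValueError(
                f"unknown selection criterion {self.selection_criterion!r}"
            )
        if self.problem_zscore_mode not in ("library", "pooled"):
            raise ValueError("problem_zscore_mode must be 'library' or 'pooled'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bootstrap_scales"] = list(self.bootstrap_scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def read_sample_table(path: str | Path, panel: ElementPanel | None = None) -> SampleTable:
    """Read a sample CSV (comma-separated, UTF-8, header required).

    The header must contain ``bird_id``, the metadata columns and one column
    per panel element; column order in the file is irrelevant and is
    normalized to panel order.
    """
    panel = panel or ElementPanel()
    df = pd.read_csv(path, dtype={"bird_id": str})
    return SampleTable(df, panel)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)
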