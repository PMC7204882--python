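"""Ca-ratio normalization and z-standardization of element concentrations.

Bone mineral (apatite) takes up trace cations readily while collagen does
not, and the mineral fraction changes as birds grow; dividing every element
by Ca removes that compositional nuisance.  The ratios are then z-scored so
no single element dominates the multivariate analyses.  The training
statistics (per-element mean and SD over the juvenile library) are kept in a
:class:`Scaler` so birds of unknown origin can be projected into the same
reference frame later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import METADATA_COLUMNS, ElementPanel, SampleTable, SchemaError

__all__ = ["RatioTable", "Scaler", "ZMatrix", "normalize_to_calcium",
           "fit_scaler", "apply_scaler"]


@dataclass
class RatioTable:
    """Element/Ca ratios (dimensionless) with metadata carried through."""

    meta: pd.DataFrame
    ratios: pd.DataFrame  # rows aligned with meta; one column per element

    @property
    def elements(self) -> list[str]:
        return list(self.ratios.columns)

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass
class Scaler:
    """Per-element mean and SD (n-1 denominator) of a training ratio table."""

    mean: pd.Series
    std: pd.Series

    def __post_init__(self) -> None:
        if (self.std <= 0).any():
            bad = self.std.index[self.std <= 0].tolist()
            raise ValueError(f"degenerate (zero) variance for elements {bad}")

    @property
    def elements(self) -> list[str]:
        return list(self.mean.index)


@dataclass
class ZMatrix:
    """Standardized ratio matrix: z = (ratio - mean) / sd per element."""

    meta: pd.DataFrame
    z: pd.DataFrame
    scaler: Scaler = field(repr=False, default=None)

    @property
    def values(self) -> np.ndarray:
        return self.z.to_numpy(dtype=float)

    @property
    def elements(self) -> list[str]:
        return list(self.z.columns)

    def __len__(self) -> int:
        return len(self.z)


def normalize_to_calcium(table: SampleTable, panel: ElementPanel | None = None) -> RatioTable:
    """Divide every non-Ca element by the bird's Ca concentration.

    The result is scale-invariant: multiplying all of a bird's
    concentrations by a constant (dilution, digestion mass) leaves the
    ratios unchanged.
    """
    panel = panel or table.panel
    ca_col = panel.calcium_symbol
    df = table.data
    ca = df[ca_col].to_numpy(dtype=float)
    if (ca <= 0).any():
        rid = df.loc[ca <= 0, "bird_id"].iloc[0]
        raise ValueError(f"{ca_col} must be positive to form ratios (bird {rid!r})")
    elems = list(panel.analysis_elements)
    ratios = df[elems].to_numpy(dtype=float) / ca[:, None]
    meta = df[list(METADATA_COLUMNS)].reset_index(drop=True)
    return RatioTable(meta=meta, ratios=pd.DataFrame(ratios, columns=elems))


def fit_scaler(ratio: RatioTable) -> Scaler:
    """Compute per-element mean and SD (n-1 denominator) of a training set."""
    if len(ratio) < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    mean = ratio.ratios.mean(axis=0)
    std = ratio.ratios.std(axis=0, ddof=1)
    if (std <= 0).any():
        bad = std.index[std <= 0].tolist()
        raise ValueError(f"constant column(s) {bad}: cannot z-score")
    return Scaler(mean=mean, std=std)


def apply_scaler(scaler: Scaler, ratio: RatioTable) -> ZMatrix:
    """Standardize a ratio table with previously fitted statistics."""
    if list(ratio.ratios.columns) != scaler.elements:
        raise SchemaError(
            "element mismatch between scaler and table: "
            f"{scaler.elements} vs {list(ratio.ratios.columns)}"
        )
    z = (ratio.ratios - scaler.mean) / scaler.std
    return ZMatrix(meta=ratio.meta.reset_index(drop=True),
                   z=z.reset_index(drop=True), scaler=scaler)
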