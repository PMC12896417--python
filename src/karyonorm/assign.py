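"""Subgenome assignment from WGS coverage ratios, with threshold sensitivity scan.

A gene's coverage ratio cr (euploid / aneuploid) identifies its subgenome:
under per-subline-independent normalization S genes sit near 1.5 and L1/L2
genes near 0.75 (under L-anchored normalization, near 2.0 and 1.0).  Fixed
thresholds with a buffer zone keep only confident calls: cr >= s_min is S,
cr <= l_max is L, and the gap between them — the "no man's land" — is NA,
as is any undefined cr.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

LABEL_S = "S"
LABEL_L = "L"
LABEL_NA = "NA"


@dataclass(frozen=True)
class AssignmentThresholds:
    """Buffer-zone thresholds: cr >= ``s_min`` -> S, cr <= ``l_max`` -> L."""

    s_min: float = 1.375
    l_max: float = 1.125

    def __post_init__(self) -> None:
        if not (self.s_min >= self.l_max > 0):
            raise ConfigurationError(
                f"need s_min >= l_max > 0, got s_min={self.s_min}, l_max={self.l_max}"
            )


DEFAULT_THRESHOLDS = AssignmentThresholds()


def assign_subgenome(
    cr: float | pd.Series,
    thresholds: AssignmentThresholds = DEFAULT_THRESHOLDS,
) -> str | pd.Series:
    """Map coverage ratio(s) to ``"S"``, ``"L"`` or ``"NA"`` (buffer zone / undefined)."""
    scalar = np.isscalar(cr) or cr is None
    values = pd.Series([cr]) if scalar else cr.astype(float)
    arr = values.to_numpy(dtype=float)
    labels = np.full(arr.shape, LABEL_NA, dtype=object)
    defined = np.isfinite(arr)
    labels[defined & (arr >= thresholds.s_min)] = LABEL_S
    labels[defined & (arr <= thresholds.l_max)] = LABEL_L
    if scalar:
        return labels[0]
    return pd.Series(labels, index=values.index, name="subgenome")


def assignment_table(
    cr: pd.Series | pd.DataFrame,
    thresholds: AssignmentThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-gene table of cr, label and the thresholds used."""
    if isinstance(cr, pd.DataFrame):
        cr = cr["cr"]
    labels = assign_subgenome(cr, thresholds)
    out = pd.DataFrame({"cr": cr, "subgenome": labels})
    out.attrs["s_min"] = thresholds.s_min
    out.attrs["l_max"] = thresholds.l_max
    return out


DEFAULT_S_MIN_GRID = (1.30, 1.35, 1.375, 1.40, 1.45, 1.50)


def sensitivity_scan(
    cr: pd.Series | pd.DataFrame,
    s_min_grid: Sequence[float] = DEFAULT_S_MIN_GRID,
    l_max_grid: Sequence[float] | None = None,
    deg_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Re-assign subgenomes over a grid of threshold pairs.

    When ``l_max_grid`` is omitted, l_max co-varies as ``s_min - 0.25`` so
    the buffer width stays constant across the scan.  For each pair the scan
    reports S/L/NA counts over all genes and, if ``deg_genes`` is given,
    restricted to that set, plus the S share among assigned genes
    (``prop_s`` = S / (S + L)).  Rows are sorted by ``s_min``.
    """
    if isinstance(cr, pd.DataFrame):
        cr = cr["cr"]
    if len(s_min_grid) == 0:
        raise ConfigurationError("empty threshold grid")
    if l_max_grid is None:
        l_max_grid = [s - 0.25 for s in s_min_grid]
    if len(l_max_grid) != len(s_min_grid):
        raise ConfigurationError("s_min and l_max grids differ in length")

    deg_index = cr.index.intersection(pd.Index(deg_genes)) if deg_genes is not None else None
    rows = []
    for s_min, l_max in sorted(zip(s_min_grid, l_max_grid)):
        thresholds = AssignmentThresholds(s_min=s_min, l_max=l_max)  # validates the pair
        labels = assign_subgenome(cr, thresholds)
        counts = labels.value_counts()
        row = {
            "s_min": s_min,
            "l_max": l_max,
            "n_s": int(counts.get(LABEL_S, 0)),
            "n_l": int(counts.get(LABEL_L, 0)),
            "n_na": int(counts.get(LABEL_NA, 0)),
        }
        assigned = row["n_s"] + row["n_l"]
        row["prop_s"] = row["n_s"] / assigned if assigned else np.nan
        if deg_index is not None:
            sub = labels.loc[deg_index].value_counts()
            row["deg_s"] = int(sub.get(LABEL_S, 0))
            row["deg_l"] = int(sub.get(LABEL_L, 0))
            row["deg_na"] = int(sub.get(LABEL_NA, 0))
            deg_assigned = row["deg_s"] + row["deg_l"]
            row["deg_prop_s"] = row["deg_s"] / deg_assigned if deg_assigned else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
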