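"""Shared in-memory containers for gene-level count data.

The pipeline moves gene-level integer count matrices (genes x sequencing
libraries) between stages, together with per-library metadata (subline,
assay, replicate) and per-gene lengths.  A thin dataclass around pandas
objects keeps those three pieces aligned and validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

WGS = "WGS"
RNA = "RNA"

LIBRARY_COLUMNS = ("subline", "assay", "replicate")


@dataclass
class CountMatrix:
    """Genes x libraries count matrix with library metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, index = gene ids, columns = library ids.
    libraries
        One row per library (index = library id) with columns
        ``subline``, ``assay`` (``"WGS"`` or ``"RNA"``) and ``replicate``.
    lengths
        Gene length in bp, indexed like ``counts``; optional for RNA data.
    """

    counts: pd.DataFrame
    libraries: pd.DataFrame
    lengths: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise InputError("duplicate gene ids in count matrix")
        if not self.counts.columns.equals(self.libraries.index):
            if set(self.counts.columns) != set(self.libraries.index):
                raise InputError("count columns and library metadata disagree")
            self.libraries = self.libraries.loc[self.counts.columns]
        missing = set(LIBRARY_COLUMNS) - set(self.libraries.columns)
        if missing:
            raise InputError(f"library metadata lacks columns: {sorted(missing)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise InputError("counts must be numeric")
        if (values < 0).any():
            raise InputError("counts must be non-negative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise InputError("lengths missing for some genes")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sublines(self) -> list[str]:
        return list(dict.fromkeys(self.libraries["subline"]))

    def libraries_of(self, subline: str) -> pd.Index:
        """Library ids belonging to one subline."""
        return self.libraries.index[self.libraries["subline"] == subline]

    def subset_libraries(self, library_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[list(library_ids)],
            libraries=self.libraries.loc[list(library_ids)],
            lengths=self.lengths,
            meta=dict(self.meta),
        )


def library_table(library_ids, sublines, assay, replicates) -> pd.DataFrame:
    """Build a library-metadata table from parallel sequences."""
    return pd.DataFrame(
        {"subline": list(sublines), "assay": assay, "replicate": list(replicates)},
        index=pd.Index(library_ids, name="library_id"),
    )
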