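"""WGS coverage normalization, coverage ratios and the gene-level dosage matrix.

The copy-number signal lives in the ratio of depth- and length-normalized
WGS coverage between the two sublines (cr).  Two normalization modes are
meaningful and deliberately kept apart:

``per_subline_independent``
    median-of-ratios size factors computed within each subline's libraries
    separately, then per-kb length normalization.  For the emulated
    karyotypes (SSL1L2 vs SSL1L1L2L2, equal subgenome sizes) this puts
    subgenome-S genes at cr = 1.5 and L1/L2 genes at cr = 0.75.

``L_anchored``
    size factors recomputed across *all* libraries using only a set of
    anchor genes (the L1/L2 subset found from the bimodal cr distribution).
    Forcing the anchors flat moves L genes to cr = 1.0 and S genes to 2.0.
    This is the normalization behind the gene-level dosage-factor matrix.

The dosage-factor matrix holds, for every gene and every RNA library, the
subline's mean L-anchored WGS coverage, row-centred to geometric mean 1.
Multiplied into the RNA-seq size factors it cancels expression changes that
merely track gene dosage — including reference copy-number (collapse)
artifacts, which inflate WGS and RNA coverage identically and therefore
drop out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import DegenerateInputError, InputError, NormalizationError
from .simulate import GeneModel

MODE_INDEPENDENT = "per_subline_independent"
MODE_L_ANCHORED = "L_anchored"

#: Genes shorter than this are expanded (in bp) before WGS counting.
MIN_GENE_SPAN = 10_000


def expand_gene_interval(
    gene: GeneModel | tuple[int, int],
    scaffold_len: int,
    min_len: int = MIN_GENE_SPAN,
) -> tuple[int, int]:
    """Expand a short gene symmetrically to ``min_len`` bp.

    Low-pass WGS needs a minimum window to accumulate counts, so genes
    shorter than ``min_len`` are grown in both directions around their
    midpoint.  If one end hits a scaffold edge the interval is shifted to
    keep its full length where the scaffold allows; otherwise it is clipped.
    Genes already >= ``min_len`` are returned unchanged.
    """
    start, end = (gene.start, gene.end) if isinstance(gene, GeneModel) else gene
    if not 0 <= start < end:
        raise InputError(f"invalid interval [{start}, {end})")
    if end > scaffold_len:
        raise InputError(f"interval [{start}, {end}) exceeds scaffold length {scaffold_len}")
    length = end - start
    if length >= min_len:
        return start, end
    pad = min_len - length
    new_start = start - pad // 2
    new_end = end + (pad - pad // 2)
    if new_start < 0:
        new_end -= new_start
        new_start = 0
    if new_end > scaffold_len:
        new_start -= new_end - scaffold_len
        new_end = scaffold_len
        new_start = max(new_start, 0)
    return new_start, new_end


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq2-style size factors: per-library median ratio to the geometric-mean gene.

    Genes with a zero count in any library are excluded from the reference,
    per the standard estimator.  Raises if no gene is positive everywhere.
    """
    if counts.shape[1] == 0:
        raise NormalizationError("no libraries")
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has positive counts in every library")
    logs = np.log(values[positive])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class NormalizedCoverage:
    """Depth- and length-normalized WGS coverage (per-kb scale)."""

    values: pd.DataFrame
    libraries: pd.DataFrame
    mode: str
    anchor_genes: pd.Index = field(default_factory=lambda: pd.Index([]))
    size_factors: pd.Series | None = None

    def subline_means(self) -> pd.DataFrame:
        """Mean normalized coverage per subline (columns = sublines)."""
        groups = self.libraries["subline"]
        return self.values.T.groupby(groups, sort=False).mean().T


def _share_anchor(counts: pd.DataFrame, factors: pd.Series) -> float:
    # rescale factors to the library share scale: normalized values become
    # per-read shares, so multiplying any one library's counts by a constant
    # changes nothing downstream (the constant enters counts and anchor alike)
    depth = counts.sum(axis=0) / factors
    return float(np.exp(np.log(depth).mean()))


def normalize_wgs(
    cm: CountMatrix,
    mode: str = MODE_INDEPENDENT,
    anchor_genes: Sequence[str] | pd.Index | None = None,
) -> NormalizedCoverage:
    """Depth- and length-normalize WGS counts under one of the two modes.

    Size factors are median-of-ratios, anchored so that normalized values
    are per-read shares (making them invariant to rescaling any library's
    counts): within each subline for the independent mode, across all
    libraries for the L-anchored mode.
    """
    if cm.lengths is None:
        raise InputError("gene lengths are required for WGS normalization")
    if mode == MODE_INDEPENDENT:
        factors = []
        for subline in cm.sublines:
            libs = list(cm.libraries_of(subline))
            f = median_of_ratios_size_factors(cm.counts[libs])
            factors.append(f * _share_anchor(cm.counts[libs], f))
        size_factors = pd.concat(factors).reindex(cm.counts.columns)
        anchors = pd.Index([])
    elif mode == MODE_L_ANCHORED:
        if anchor_genes is None or len(anchor_genes) == 0:
            raise NormalizationError("L-anchored normalization requires a non-empty anchor set")
        anchors = pd.Index(anchor_genes)
        missing = anchors.difference(cm.gene_ids)
        if len(missing):
            raise InputError(f"anchor genes absent from matrix: {list(missing)[:5]}")
        size_factors = median_of_ratios_size_factors(cm.counts.loc[anchors])
        size_factors = size_factors * _share_anchor(cm.counts, size_factors)
    else:
        raise InputError(f"unknown normalization mode {mode!r}")

    # reads-per-million share per kb: a convenient absolute scale
    per_kb = 1e6 * cm.counts.div(size_factors, axis=1).div(cm.lengths / 1_000.0, axis=0)
    return NormalizedCoverage(
        values=per_kb,
        libraries=cm.libraries,
        mode=mode,
        anchor_genes=anchors,
        size_factors=size_factors,
    )


def compute_coverage_ratio(
    normcov: NormalizedCoverage,
    cm: CountMatrix,
    numerator: str,
    denominator: str,
    min_total_count: float | None = None,
) -> pd.DataFrame:
    """Per-gene coverage ratio cr = mean(numerator subline) / mean(denominator).

    Genes whose total raw WGS count falls below ``min_total_count``
    (default: 10 x number of libraries) are flagged ``low_coverage`` and get
    cr = NaN, to be filled by :func:`impute_low_coverage`.  A zero
    denominator likewise yields NaN + flag, never a division error.
    """
    for subline in (numerator, denominator):
        if len(cm.libraries_of(subline)) == 0:
            raise InputError(f"subline {subline!r} has no WGS libraries")
    if min_total_count is None:
        min_total_count = 10.0 * cm.counts.shape[1]
    means = normcov.subline_means()
    num, den = means[numerator], means[denominator]
    low = (cm.counts.sum(axis=1) < min_total_count) | (den <= 0)
    cr = num / den.where(den > 0)
    cr[low] = np.nan
    table = pd.DataFrame(
        {
            "cr": cr,
            f"mean_{numerator}": num,
            f"mean_{denominator}": den,
            "low_coverage": low,
            "imputed_from": pd.Series(pd.NA, index=means.index, dtype="object"),
        }
    )
    table.attrs["numerator"] = numerator
    table.attrs["denominator"] = denominator
    table.attrs["mode"] = normcov.mode
    return table


def _two_means_1d(x: np.ndarray, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D 2-means: Lloyd iterations from 25th/75th-percentile centres."""
    centres = np.percentile(x, [25.0, 75.0]).astype(float)
    if centres[0] == centres[1]:
        return np.zeros(len(x), dtype=int), centres
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        new_labels = (np.abs(x[:, None] - centres[None, :])).argmin(axis=1)
        for k in (0, 1):
            if (new_labels == k).any():
                centres[k] = x[new_labels == k].mean()
        if (new_labels == labels).all():
            break
        labels = new_labels
    return labels, centres


def extract_l_subset(cr: pd.Series | pd.DataFrame, min_fold: float = 1.5) -> pd.Index:
    """Split the bimodal log-cr distribution and return the lower-cr (L) genes.

    The two modes must differ by at least ``min_fold`` (the 1.5-fold
    criterion separating single-copy-ratio from balanced genes); otherwise
    the distribution is effectively unimodal and a
    :class:`DegenerateInputError` is raised with the observed fold change.
    """
    if isinstance(cr, pd.DataFrame):
        cr = cr["cr"]
    finite = cr[np.isfinite(cr) & (cr > 0)]
    if len(finite) < 2:
        raise DegenerateInputError("need at least two genes with defined cr")
    labels, centres = _two_means_1d(np.log(finite.to_numpy()))
    fold = float(np.exp(abs(centres[1] - centres[0])))
    if fold < min_fold:
        raise DegenerateInputError(
            f"coverage-ratio modes differ by {fold:.3f}-fold < {min_fold}-fold; "
            "no L1/L2 subset can be separated"
        )
    low_cluster = int(np.argmin(centres))
    return finite.index[labels == low_cluster]


def impute_low_coverage(
    table: pd.DataFrame,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Fill low-coverage genes' cr from the nearest covered gene on the same scaffold.

    Distance is between interval midpoints; ties go to the upstream
    neighbour.  A low-coverage gene alone on its scaffold keeps cr = NaN
    (it will be assigned NA downstream and receive a neutral dosage row).
    ``imputed_from`` records the donor.
    """
    table = table.copy()
    info = pd.DataFrame(
        {
            "scaffold": [g.scaffold for g in genes],
            "mid": [(g.start + g.end) / 2.0 for g in genes],
            "start": [g.start for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    ).reindex(table.index)
    if info["scaffold"].isna().any():
        raise InputError("annotation does not cover all genes in the ratio table")

    needs = table.index[table["low_coverage"] & table["cr"].isna()]
    donors_ok = ~table["low_coverage"] & table["cr"].notna()
    for gene in needs:
        scaffold = info.at[gene, "scaffold"]
        candidates = info.index[(info["scaffold"] == scaffold) & donors_ok.reindex(info.index, fill_value=False)]
        candidates = candidates.difference([gene])
        if len(candidates) == 0:
            continue
        dist = (info.loc[candidates, "mid"] - info.at[gene, "mid"]).abs()
        best = dist.min()
        nearest = dist.index[dist == best]
        if len(nearest) > 1:  # tie: prefer the upstream (smaller start) neighbour
            nearest = [info.loc[nearest, "start"].idxmin()]
        donor = nearest[0]
        table.at[gene, "cr"] = table.at[donor, "cr"]
        table.at[gene, "imputed_from"] = donor
    return table


@dataclass
class DosageFactorMatrix:
    """Genes x RNA-libraries multiplicative dosage factors (row geomean = 1)."""

    values: pd.DataFrame
    mode: str
    anchor_genes: pd.Index

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise InputError("dosage factors must be positive and finite")


def build_dosage_matrix(
    normcov: NormalizedCoverage,
    rna_libraries: pd.DataFrame,
    ratio_table: pd.DataFrame | None = None,
) -> DosageFactorMatrix:
    """Turn L-anchored WGS coverage into per-RNA-sample dosage factors.

    Every RNA library inherits its subline's mean normalized WGS coverage,
    gene by gene; rows are then centred to geometric mean 1 so the matrix
    carries only *relative* dosage between sublines and leaves library size
    factors interpretable.  Low-coverage genes take their donor's row (from
    ``ratio_table.imputed_from``) or a neutral all-ones row.
    """
    means = normcov.subline_means()
    missing = set(rna_libraries["subline"]) - set(means.columns)
    if missing:
        raise InputError(f"RNA sublines absent from WGS data: {sorted(missing)}")

    per_subline = means.copy()
    usable = per_subline.notna().all(axis=1) & (per_subline > 0).all(axis=1)
    if ratio_table is not None:
        low = ratio_table["low_coverage"].reindex(per_subline.index, fill_value=False)
        usable &= ~low.astype(bool)
        filled = pd.Series(False, index=per_subline.index)
        for gene, donor in ratio_table["imputed_from"].dropna().items():
            if gene in per_subline.index and donor in per_subline.index and usable[donor]:
                per_subline.loc[gene] = per_subline.loc[donor]
                filled[gene] = True
        usable |= filled
    per_subline[~usable] = 1.0  # unusable rows: neutral dosage

    matrix = pd.DataFrame(
        {lib: per_subline[sub] for lib, sub in rna_libraries["subline"].items()},
        index=per_subline.index,
    )
    geomean = np.exp(np.log(matrix).mean(axis=1))
    matrix = matrix.div(geomean, axis=0)
    return DosageFactorMatrix(values=matrix, mode=normcov.mode, anchor_genes=normcov.anchor_genes)


def wgs_dosage_workflow(
    cm: CountMatrix,
    genes: Sequence[GeneModel],
    rna_libraries: pd.DataFrame,
    numerator: str,
    denominator: str,
    min_total_count: float | None = None,
    min_fold: float = 1.5,
):
    """Full WGS arm: independent cr -> L subset -> anchored cr -> dosage matrix.

    Returns ``(ratio_table, anchored_table, dosage_matrix, anchors)`` where
    ``ratio_table`` holds the per-subline-independent cr used for subgenome
    assignment (low-coverage genes imputed) and ``anchored_table`` the
    L-anchored cr used for the threshold scan.
    """
    independent = normalize_wgs(cm, MODE_INDEPENDENT)
    table = compute_coverage_ratio(independent, cm, numerator, denominator, min_total_count)
    anchors = extract_l_subset(table, min_fold=min_fold)
    anchored = normalize_wgs(cm, MODE_L_ANCHORED, anchor_genes=anchors)
    anchored_table = compute_coverage_ratio(anchored, cm, numerator, denominator, min_total_count)
    table = impute_low_coverage(table, genes)
    anchored_table = impute_low_coverage(anchored_table, genes)
    dosage = build_dosage_matrix(anchored, rna_libraries, ratio_table=anchored_table)
    return table, anchored_table, dosage, anchors
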