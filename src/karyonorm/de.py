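"""Dosage-normalized differential expression between two sublines.

The central object is a gene x sample matrix of normalization factors
f_gj = s_j * w_gj combining ordinary library size factors s_j with the
WGS-derived dosage factors w_gj.  Used as offsets in a negative-binomial
GLM, the dosage term cancels expression differences that merely track gene
copy number, so the Wald test on the subline coefficient detects only
regulatory departures from dosage proportionality (dosage compensation,
trans-effects of aneuploidy).

Size factors are estimated by median-of-ratios on counts *divided by* the
dosage matrix (the DESeq2 ``normMatrix`` convention).  Dividing out the
dosage term first makes the per-library ratio distribution unimodal; on raw
counts the pooled median would land at an off-centre quantile of whichever
subgenome holds the majority of genes and bias every fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .errors import InputError, ModelError
from .glm import nb_irls
from .simulate import SublineKaryotype, genome_size_ratio
from .wgs import DosageFactorMatrix, median_of_ratios_size_factors

LOG2 = float(np.log(2.0))
_ALPHA_FLOOR = 1e-8


@dataclass
class NormalizationBundle:
    """Library size factors, dosage factors and their elementwise product."""

    size_factors: pd.Series
    dosage: pd.DataFrame  # genes x libraries, row geomean 1 (all ones if no WGS arm)
    factors: pd.DataFrame  # f = s * w

    def depth_only_factors(self) -> pd.DataFrame:
        """Offsets with the gene-level dosage term switched off (w = 1)."""
        return pd.DataFrame(
            np.tile(self.size_factors.to_numpy(), (len(self.factors), 1)),
            index=self.factors.index,
            columns=self.factors.columns,
        )


def combine_normalization(
    cm: CountMatrix,
    dosage: DosageFactorMatrix | pd.DataFrame | None = None,
) -> NormalizationBundle:
    """Combine RNA-seq size factors with the WGS dosage matrix.

    With no dosage matrix this reduces to plain median-of-ratios size
    factors broadcast over genes.
    """
    counts = cm.counts
    if dosage is None:
        w = pd.DataFrame(1.0, index=counts.index, columns=counts.columns)
    else:
        w = dosage.values if isinstance(dosage, DosageFactorMatrix) else dosage
        if not counts.index.equals(w.index):
            if set(counts.index) != set(w.index):
                raise InputError("dosage matrix and counts cover different gene universes")
            w = w.reindex(counts.index)
        if not counts.columns.equals(w.columns):
            if set(counts.columns) != set(w.columns):
                raise InputError("dosage matrix and counts cover different libraries")
            w = w[counts.columns]
        # defensive re-centring: rows must have geometric mean 1
        w = w.div(np.exp(np.log(w).mean(axis=1)), axis=0)
    s = median_of_ratios_size_factors(counts / w)
    f = w.mul(s, axis=1)
    return NormalizationBundle(size_factors=s, dosage=w, factors=f)


def filter_low_expression(cm: CountMatrix, min_mean: float = 10.0) -> pd.Series:
    """Keep genes whose mean raw count reaches ``min_mean`` in at least one subline.

    Mirrors the exclusion rule "mean counts less than ``min_mean`` in *both*
    groups": a single passing group suffices, and the boundary value passes
    (the comparison is strict below).
    """
    groups = cm.libraries["subline"]
    group_means = cm.counts.T.groupby(groups, sort=False).mean().T
    kept = (group_means >= min_mean).any(axis=1)
    kept.name = "kept"
    return kept


def _dispersion_trend(base_mean: np.ndarray, alpha_gene: np.ndarray) -> np.ndarray:
    """Mean--dispersion trend alpha(mu) = a0 + a1/mu through gene-wise estimates.

    Fit as a gamma GLM with identity link (iteratively reweighted least
    squares with 1/pred^2 weights, extreme-ratio genes dropped between
    rounds).  The identity-link fit targets the arithmetic mean of the
    skewed gene-wise sampling distribution, for which the adjusted profile
    MLE is nearly unbiased; a log-scale fit would track its median and
    underestimate the trend.
    """
    ok = (alpha_gene > 0) & (base_mean > 0)
    if ok.sum() < 10:
        level = float(np.mean(alpha_gene[ok])) if ok.any() else _ALPHA_FLOOR
        return np.full_like(base_mean, max(level, _ALPHA_FLOOR))
    x = 1.0 / base_mean[ok]
    y = alpha_gene[ok]
    use = np.ones(len(y), dtype=bool)
    coef = np.array([max(float(np.mean(y)), 1e-8), 0.0])
    for _ in range(12):
        pred = np.maximum(coef[0] + coef[1] * x, 1e-10)
        ratio = y / pred
        new_use = (ratio < 15.0) & (ratio > 1e-4)
        w = 1.0 / pred[new_use] ** 2
        X = np.column_stack([np.ones(new_use.sum()), x[new_use]])
        wX = X * w[:, None]
        try:
            new_coef = np.linalg.solve(wX.T @ X, wX.T @ y[new_use])
        except np.linalg.LinAlgError:
            break
        new_coef = np.maximum(new_coef, 0.0)
        if np.allclose(new_coef, coef, rtol=1e-6) and (new_use == use).all():
            coef = new_coef
            break
        coef, use = new_coef, new_use
    if coef.sum() <= 0:
        coef[0] = max(float(np.mean(y)), _ALPHA_FLOOR)
    return np.maximum(coef[0] + coef[1] / np.maximum(base_mean, 1e-12), _ALPHA_FLOOR)


_ALPHA_GRID = np.exp(np.linspace(np.log(1e-6), np.log(10.0), 81))


def _genewise_dispersion_mle(
    K: np.ndarray, f: np.ndarray, in_alt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cox--Reid-adjusted profile-likelihood dispersion, maximized on a log grid.

    Group means are profiled out as sum(K)/sum(f) per group; the adjustment
    -0.5*(log sum W_ref + log sum W_alt), W = mu/(1+alpha*mu), corrects the
    downward small-sample bias from plugging in estimated means.  Returns
    the per-gene argmax (with one parabolic refinement in log alpha) and a
    mask of genes whose maximum is interior to the grid.
    """
    from scipy.special import gammaln

    mu = np.empty_like(f)
    for mask in (~in_alt, in_alt):
        m = K[:, mask].sum(axis=1) / f[:, mask].sum(axis=1)
        mu[:, mask] = f[:, mask] * np.maximum(m, 1e-300)[:, None]

    n_genes = K.shape[0]
    ll = np.empty((n_genes, len(_ALPHA_GRID)))
    for i, a in enumerate(_ALPHA_GRID):
        size = 1.0 / a
        term = (
            gammaln(K + size)
            - gammaln(size)
            + K * np.log(a * mu / (1.0 + a * mu))
            - size * np.log1p(a * mu)
        )
        W = mu / (1.0 + a * mu)
        cr = 0.5 * (np.log(W[:, ~in_alt].sum(axis=1)) + np.log(W[:, in_alt].sum(axis=1)))
        ll[:, i] = term.sum(axis=1) - cr

    best = ll.argmax(axis=1)
    interior = (best > 0) & (best < len(_ALPHA_GRID) - 1)
    log_grid = np.log(_ALPHA_GRID)
    alpha = log_grid[best].copy()
    if interior.any():
        i = best[interior]
        y0, y1, y2 = (ll[interior, i - 1], ll[interior, i], ll[interior, i + 1])
        denom = y0 - 2.0 * y1 + y2
        step = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        h = log_grid[1] - log_grid[0]
        alpha[interior] = log_grid[i] + np.clip(step, -1.0, 1.0) * h
    return np.exp(alpha), interior


def estimate_dispersion(
    cm: CountMatrix,
    bundle: NormalizationBundle,
    genes: Sequence[str] | None = None,
) -> pd.Series:
    """Per-gene NB dispersion: adjusted profile MLE squeezed toward a trend.

    Gene-wise estimates maximize the Cox--Reid-adjusted NB profile
    likelihood given the normalization offsets.  They are then shrunk on the
    log scale toward a robust mean--dispersion trend alpha(mu) = a0 + a1/mu
    with an empirical-Bayes weight: the gene-wise log-estimate's approximate
    sampling variance V_g is compared with the observed residual spread
    around the trend, and the gene-wise term keeps weight tau^2/(tau^2+V_g)
    where tau^2 is the excess (true between-gene) variance.  With few
    replicates this collapses to the trend unless dispersions genuinely
    vary between genes.  Genes whose likelihood peaks at the lower grid
    boundary (no measurable overdispersion) take the trend value;
    everything is floored at 1e-8.
    """
    index = pd.Index(genes) if genes is not None else cm.gene_ids
    counts = cm.counts.loc[index]
    f = bundle.factors.loc[index]
    groups = cm.libraries["subline"]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ModelError("dispersion estimation needs >= 2 replicates per subline")
    in_alt = (groups != groups.iloc[0]).to_numpy()
    df = len(groups) - 2

    K = counts.to_numpy(dtype=float)
    fv = f.to_numpy(dtype=float)
    alpha_gene, informative = _genewise_dispersion_mle(K, fv, in_alt)

    y = counts / f
    mu_bar = np.maximum(y.mean(axis=1).to_numpy(), 1e-300)
    xi = (1.0 / f).mean(axis=1).to_numpy()
    trend = _dispersion_trend(mu_bar, np.where(informative, alpha_gene, -1.0))

    v_g = (2.0 / df) * (1.0 + xi / np.maximum(trend * mu_bar, 1e-12)) ** 2
    resid = np.log(alpha_gene[informative]) - np.log(trend[informative])
    if resid.size >= 10:
        v_obs = float((1.4826 * np.median(np.abs(resid - np.median(resid)))) ** 2)
    else:
        v_obs = 0.0
    base_v = float(np.median(v_g[informative])) if informative.any() else 0.0
    tau2 = max(v_obs - base_v, 0.0)
    weight = tau2 / (tau2 + v_g)

    log_alpha = np.log(trend)
    log_alpha[informative] = (1.0 - weight[informative]) * np.log(trend[informative]) + weight[
        informative
    ] * np.log(alpha_gene[informative])
    alpha = np.maximum(np.exp(log_alpha), _ALPHA_FLOOR)
    return pd.Series(alpha, index=index, name="dispersion")


def wald_test_nb(
    cm: CountMatrix,
    bundle: NormalizationBundle,
    dispersions: pd.Series,
    contrast: tuple[str, str],
    genes: Sequence[str] | None = None,
    use_dosage: bool = True,
) -> pd.DataFrame:
    """NB GLM Wald test of the subline coefficient for every gene.

    ``contrast = (reference, alternative)``; log2FC is alternative vs
    reference.  ``use_dosage=False`` fits the same model with the gene-level
    dosage term removed from the offsets (the ablation of the method).
    Non-converged or degenerate genes (a group with zero total count) get
    NaN statistics and are excluded from multiple-testing correction.
    """
    index = pd.Index(genes) if genes is not None else cm.gene_ids
    ref, alt = contrast
    for subline in contrast:
        if subline not in set(cm.libraries["subline"]):
            raise InputError(f"subline {subline!r} not present in RNA libraries")
    f = bundle.factors if use_dosage else bundle.depth_only_factors()
    f = f.loc[index]
    counts = cm.counts.loc[index]
    x = (cm.libraries["subline"] == alt).to_numpy(dtype=float)

    fit = nb_irls(
        counts.to_numpy(dtype=float),
        np.log(f.to_numpy(dtype=float)),
        x,
        dispersions.reindex(index).to_numpy(dtype=float),
    )
    beta1 = fit["beta1"]
    se1 = fit["se1"]
    ok = fit["converged"]
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(ok, beta1 / se1, np.nan)
    p = np.where(np.isfinite(stat), 2.0 * stats.norm.sf(np.abs(stat)), np.nan)

    base_mean = (counts / f).mean(axis=1).to_numpy()
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(ok, beta1 / LOG2, np.nan),
            "se_log2fc": np.where(ok, se1 / LOG2, np.nan),
            "stat": stat,
            "pvalue": p,
        },
        index=index,
    )
    out["converged"] = ok
    out.attrs["contrast"] = contrast
    out.attrs["use_dosage"] = use_dosage
    return out


def adjust_bh(p: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini--Hochberg step-up over the non-NaN entries."""
    series = isinstance(p, pd.Series)
    arr = np.asarray(p, dtype=float)
    valid = np.isfinite(arr)
    if ((arr[valid] < 0) | (arr[valid] > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if valid.any():
        out[valid] = multipletests(arr[valid], method="fdr_bh")[1]
    if series:
        return pd.Series(out, index=p.index, name="padj")
    return out


def call_and_classify_degs(
    results: pd.DataFrame,
    assignments: pd.Series | pd.DataFrame | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag DEGs (padj < alpha and |FC| > fc_threshold) and tabulate by subgenome.

    Returns the augmented per-gene table and a direction x subgenome count
    summary.  Direction is ``up``/``down`` for DEGs (sign of log2FC) and
    ``none`` otherwise.
    """
    out = results.copy()
    if "padj" not in out:
        out["padj"] = adjust_bh(out["pvalue"])
    lfc_cut = np.log2(fc_threshold)
    deg = (out["padj"] < alpha) & (out["log2fc"].abs() > lfc_cut)
    deg = deg.fillna(False)
    out["deg"] = deg
    out["direction"] = np.where(~deg, "none", np.where(out["log2fc"] > 0, "up", "down"))
    if assignments is not None:
        if isinstance(assignments, pd.DataFrame):
            assignments = assignments["subgenome"]
        out["subgenome"] = assignments.reindex(out.index).fillna("NA")
    else:
        out["subgenome"] = "NA"
    summary = (
        out[out["deg"]]
        .groupby(["direction", "subgenome"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return out, summary


def ddpcr_correction(
    subgenome_or_copies: str | tuple[float, float],
    karyotypes: tuple[SublineKaryotype, SublineKaryotype],
    subgenome_sizes: Mapping[str, float] | None = None,
) -> float:
    """Multiplicative correction for aneuploid-subline transcript abundance.

    ddPCR measures absolute transcript concentration; to compare against a
    per-transcriptome (relative) RNA-seq fold change, the aneuploid
    measurement must be rescaled by the genome-size ratio G divided by the
    gene's copy ratio c_alt/c_ref:

        factor = G / (c_alt / c_ref)

    For the emulated karyotypes (G = 1.5): an S target (copy ratio 1) is
    multiplied by 1.5, an L target (copy ratio 2) by 0.75.
    """
    ref, alt = karyotypes
    if isinstance(subgenome_or_copies, str):
        c_ref = ref.copy_number(subgenome_or_copies)
        c_alt = alt.copy_number(subgenome_or_copies)
    else:
        c_ref, c_alt = subgenome_or_copies
    if c_ref == 0:
        raise InputError("reference copy number is zero; correction undefined")
    g = genome_size_ratio(alt, ref, subgenome_sizes)
    return g / (c_alt / c_ref)


def run_differential_expression(
    cm: CountMatrix,
    contrast: tuple[str, str],
    dosage: DosageFactorMatrix | pd.DataFrame | None = None,
    assignments: pd.Series | pd.DataFrame | None = None,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    min_mean: float = 10.0,
    use_dosage: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, normalize, fit, test, adjust and classify in one call.

    The returned table covers the full gene universe with a ``filtered``
    column; filtered genes carry NaN statistics.  ``use_dosage=False`` keeps
    the same size factors but drops the gene-level dosage term (ablation).
    """
    kept = filter_low_expression(cm, min_mean=min_mean)
    bundle = combine_normalization(cm, dosage)
    tested = kept.index[kept]
    dispersions = estimate_dispersion(cm, bundle, genes=tested)
    results = wald_test_nb(cm, bundle, dispersions, contrast, genes=tested, use_dosage=use_dosage)
    results["padj"] = adjust_bh(results["pvalue"])
    results = results.reindex(cm.gene_ids)
    results["filtered"] = ~kept
    results["converged"] = results["converged"].fillna(False).astype(bool)
    table, summary = call_and_classify_degs(
        results, assignments, alpha=alpha, fc_threshold=fc_threshold
    )
    table.attrs["contrast"] = contrast
    table.attrs["use_dosage"] = use_dosage
    return table, summary
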