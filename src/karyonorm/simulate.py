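"""Synthetic genomes, WGS and RNA-seq count matrices for a two-subline design.

The generator emulates a pair of *Macrostomum lignano* sublines that differ
in the copy number of the large fused chromosome: a hidden tetraploid
(karyotype SSL1L2, 2n = 8) and a hidden hexaploid (SSL1L1L2L2, 2n = 10).
Genes live on one of three subgenomes (S, L1, L2); the two sublines share
the S complement (two copies each) and differ two-fold on L1 and L2.

Counts are drawn under *fixed-total-reads* (compositional) sampling: each
library sequences a fixed read budget, and a gene's expected count is its
share of the subline's total sequenceable material.  For WGS the share is
proportional to gene length x copy number; for RNA-seq it is proportional
to the per-copy transcription rate x copy number x a regulatory multiplier.
This is what makes dosage normalization non-trivial: nothing in a single
library reveals absolute copy number, only relative shares do.

Three kinds of "special" genes break pure dosage proportionality:

* trans-DE genes carry a regulatory multiplier m != 1 in the aneuploid
  subline (the nonlinear transcriptional response to aneuploidy);
* dosage-compensated L genes halve their per-copy output when the copy
  number doubles, so total transcript output is copy-invariant;
* collapsed genes model reference-assembly copy-number errors: a single
  multiplier (> 1) inflates both WGS and RNA coverage identically in both
  sublines, and must therefore cancel out of every downstream contrast.

A small fraction of genes is additionally given near-zero WGS capture
efficiency to exercise the nearest-gene imputation of coverage ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import RNA, WGS, CountMatrix, library_table
from .errors import ConfigurationError

SUBGENOMES = ("S", "L1", "L2")


@dataclass(frozen=True)
class SublineKaryotype:
    """Per-subgenome copy numbers of one subline."""

    subline_id: str
    copies: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.copies.values()):
            raise ConfigurationError("copy numbers must be non-negative")
        if sum(self.copies.values()) <= 0:
            raise ConfigurationError("karyotype must have at least one chromosome copy")

    def copy_number(self, subgenome: str) -> int:
        return int(self.copies.get(subgenome, 0))


#: The euploid 2n = 8 subline: two S copies, one copy each of L1 and L2.
DV1_8 = SublineKaryotype("DV1_8", {"S": 2, "L1": 1, "L2": 1})
#: The aneuploid 2n = 10 subline: two extra copies of the large chromosome.
DV1_10 = SublineKaryotype("DV1_10", {"S": 2, "L1": 2, "L2": 2})


def genome_size_ratio(
    alt: SublineKaryotype,
    ref: SublineKaryotype,
    subgenome_sizes: Mapping[str, float] | None = None,
) -> float:
    """Ratio of total genome size, alt / ref, weighting subgenomes by size.

    With equal subgenome sizes and the default karyotypes this is
    (2+2+2)/(2+1+1) = 1.5, matching the ~1.5x larger aneuploid genome.
    """
    subgenomes = set(alt.copies) | set(ref.copies)
    sizes = subgenome_sizes or {h: 1.0 for h in subgenomes}
    num = sum(sizes.get(h, 0.0) * alt.copy_number(h) for h in subgenomes)
    den = sum(sizes.get(h, 0.0) * ref.copy_number(h) for h in subgenomes)
    if den == 0:
        raise ConfigurationError("reference karyotype has zero genome size")
    return num / den


@dataclass
class GeneModel:
    """One annotated gene with its simulation truth.

    Coordinates are 0-based half-open.  ``per_copy_rate`` is the expression
    rate per gene copy (arbitrary units); ``reg_multiplier`` maps subline id
    to the regulatory multiplier m applied on top of dosage (m = 1 for all
    sublines means the gene is purely dosage-proportional).
    ``collapse_factor`` >= 1 models a reference copy-number (collapse)
    artifact inflating WGS and RNA coverage identically in both sublines;
    ``wgs_efficiency`` scales WGS capture only (low-coverage genes).
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    subgenome: str
    per_copy_rate: float
    reg_multiplier: Mapping[str, float]
    collapse_factor: float = 1.0
    wgs_efficiency: float = 1.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigurationError(f"{self.gene_id}: end must exceed start")
        if self.per_copy_rate <= 0 or self.collapse_factor < 1.0:
            raise ConfigurationError(f"{self.gene_id}: invalid rate or collapse factor")

    @property
    def length(self) -> int:
        return self.end - self.start

    def multiplier(self, subline_id: str) -> float:
        return float(self.reg_multiplier.get(subline_id, 1.0))


def _even_depths(n: int, spread: float = 0.1) -> tuple[float, ...]:
    # evenly spaced per-library depth scalars, geometric mean ~1, identical
    # between sublines so per-subline normalization has no global offset
    if n == 1:
        return (1.0,)
    return tuple(1.0 - spread + 2.0 * spread * i / (n - 1) for i in range(n))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic two-subline experiment.

    Defaults mirror the emulated study: three worm pools per subline with
    two WGS replicate libraries each (6 WGS libraries/subline) and one RNA
    library per pool (3 RNA libraries/subline); negative-binomial counts
    with variance mu + alpha*mu^2.  RNA dispersion 0.05 reflects biological
    replication; WGS libraries re-sequence the same pooled DNA, so their
    dispersion is near-technical (0.002).  Special-gene fractions must sum
    to <= 0.2 so that median-based size factors anchor on the
    dosage-proportional majority.
    """

    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {"S": 666, "L1": 667, "L2": 667}
    )
    genes_per_scaffold: int = 20
    intergenic_gap: int = 2_000
    length_range: tuple[int, int] = (500, 30_000)
    rate_range: tuple[float, float] = (1.0, 100.0)
    karyotypes: tuple[SublineKaryotype, SublineKaryotype] = (DV1_8, DV1_10)
    n_wgs_libraries: int = 6
    n_rna_libraries: int = 3
    wgs_depths: Sequence[float] | None = None
    rna_depths: Sequence[float] | None = None
    wgs_reads_per_library: float = 2_000_000.0
    rna_reads_per_library: float = 2_000_000.0
    wgs_dispersion: float = 0.002
    rna_dispersion: float = 0.05
    frac_trans_de: float = 0.05
    trans_de_log2_effect: float = 2.0
    frac_compensated: float = 0.05
    frac_collapsed: float = 0.05
    collapse_factor: float = 2.0
    frac_low_coverage: float = 0.02
    low_coverage_efficiency: float = 0.005
    min_gene_span: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for h, n in self.n_genes.items():
            if h not in SUBGENOMES or n < 0:
                raise ConfigurationError(f"bad gene count for subgenome {h!r}")
        if sum(self.n_genes.values()) == 0:
            raise ConfigurationError("no genes requested")
        if self.genes_per_scaffold < 1 or self.intergenic_gap < 0:
            raise ConfigurationError("invalid scaffold layout")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid gene length range")
        fracs = (
            self.frac_trans_de,
            self.frac_compensated,
            self.frac_collapsed,
            self.frac_low_coverage,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if sum(fracs) > 0.2:
            raise ConfigurationError(
                "special-gene fractions sum to > 0.2; median-based normalization "
                "needs a dosage-proportional majority"
            )
        if self.wgs_dispersion < 0 or self.rna_dispersion < 0:
            raise ConfigurationError("dispersions must be >= 0")
        if self.wgs_reads_per_library <= 0 or self.rna_reads_per_library <= 0:
            raise ConfigurationError("library depths must be positive")
        for depths, n in ((self.wgs_depths, self.n_wgs_libraries),
                          (self.rna_depths, self.n_rna_libraries)):
            if depths is not None:
                if len(depths) != n:
                    raise ConfigurationError("depth scalars do not match library count")
                if any(d <= 0 for d in depths):
                    raise ConfigurationError("depth scalars must be positive")
        a, b = self.karyotypes
        if a.subline_id == b.subline_id:
            raise ConfigurationError("sublines must have distinct ids")
        if a.copy_number("S") < 1 or b.copy_number("S") < 1:
            raise ConfigurationError("both sublines need at least one S copy")
        if all(a.copy_number(h) == b.copy_number(h) for h in SUBGENOMES):
            raise ConfigurationError("sublines must differ in at least one subgenome")

    def resolved_depths(self, assay: str) -> tuple[float, ...]:
        if assay == WGS:
            return tuple(self.wgs_depths) if self.wgs_depths else _even_depths(self.n_wgs_libraries)
        return tuple(self.rna_depths) if self.rna_depths else _even_depths(self.n_rna_libraries)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["karyotypes"] = [
            {"subline_id": k.subline_id, "copies": dict(k.copies)} for k in self.karyotypes
        ]
        for key, value in d.items():  # keep the dict YAML-safe
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "karyotypes" in d:
            d["karyotypes"] = tuple(
                SublineKaryotype(k["subline_id"], dict(k["copies"])) for k in d["karyotypes"]
            )
        for key in ("length_range", "rate_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one independent stream per matrix / per stage, all derived from one seed
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def make_genome(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Lay out genes on scaffolds and assign the simulation truth.

    Scaffolds belong entirely to one subgenome (as real subgenome scaffolds
    do), so a low-coverage gene's nearest neighbour shares its subgenome.
    Returns the gene models and a truth table (one row per gene) recording
    subgenome, copy numbers, regulatory multipliers and special-gene flags.
    """
    rng = _rng(config, 0)
    ref, alt = config.karyotypes

    gene_ids: list[str] = []
    records: list[dict] = []
    for subgenome in SUBGENOMES:
        n = config.n_genes.get(subgenome, 0)
        for i in range(n):
            scaf_index = i // config.genes_per_scaffold
            records.append(
                {
                    "subgenome": subgenome,
                    "scaffold": f"scaf_{subgenome}_{scaf_index + 1}",
                    "rank": i % config.genes_per_scaffold,
                    "locus": i,
                }
            )
    n_total = len(records)

    # one length/rate per ancestral locus, shared by its three homeologs:
    # the S, L1 and L2 subgenomes descend from the same gene complement, so
    # matched draws keep total subgenome sizes equal (the "equal subgenome
    # size" geometry behind the 1.5x genome-size ratio)
    n_pool = max(config.n_genes.get(h, 0) for h in SUBGENOMES)
    lo, hi = config.length_range
    length_pool = np.exp(rng.uniform(np.log(lo), np.log(hi), n_pool)).astype(int)
    rlo, rhi = config.rate_range
    rate_pool = np.exp(rng.uniform(np.log(rlo), np.log(rhi), n_pool))
    locus = np.array([r["locus"] for r in records])
    lengths = length_pool[locus]
    rates = rate_pool[locus]

    # disjoint special-gene classes, drawn without replacement
    order = rng.permutation(n_total)
    subg = np.array([r["subgenome"] for r in records])
    is_l = np.isin(subg, ("L1", "L2"))
    n_comp = int(round(config.frac_compensated * is_l.sum()))
    l_order = [i for i in order if is_l[i]]
    compensated = set(l_order[:n_comp])
    remaining = [i for i in order if i not in compensated]
    n_trans = int(round(config.frac_trans_de * n_total))
    trans = set(remaining[:n_trans])
    remaining = remaining[n_trans:]
    n_coll = int(round(config.frac_collapsed * n_total))
    collapsed = set(remaining[:n_coll])
    remaining = remaining[n_coll:]
    n_low = int(round(config.frac_low_coverage * n_total))
    lowcov = set(remaining[:n_low])

    trans_signs = rng.choice([-1.0, 1.0], size=n_total)

    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    cursor: dict[str, int] = {}
    for i, rec in enumerate(records):
        scaffold = rec["scaffold"]
        if rec["rank"] == 0:
            cursor[scaffold] = config.intergenic_gap
        start = cursor[scaffold]
        end = start + int(lengths[i])
        cursor[scaffold] = end + config.intergenic_gap

        subgenome = rec["subgenome"]
        m_alt = 1.0
        if i in compensated:
            # per-copy output halves when copy number doubles: total invariant
            c_alt = alt.copy_number(subgenome)
            m_alt = ref.copy_number(subgenome) / c_alt if c_alt else 1.0
        elif i in trans:
            m_alt = float(2.0 ** (trans_signs[i] * config.trans_de_log2_effect))
        collapse = config.collapse_factor if i in collapsed else 1.0
        efficiency = config.low_coverage_efficiency if i in lowcov else 1.0

        gene_id = f"g{i + 1:05d}_{subgenome}"
        gene_ids.append(gene_id)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=scaffold,
                start=start,
                end=end,
                subgenome=subgenome,
                per_copy_rate=float(rates[i]),
                reg_multiplier={ref.subline_id: 1.0, alt.subline_id: float(m_alt)},
                collapse_factor=collapse,
                wgs_efficiency=efficiency,
            )
        )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "scaffold": scaffold,
                "start": start,
                "end": end,
                "length": end - start,
                "subgenome": subgenome,
                f"copies_{ref.subline_id}": ref.copy_number(subgenome),
                f"copies_{alt.subline_id}": alt.copy_number(subgenome),
                f"m_{ref.subline_id}": 1.0,
                f"m_{alt.subline_id}": float(m_alt),
                "per_copy_rate": float(rates[i]),
                "is_trans_de": i in trans,
                "is_compensated": i in compensated,
                "is_low_coverage": i in lowcov,
                "collapse_factor": collapse,
            }
        )

    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return genes, truth


def wgs_window_lengths(genes: Sequence[GeneModel], min_span: int) -> np.ndarray:
    """Effective WGS counting-window length per gene (10 Kb expansion rule).

    Low-pass WGS counts the whole gene body; genes shorter than ``min_span``
    are counted over an interval expanded symmetrically to that span
    (clipped at scaffold edges).  Scaffold lengths are inferred from the
    gene layout: last gene end plus the leading margin of the scaffold.
    """
    from .wgs import expand_gene_interval  # local import to avoid a module cycle

    scaf_end: dict[str, int] = {}
    scaf_margin: dict[str, int] = {}
    for g in genes:
        scaf_end[g.scaffold] = max(scaf_end.get(g.scaffold, 0), g.end)
        scaf_margin[g.scaffold] = min(scaf_margin.get(g.scaffold, g.start), g.start)
    out = []
    for g in genes:
        scaffold_len = scaf_end[g.scaffold] + scaf_margin[g.scaffold]
        s, e = expand_gene_interval(g, scaffold_len, min_span)
        out.append(e - s)
    return np.array(out, dtype=float)


def _expected_shares(
    genes: Sequence[GeneModel],
    karyotype: SublineKaryotype,
    assay: str,
    wgs_lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene share of a library's reads under fixed-total-reads sampling."""
    if assay == WGS:
        lengths = (
            wgs_lengths
            if wgs_lengths is not None
            else np.array([g.length for g in genes], dtype=float)
        )
        weight = lengths * np.array(
            [
                karyotype.copy_number(g.subgenome) * g.collapse_factor * g.wgs_efficiency
                for g in genes
            ]
        )
    else:
        weight = np.array(
            [
                g.per_copy_rate
                * karyotype.copy_number(g.subgenome)
                * g.multiplier(karyotype.subline_id)
                * g.collapse_factor
                for g in genes
            ]
        )
    total = weight.sum()
    if total <= 0:
        raise ConfigurationError("karyotype has zero sequenceable material")
    return weight / total


def expected_counts(
    genes: Sequence[GeneModel],
    karyotypes: Sequence[SublineKaryotype],
    config: SimConfig,
    assay: str,
) -> pd.DataFrame:
    """Expected (noise-free) counts for every library of the design."""
    depths = config.resolved_depths(assay)
    reads = config.wgs_reads_per_library if assay == WGS else config.rna_reads_per_library
    wgs_lengths = wgs_window_lengths(genes, config.min_gene_span) if assay == WGS else None
    cols: dict[str, np.ndarray] = {}
    for karyotype in karyotypes:
        share = _expected_shares(genes, karyotype, assay, wgs_lengths=wgs_lengths)
        for r, depth in enumerate(depths, start=1):
            cols[f"{karyotype.subline_id}_{assay}_{r}"] = depth * reads * share
    return pd.DataFrame(cols, index=pd.Index([g.gene_id for g in genes], name="gene_id"))


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def _simulate(
    genes: Sequence[GeneModel],
    karyotypes: Sequence[SublineKaryotype],
    config: SimConfig,
    assay: str,
    stream: int,
    noise: bool,
) -> CountMatrix:
    if not genes:
        raise ConfigurationError("no genes to simulate")
    mu = expected_counts(genes, karyotypes, config, assay)
    if noise:
        rng = _rng(config, stream)
        dispersion = config.wgs_dispersion if assay == WGS else config.rna_dispersion
        values = _sample_nb(rng, mu.to_numpy(), dispersion)
    else:
        values = np.rint(mu.to_numpy()).astype(np.int64)
    counts = pd.DataFrame(values, index=mu.index, columns=mu.columns)

    depths = config.resolved_depths(assay)
    sublines = [k.subline_id for k in karyotypes for _ in depths]
    replicates = [r for _ in karyotypes for r in range(1, len(depths) + 1)]
    libraries = library_table(mu.columns, sublines, assay, replicates)
    if assay == WGS:
        # the counting window, not the annotated gene: downstream length
        # normalization must divide by what was actually counted
        lengths = pd.Series(
            wgs_window_lengths(genes, config.min_gene_span), index=mu.index, name="length"
        )
    else:
        lengths = pd.Series([g.length for g in genes], index=mu.index, name="length")
    meta = {"assay": assay, "seed": config.seed, "stream": stream, "noise": noise}
    return CountMatrix(counts=counts, libraries=libraries, lengths=lengths, meta=meta)


def simulate_wgs(
    genes: Sequence[GeneModel],
    karyotypes: Sequence[SublineKaryotype],
    config: SimConfig,
    noise: bool = True,
) -> CountMatrix:
    """Simulate gene-level WGS counts for every library of both sublines.

    Counts are NB(mean = depth x length x copies x collapse x efficiency / Z,
    dispersion = ``wgs_dispersion``) with Z the subline's total weighted
    length (fixed-total-reads sampling).  ``noise=False`` returns rounded
    expected counts for closed-form checks.
    """
    return _simulate(genes, karyotypes, config, WGS, stream=1, noise=noise)


def simulate_rnaseq(
    genes: Sequence[GeneModel],
    karyotypes: Sequence[SublineKaryotype],
    config: SimConfig,
    noise: bool = True,
) -> CountMatrix:
    """Simulate gene-level RNA-seq counts (rate x copies x m x collapse shares)."""
    return _simulate(genes, karyotypes, config, RNA, stream=2, noise=noise)


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: genome + truth + WGS and RNA count matrices."""
    genes, truth = make_genome(config)
    wgs = simulate_wgs(genes, config.karyotypes, config)
    rna = simulate_rnaseq(genes, config.karyotypes, config)
    return genes, truth, wgs, rna
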