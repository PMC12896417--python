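"""WGS normalization, coverage ratios, L-subset extraction and dosage factors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import karyonorm as kn
from karyonorm.containers import library_table


def _wgs_matrix(counts: dict, sublines: dict, lengths: dict) -> kn.CountMatrix:
    df = pd.DataFrame(counts)
    libs = library_table(df.columns, [sublines[c] for c in df.columns], "WGS", range(len(df.columns)))
    return kn.CountMatrix(df, libs, pd.Series(lengths))


# ---------------------------------------------------------------- intervals


@pytest.mark.parametrize(
    "interval,scaffold_len,expected",
    [
        ((10_000, 14_000), 100_000, (7_000, 17_000)),  # symmetric expansion
        ((0, 12_000), 100_000, (0, 12_000)),  # already long enough
        ((1_000, 3_000), 100_000, (0, 10_000)),  # shifted off the left edge
        ((95_000, 99_000), 100_000, (90_000, 100_000)),  # shifted off the right edge
    ],
)
def test_expand_gene_interval_cases(interval, scaffold_len, expected):
    assert kn.expand_gene_interval(interval, scaffold_len) == expected


def test_expand_gene_interval_rejects_bad_coordinates():
    with pytest.raises(kn.InputError):
        kn.expand_gene_interval((5_000, 12_000), 10_000)


@given(
    start=st.integers(0, 50_000),
    length=st.integers(1, 40_000),
    scaffold_extra=st.integers(0, 60_000),
)
def test_expand_gene_interval_properties(start, length, scaffold_extra):
    """Expanded interval contains the gene and has length min(max(len, 10kb), scaffold)."""
    end = start + length
    scaffold_len = end + scaffold_extra
    s, e = kn.expand_gene_interval((start, end), scaffold_len)
    assert 0 <= s <= start and end <= e <= scaffold_len
    assert e - s == min(max(length, 10_000), scaffold_len)


# ------------------------------------------------------ median of ratios


def test_size_factor_single_library_is_one():
    counts = pd.DataFrame({"a": [5, 10, 20]})
    assert kn.median_of_ratios_size_factors(counts)["a"] == pytest.approx(1.0)


def test_size_factor_hand_example():
    """Genes (10,20) and (30,60): geomeans 14.14/42.43 give factors 1/sqrt(2), sqrt(2)."""
    counts = pd.DataFrame({"lib1": [10, 30], "lib2": [20, 60]})
    f = kn.median_of_ratios_size_factors(counts)
    assert f["lib1"] == pytest.approx(0.7071, abs=1e-4)
    assert f["lib2"] == pytest.approx(1.4142, abs=1e-4)


@given(scale=st.floats(0.1, 10.0))
def test_size_factor_equivariance(scale):
    """Scaling one library scales its factor relative to every other library."""
    counts = pd.DataFrame({"a": [10, 30, 7], "b": [20, 60, 9], "c": [15, 45, 8]})
    base = kn.median_of_ratios_size_factors(counts)
    scaled = counts.copy()
    scaled["b"] = scaled["b"] * scale
    new = kn.median_of_ratios_size_factors(scaled)
    assert new["b"] / new["a"] == pytest.approx(scale * base["b"] / base["a"], rel=1e-9)
    assert new["c"] / new["a"] == pytest.approx(base["c"] / base["a"], rel=1e-9)


def test_size_factor_requires_positive_reference():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(kn.NormalizationError):
        kn.median_of_ratios_size_factors(counts)


# ------------------------------------------------------------ noise-free cr


def test_noise_free_coverage_ratios(noise_free):
    """Independent mode: S at 1.5, L at 0.75; L-anchored: L at 1.0, S at 2.0."""
    wgs, truth = noise_free["wgs"], noise_free["truth"]
    ind = kn.normalize_wgs(wgs, kn.MODE_INDEPENDENT)
    tab = kn.compute_coverage_ratio(ind, wgs, "DV1_8", "DV1_10")
    covered = ~truth.is_low_coverage
    s = truth.index[(truth.subgenome == "S") & covered]
    l = truth.index[(truth.subgenome != "S") & covered]
    assert tab.loc[s, "cr"].median() == pytest.approx(1.5, rel=1e-2)
    assert tab.loc[l, "cr"].median() == pytest.approx(0.75, rel=1e-2)

    anchored = kn.normalize_wgs(wgs, kn.MODE_L_ANCHORED, anchor_genes=l)
    tab2 = kn.compute_coverage_ratio(anchored, wgs, "DV1_8", "DV1_10")
    assert tab2.loc[l, "cr"].median() == pytest.approx(1.0, rel=1e-2)
    assert tab2.loc[s, "cr"].median() == pytest.approx(2.0, rel=1e-2)


def test_mode_relationship_global_rescaling(noise_free):
    """L-anchored cr equals independent cr times one global constant."""
    wgs, truth = noise_free["wgs"], noise_free["truth"]
    l = truth.index[(truth.subgenome != "S") & ~truth.is_low_coverage]
    ind = kn.compute_coverage_ratio(kn.normalize_wgs(wgs, kn.MODE_INDEPENDENT), wgs, "DV1_8", "DV1_10")
    anc = kn.compute_coverage_ratio(
        kn.normalize_wgs(wgs, kn.MODE_L_ANCHORED, anchor_genes=l), wgs, "DV1_8", "DV1_10"
    )
    k = (anc["cr"] / ind["cr"]).dropna()
    assert k.std() / k.mean() < 0.02


def test_scale_invariance_of_normalized_coverage(small_dataset):
    """Multiplying one WGS library by a constant leaves normalized coverage unchanged."""
    wgs = small_dataset["wgs"]
    scaled_counts = wgs.counts.copy()
    scaled_counts.iloc[:, 0] = scaled_counts.iloc[:, 0] * 3
    scaled = kn.CountMatrix(scaled_counts, wgs.libraries, wgs.lengths)
    a = kn.normalize_wgs(wgs, kn.MODE_INDEPENDENT).values
    b = kn.normalize_wgs(scaled, kn.MODE_INDEPENDENT).values
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)


def test_coverage_ratio_edge_cases():
    # equal library totals, so per-read shares compare directly
    cm = _wgs_matrix(
        {"a1": [300, 0, 100, 300], "b1": [200, 0, 0, 500]},
        {"a1": "A", "b1": "B"},
        {0: 1000, 1: 1000, 2: 1000, 3: 1000},
    )
    norm = kn.normalize_wgs(cm, kn.MODE_INDEPENDENT)
    tab = kn.compute_coverage_ratio(norm, cm, "A", "B", min_total_count=20)
    assert tab.loc[0, "cr"] == pytest.approx(1.5)  # coverage in 3:2 proportion
    assert tab.loc[1, "low_coverage"] and np.isnan(tab.loc[1, "cr"])
    assert tab.loc[2, "low_coverage"] and np.isnan(tab.loc[2, "cr"])  # zero denominator
    assert tab.loc[3, "cr"] == pytest.approx(0.6)


# ------------------------------------------------------------- L subset


def test_extract_l_subset_simple():
    cr = pd.Series({"g1": 1.5, "g2": 1.5, "g3": 0.75, "g4": 0.75})
    assert set(kn.extract_l_subset(cr)) == {"g3", "g4"}


def test_extract_l_subset_unimodal_raises():
    cr = pd.Series(np.full(50, 1.0) * np.linspace(0.98, 1.02, 50))
    with pytest.raises(kn.DegenerateInputError):
        kn.extract_l_subset(cr)


def test_extract_l_subset_recovers_truth(noise_free):
    wgs, truth = noise_free["wgs"], noise_free["truth"]
    tab = kn.compute_coverage_ratio(kn.normalize_wgs(wgs, kn.MODE_INDEPENDENT), wgs, "DV1_8", "DV1_10")
    found = set(kn.extract_l_subset(tab))
    # exactly the true L1/L2 genes among those with a defined ratio
    expected = set(truth.index[truth.subgenome != "S"]) & set(tab.index[tab["cr"].notna()])
    assert found == expected


# ------------------------------------------------------------- imputation


def _gene(gene_id, scaffold, start, end, subgenome="S"):
    return kn.GeneModel(
        gene_id=gene_id,
        scaffold=scaffold,
        start=start,
        end=end,
        subgenome=subgenome,
        per_copy_rate=1.0,
        reg_multiplier={},
    )


def test_impute_takes_nearest_neighbour():
    genes = [
        _gene("near", "s1", 4_000, 6_000),  # midpoint 5k away
        _gene("lowcov", "s1", 9_500, 10_500),
        _gene("far", "s1", 17_500, 18_500),  # midpoint 8k away
    ]
    tab = pd.DataFrame(
        {
            "cr": [1.4, np.nan, 0.8],
            "low_coverage": [False, True, False],
            "imputed_from": pd.Series([pd.NA] * 3, dtype="object"),
        },
        index=["near", "lowcov", "far"],
    )
    out = kn.impute_low_coverage(tab, genes)
    assert out.loc["lowcov", "cr"] == pytest.approx(1.4)
    assert out.loc["lowcov", "imputed_from"] == "near"


def test_impute_noop_without_low_coverage():
    genes = [_gene("a", "s1", 0, 1_000), _gene("b", "s1", 2_000, 3_000)]
    tab = pd.DataFrame(
        {
            "cr": [1.0, 1.2],
            "low_coverage": [False, False],
            "imputed_from": pd.Series([pd.NA] * 2, dtype="object"),
        },
        index=["a", "b"],
    )
    out = kn.impute_low_coverage(tab, genes)
    pd.testing.assert_frame_equal(out, tab)


def test_impute_sole_gene_stays_undefined():
    genes = [_gene("solo", "s9", 0, 1_000), _gene("other", "s1", 0, 1_000)]
    tab = pd.DataFrame(
        {
            "cr": [np.nan, 1.5],
            "low_coverage": [True, False],
            "imputed_from": pd.Series([pd.NA] * 2, dtype="object"),
        },
        index=["solo", "other"],
    )
    out = kn.impute_low_coverage(tab, genes)
    assert np.isnan(out.loc["solo", "cr"])
    assert pd.isna(out.loc["solo", "imputed_from"])


def test_pipeline_imputes_from_same_scaffold():
    # capture efficiency low enough that low-coverage genes trip the flag
    # even at this small (hence deep-per-gene) design
    cfg = kn.SimConfig(
        n_genes={"S": 100, "L1": 100, "L2": 100},
        low_coverage_efficiency=5e-4,
        seed=7,
    )
    genes, truth, wgs, rna = kn.simulate_dataset(cfg)
    res = kn.run_pipeline(genes, wgs, rna, contrast=("DV1_8", "DV1_10"), run_scan=False)
    low = truth.index[truth.is_low_coverage]
    imputed = res.ratio_table.loc[low, "imputed_from"].dropna()
    assert len(imputed) > 0
    scaffold = truth["scaffold"]
    for gene, donor in imputed.items():
        assert scaffold[gene] == scaffold[donor]


# ---------------------------------------------------------- dosage matrix


def test_dosage_matrix_noise_free_row_ratios(noise_free):
    """S rows contrast 2:1 (ratio 0.5 for the aneuploid), L rows 1:1."""
    wgs, rna, truth = noise_free["wgs"], noise_free["rna"], noise_free["truth"]
    covered = ~truth.is_low_coverage
    l = truth.index[(truth.subgenome != "S") & covered]
    anchored = kn.normalize_wgs(wgs, kn.MODE_L_ANCHORED, anchor_genes=l)
    dm = kn.build_dosage_matrix(anchored, rna.libraries)
    w = dm.values
    lib8 = rna.libraries_of("DV1_8")[0]
    lib10 = rna.libraries_of("DV1_10")[0]
    ratio = w[lib10] / w[lib8]
    s = truth.index[(truth.subgenome == "S") & covered]
    assert ratio[s].median() == pytest.approx(0.5, rel=1e-2)
    assert ratio[l].median() == pytest.approx(1.0, rel=1e-2)
    # contract: rows centred to geometric mean one, constant within subline
    geomean = np.exp(np.log(w).mean(axis=1))
    np.testing.assert_allclose(geomean, 1.0, rtol=1e-9)
    for subline in ("DV1_8", "DV1_10"):
        libs = list(rna.libraries_of(subline))
        np.testing.assert_allclose(w[libs].std(axis=1), 0.0, atol=1e-12)


def test_dosage_matrix_collapse_invariant(noise_free):
    """Collapse-artifact genes get the same centred row as clean genes of their subgenome."""
    wgs, rna, truth = noise_free["wgs"], noise_free["rna"], noise_free["truth"]
    covered = ~truth.is_low_coverage
    l = truth.index[(truth.subgenome != "S") & covered]
    dm = kn.build_dosage_matrix(
        kn.normalize_wgs(wgs, kn.MODE_L_ANCHORED, anchor_genes=l), rna.libraries
    )
    coll = truth.index[(truth.collapse_factor > 1) & (truth.subgenome == "S") & covered]
    clean = truth.index[(truth.collapse_factor == 1) & (truth.subgenome == "S") & covered]
    if len(coll) == 0:
        pytest.skip("no collapsed S genes at this size")
    np.testing.assert_allclose(
        dm.values.loc[coll].median(axis=0),
        dm.values.loc[clean].median(axis=0),
        rtol=1e-2,
    )


def test_dosage_matrix_single_subline_is_neutral(noise_free):
    wgs, truth = noise_free["wgs"], noise_free["truth"]
    only8 = wgs.subset_libraries(wgs.libraries_of("DV1_8"))
    l = truth.index[(truth.subgenome != "S") & ~truth.is_low_coverage]
    anchored = kn.normalize_wgs(only8, kn.MODE_L_ANCHORED, anchor_genes=l)
    rna_libs = library_table(["r1", "r2"], ["DV1_8", "DV1_8"], "RNA", [1, 2])
    dm = kn.build_dosage_matrix(anchored, rna_libs)
    np.testing.assert_allclose(dm.values.to_numpy(), 1.0, rtol=1e-9)


def test_dosage_matrix_rejects_unknown_subline(noise_free):
    wgs, truth = noise_free["wgs"], noise_free["truth"]
    l = truth.index[(truth.subgenome != "S") & ~truth.is_low_coverage]
    anchored = kn.normalize_wgs(wgs, kn.MODE_L_ANCHORED, anchor_genes=l)
    rna_libs = library_table(["r1"], ["DV1_99"], "RNA", [1])
    with pytest.raises(kn.InputError):
        kn.build_dosage_matrix(anchored, rna_libs)


def test_l_anchored_requires_anchors(small_dataset):
    with pytest.raises(kn.NormalizationError):
        kn.normalize_wgs(small_dataset["wgs"], kn.MODE_L_ANCHORED, anchor_genes=[])
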