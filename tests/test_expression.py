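"""Normalization, expressed filter, DEG calling and set algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest

from promusage.expression import (
    call_degs,
    deg_set_algebra,
    expressed_filter,
    normalize_expression,
    size_factors_median_of_ratios,
)
from promusage.simulate import simulate_count_matrix


def _df(rows, samples):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))], columns=samples)


# ---------------------------------------------------------------------------
# size factors

def test_size_factors_pure_depth_difference():
    a = np.array([10, 50, 200, 7, 90])
    m = _df(np.column_stack([a, 2 * a]), ["s1", "s2"])
    sf = size_factors_median_of_ratios(m)
    assert sf["s2"] / sf["s1"] == pytest.approx(2.0)


def test_size_factors_identical_columns():
    a = np.array([10, 50, 200, 7, 90])
    m = _df(np.column_stack([a, a, a]), ["s1", "s2", "s3"])
    assert size_factors_median_of_ratios(m).nunique() == 1


def _manual_median_of_ratios(m):
    """Independent step-by-step evaluation of the formula."""
    x = m.to_numpy(float)
    out = []
    for j in range(x.shape[1]):
        ratios = []
        for g in range(x.shape[0]):
            geo = np.prod(x[g]) ** (1 / x.shape[1])
            if geo > 0:
                ratios.append(x[g, j] / geo)
        out.append(float(np.median(ratios)))
    return np.array(out)


@pytest.mark.parametrize(
    "rows,expected,rel",
    [
        # frozen from Bioconductor DESeq2 estimateSizeFactors on the same
        # matrices; the second matrix has an even number of usable genes, where
        # DESeq2 averages the two middle ratios geometrically while the
        # ratio-space median averages them arithmetically, hence the loose rel
        ([[100, 200, 50], [120, 180, 60], [30, 45, 15], [500, 1000, 250], [80, 160, 40]],
         [1.0, 2.0, 0.5], 1e-8),
        ([[13, 7, 52], [101, 220, 86], [0, 4, 19], [640, 310, 990], [55, 48, 61]],
         [0.9070808263, 0.6859351024, 1.3818601009], 5e-2),
    ],
)
def test_size_factors_match_deseq2_and_manual_formula(rows, expected, rel):
    m = _df(np.array(rows), ["s1", "s2", "s3"])
    sf = size_factors_median_of_ratios(m)
    assert sf.to_numpy() == pytest.approx(np.array(expected), rel=rel)
    assert sf.to_numpy() == pytest.approx(_manual_median_of_ratios(m), rel=1e-12)


def test_size_factors_random_matrix_vs_manual(rng):
    m = _df(rng.integers(0, 400, size=(20, 5)), list("abcde"))
    sf = size_factors_median_of_ratios(m)
    assert sf.to_numpy() == pytest.approx(_manual_median_of_ratios(m), rel=1e-12)


def test_size_factors_scale_equivariance(rng):
    """Scaling one column by k scales its factor relative to the others by k
    (factors are defined only up to a common scale)."""
    m = _df(rng.integers(1, 400, size=(21, 3)), ["s1", "s2", "s3"])
    sf = size_factors_median_of_ratios(m)
    m2 = m.copy()
    m2["s2"] = m2["s2"] * 3
    sf2 = size_factors_median_of_ratios(m2)
    assert sf2["s2"] / sf2["s1"] == pytest.approx(3 * sf["s2"] / sf["s1"])
    assert sf2["s3"] / sf2["s1"] == pytest.approx(sf["s3"] / sf["s1"])


def test_size_factors_all_zero_gene_row_error():
    m = _df([[0, 5], [3, 0]], ["s1", "s2"])
    with pytest.raises(ValueError, match="size factors undefined"):
        size_factors_median_of_ratios(m)


# ---------------------------------------------------------------------------
# FPKM / TPM

def test_fpkm_definition():
    m = _df([[10], [999_990]], ["s1"])  # 1e6 mapped total
    lengths = pd.Series({"g0": 2000, "g1": 1000})
    fpkm = normalize_expression(m, lengths, "FPKM")
    assert fpkm.loc["g0", "s1"] == pytest.approx(5.0)


def test_tpm_columns_sum_to_million(rng):
    m = _df(rng.integers(0, 1000, size=(50, 4)), list("wxyz"))
    lengths = pd.Series(rng.integers(200, 5000, 50), index=m.index)
    tpm = normalize_expression(m, lengths, "TPM")
    assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)


def test_tpm_is_column_renormalized_fpkm(rng):
    m = _df(rng.integers(0, 1000, size=(40, 3)), list("abc"))
    lengths = pd.Series(rng.integers(200, 5000, 40), index=m.index)
    fpkm = normalize_expression(m, lengths, "FPKM")
    tpm = normalize_expression(m, lengths, "TPM")
    expected = fpkm / fpkm.sum(axis=0) * 1e6
    assert np.allclose(tpm, expected, rtol=1e-10)


def test_normalize_zero_column_error():
    m = _df([[0, 5], [0, 3]], ["s1", "s2"])
    with pytest.raises(ValueError, match="s1"):
        normalize_expression(m, pd.Series({"g0": 100, "g1": 100}), "TPM")


# ---------------------------------------------------------------------------
# expressed filter

def test_expressed_filter_rules():
    m = _df([[0, 0], [4, 0], [3, 3]], ["s1", "s2"])
    sf = pd.Series({"s1": 1.0, "s2": 1.0})
    kept = expressed_filter(m, sf, threshold=3)
    assert kept == {"g1"}  # all-zero excluded; 3 is not > 3; 4 passes


def test_expressed_filter_at_least_one_rule():
    m = _df([[3.5, 0, 0]], ["s1", "s2", "s3"]).astype(float)
    sf = pd.Series({"s1": 1.0, "s2": 1.0, "s3": 1.0})
    assert expressed_filter(m, sf, threshold=3) == {"g0"}


def test_expressed_filter_threshold_zero_is_nonzero_genes(rng):
    m = _df(rng.integers(0, 3, size=(30, 4)), list("abcd"))
    sf = pd.Series(1.0, index=m.columns)
    assert expressed_filter(m, sf, threshold=0) == set(m.index[(m > 0).any(axis=1)])


def test_expressed_filter_planted_fixture_exhaustive(rng):
    """20-gene fixture with normalized values straddling 3: membership equals
    an exhaustive per-entry scan."""
    m = _df(rng.integers(0, 12, size=(20, 3)), ["s1", "s2", "s3"])
    sf = pd.Series({"s1": 0.8, "s2": 1.0, "s3": 2.5})
    got = expressed_filter(m, sf, threshold=3)
    expected = {
        g
        for g in m.index
        if any(m.loc[g, s] / sf[s] > 3 for s in m.columns)
    }
    assert got == expected


# ---------------------------------------------------------------------------
# DEG calling

def test_call_degs_identical_groups_null():
    m = _df([[10, 12, 11, 10, 12, 11], [200, 210, 190, 200, 210, 190]], list("abcdef"))
    sf = pd.Series(1.0, index=m.columns)
    res = call_degs(m, sf, ["a", "b", "c"], ["d", "e", "f"])
    assert np.allclose(res["log2_fold_change"], 0)
    assert not res["is_deg"].any()


def test_call_degs_pseudocount_arithmetic():
    # group means 2 and 8 normalized: log2FC exactly log2(9/3) with pseudocount 1
    m = _df([[2, 2, 2, 8, 8, 8]], list("abcdef"))
    sf = pd.Series(1.0, index=m.columns)
    res = call_degs(m, sf, ["a", "b", "c"], ["d", "e", "f"])
    assert res["log2_fold_change"].iloc[0] == pytest.approx(np.log2(9 / 3))
    assert abs(res["log2_fold_change"].iloc[0] - 2.0) < 0.5  # pseudocount shrinkage


def test_call_degs_label_symmetry(rng):
    sim = simulate_count_matrix(n_genes=150, seed=3)
    sf = pd.Series(1.0, index=sim.counts.columns)
    ab = call_degs(sim.counts, sf, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
    ba = call_degs(sim.counts, sf, ["B1", "B2", "B3"], ["A1", "A2", "A3"])
    assert np.allclose(ab["log2_fold_change"], -ba["log2_fold_change"])
    assert np.allclose(ab["p_value"], ba["p_value"])


def test_call_degs_recovers_planted_effects():
    sim = simulate_count_matrix(
        n_genes=600, frac_de=0.1, effect_log2fc=2.0, nb_dispersion=0.05, seed=17
    )
    sf = size_factors_median_of_ratios(sim.counts)
    res = call_degs(sim.counts, sf, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
    truth = sim.truth["is_de"]
    sens = (res["is_deg"] & truth).sum() / truth.sum()
    fpr = (res["is_deg"] & ~truth).sum() / (~truth).sum()
    assert sens > 0.7
    assert fpr < 0.10


def test_call_degs_needs_replicates():
    m = _df([[1, 2, 3]], list("abc"))
    sf = pd.Series(1.0, index=m.columns)
    with pytest.raises(ValueError, match="group_b"):
        call_degs(m, sf, ["a", "b"], ["c"])


# ---------------------------------------------------------------------------
# set algebra

def test_set_algebra_enumerable_case():
    res = deg_set_algebra({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
    row = res.pairwise.iloc[0]
    assert row["shared"] == 2 and row["union"] == 4
    assert row["shared_pct_of_union"] == pytest.approx(50.0)
    assert row["shared_pct_of_total"] == pytest.approx(100 * 2 / 6)


def test_set_algebra_disjoint():
    res = deg_set_algebra({"x": {"a"}, "y": {"b"}})
    assert res.pairwise["shared"].iloc[0] == 0
    assert res.global_intersection == 0 and res.global_union == 2


def test_set_algebra_matches_brute_force(rng):
    universe = [f"g{i}" for i in range(60)]
    sets = {
        name: set(rng.choice(universe, size=int(rng.integers(5, 40)), replace=False))
        for name in "abcd"
    }
    res = deg_set_algebra(sets)
    for _, row in res.pairwise.iterrows():
        sa, sb = sets[row["set_a"]], sets[row["set_b"]]
        shared = sum(1 for g in universe if g in sa and g in sb)
        union = sum(1 for g in universe if g in sa or g in sb)
        assert row["shared"] == shared and row["union"] == union
    assert res.global_union == sum(
        1 for g in universe if any(g in s for s in sets.values())
    )
    assert res.global_intersection == sum(
        1 for g in universe if all(g in s for s in sets.values())
    )
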