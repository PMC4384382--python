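"""NB Wald test, dispersion estimation, BH correction, DE counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cd4atlas as ca
from cd4atlas.differential_expression import (
    DETable,
    bh_adjust,
    count_de,
    estimate_dispersion,
    nb_wald_test,
    pairwise_de,
)
from cd4atlas.errors import ConfigError, ValidationError
from cd4atlas.evaluation import brute_force_bh, null_type1_error, planted_de_power

from conftest import make_counts


# ---------------------------------------------------------------------------
# dispersion

def test_equal_replicates_hit_dispersion_floor():
    assert estimate_dispersion([5, 5], [9, 9], [1, 1], [1, 1]) == 1e-8


def test_hand_computed_moment_dispersion():
    # within-group variances both 200, pooled mean 150 -> (200-150)/150^2
    alpha = estimate_dispersion([90, 110], [190, 210], [1, 1], [1, 1])
    assert np.isclose(alpha, 50 / 150**2, rtol=1e-12)


def test_dispersion_recovery_monte_carlo():
    rng = np.random.default_rng(8)
    true_alpha, n_genes = 0.1, 1000
    mu = rng.uniform(50, 500, n_genes)
    size = 1 / true_alpha
    estimates = []
    for m in mu:
        counts = rng.negative_binomial(size, size / (size + m), 4)
        estimates.append(estimate_dispersion(counts[:2], counts[2:], [1, 1], [1, 1]))
    med = np.median(estimates)
    assert true_alpha / 3 <= med <= true_alpha * 3


def test_all_zero_gene_is_untestable():
    assert np.isnan(estimate_dispersion([0, 0], [0, 0], [1, 1], [1, 1]))


# ---------------------------------------------------------------------------
# Wald test

def test_null_identity():
    res = nb_wald_test([10, 12], [10, 12], [1, 1], [1, 1], 0.01)
    assert res["log2fc"][0] == 0.0
    assert res["wald"][0] == 0.0
    assert res["p"][0] == 1.0


def test_group_swap_antisymmetry(rng):
    for _ in range(20):
        a = rng.poisson(rng.uniform(1, 100), 2)
        b = rng.poisson(rng.uniform(1, 100), 2)
        if a.sum() == 0 and b.sum() == 0:
            continue
        fwd = nb_wald_test(a, b, [1, 1], [1, 1], 0.05)
        rev = nb_wald_test(b, a, [1, 1], [1, 1], 0.05)
        assert np.isclose(fwd["log2fc"][0], -rev["log2fc"][0])
        assert np.isclose(fwd["wald"][0], -rev["wald"][0], equal_nan=True)
        assert np.isclose(fwd["p"][0], rev["p"][0], equal_nan=True)


def test_ne_in_both_groups_gives_nan_p():
    res = nb_wald_test([0, 0], [0, 0], [1, 1], [1, 1], 0.05)
    assert np.isnan(res["p"][0])


def test_null_type1_error_in_band():
    rate, n_tested = null_type1_error(seed=11)
    assert n_tested > 4000
    assert 0.03 <= rate <= 0.08


def test_power_monotone_in_effect_size():
    powers = [planted_de_power(seed=19, log2fc=fc) for fc in (1.0, 2.0, 3.0)]
    assert powers[0] <= powers[1] <= powers[2]
    assert powers[2] > powers[0]
    assert powers[2] >= 0.8  # planted recall at the study effect size


def test_empirical_fdr_on_planted_atlas(atlas):
    fdr, calls = ca.evaluation.de_truth_fdr(
        atlas["counts"], atlas["samples"], atlas["sf"], atlas["truth"]
    )
    assert calls > 1000
    assert fdr <= 0.05


# ---------------------------------------------------------------------------
# BH

def test_single_pvalue_unchanged():
    assert bh_adjust([0.03])[0] == 0.03


def test_hand_stepup_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.1]), [0.03, 0.03, 0.1])


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.5])


def test_bh_passes_nan_through():
    out = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(out[1])
    assert np.allclose(out[[0, 2]], brute_force_bh([0.01, 0.5]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
def test_bh_matches_brute_force_and_statsmodels(pvals):
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals)
    ours = bh_adjust(p)
    assert np.allclose(ours, brute_force_bh(p), atol=1e-12)
    sm = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, sm, atol=1e-10)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30))
def test_bh_is_monotone_and_at_least_p(pvals):
    p = np.asarray(pvals)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-15)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# pairwise tables and counts

def test_six_subtypes_give_fifteen_pairs(atlas):
    assert len(atlas["table"].pairs) == 15


def test_single_replicate_subtype_rejected():
    counts = make_counts([[5, 6, 7]], samples=["a1", "a2", "b1"])
    samples = pd.DataFrame(
        {"sample_id": ["a1", "a2", "b1"], "subtype": ["A", "A", "B"], "replicate": [1, 2, 1]}
    )
    with pytest.raises(ConfigError):
        pairwise_de(counts, samples, pd.Series([1.0, 1.0, 1.0], index=counts.columns))


def test_planted_su_recall(atlas):
    """Planted SU genes reach padj <= 0.01 in their pairs with recall >= 0.8."""
    truth, table = atlas["truth"], atlas["table"]
    hits = total = 0
    for t, planted in truth.planted_su.items():
        for other in truth.subtypes:
            if other == t:
                continue
            frame = table.get(other, t)
            for g in planted:
                total += 1
                padj = frame["padj"].get(g, np.nan)
                hits += int(np.isfinite(padj) and padj <= 0.01 and frame.loc[g, "log2fc"] > 0)
    assert hits / total >= 0.8


def toy_table():
    frame = pd.DataFrame(
        {
            "log2fc": [0.5, 1.5, -3.0, 4.0, 0.0],
            "se": [0.1] * 5,
            "wald": [1.0] * 5,
            "p": [0.001, 0.002, 0.001, 0.001, 0.9],
            "padj": [0.005, 0.008, 0.002, 0.009, 0.95],
        },
        index=[f"g{i}" for i in range(5)],
    )
    return DETable(pairs={("A", "B"): frame})


def test_count_de_hand_tally():
    counts = count_de(toy_table())
    by_cutoff = counts.set_index("cutoff")["n"]
    # padj <= 0.01: g0..g3; |lfc| >= 1: g1,g2,g3; |lfc| >= log2(5): g2,g3
    assert by_cutoff[0.0] == 4
    assert by_cutoff[2.0] == 3
    assert by_cutoff[5.0] == 2


def test_count_de_nested_and_empty(atlas):
    counts = count_de(atlas["table"])
    for _, grp in counts.groupby("pair"):
        n = grp.sort_values("cutoff")["n"].to_numpy()
        assert np.all(np.diff(n) <= 0)
    empty = DETable(pairs={("A", "B"): toy_table().pairs[("A", "B")].assign(padj=1.0)})
    assert (count_de(empty)["n"] == 0).all()


def test_pair_orientation_flip(atlas):
    table = atlas["table"]
    (a, b) = next(iter(table.pairs))
    fwd = table.get(a, b)
    rev = table.get(b, a)
    assert np.allclose(fwd["log2fc"], -rev["log2fc"], equal_nan=True)
    assert np.allclose(fwd["p"], rev["p"], equal_nan=True)
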