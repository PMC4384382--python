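"""Generator tests: determinism, planted-effect recoverability, round trips."""

import numpy as np
import pandas as pd
import pytest

import cd4atlas as ca
from cd4atlas import io
from cd4atlas.errors import ConfigError, ConsistencyError
from cd4atlas.isoforms import subtype_major_isoforms


def test_seed_determinism_bitwise():
    config = ca.SimConfig(n_genes=120, su_per_subtype=3, n_switch_genes=4, seed=9)
    a = ca.generate_all(config)
    b = ca.generate_all(config)
    pd.testing.assert_frame_equal(a[0], b[0])  # counts
    pd.testing.assert_frame_equal(a[3], b[3])  # catalog
    pd.testing.assert_frame_equal(a[4].classes, b[4].classes)
    pd.testing.assert_frame_equal(a[5].base_means, b[5].base_means)
    assert a[5].planted_switches == b[5].planted_switches


def test_different_seeds_differ():
    base = dict(n_genes=120, su_per_subtype=3, n_switch_genes=4)
    a, *_ = ca.generate_atlas(ca.SimConfig(seed=1, **base))
    b, *_ = ca.generate_atlas(ca.SimConfig(seed=2, **base))
    assert not a.equals(b)


def test_no_planted_effect_gives_equal_subtype_means():
    """With dispersion 0, equal depths and no SU effect, per-gene subtype
    means agree within Poisson sampling error."""
    config = ca.SimConfig(
        n_genes=2000,
        su_log2fc=0.0,
        dispersion=0.0,
        depth_factors=(1.0,) * 12,
        frac_multi_isoform=0.0,
        n_switch_genes=0,
        seed=21,
    )
    counts, samples, genes, truth = ca.generate_atlas(config)
    # z-score of the between-subtype difference under Poisson noise
    first = counts[[f"{t}_r{r}" for t in ("Naive", "Th1") for r in (1, 2)]]
    m_a = first.iloc[:, :2].mean(axis=1)
    m_b = first.iloc[:, 2:].mean(axis=1)
    mu = truth.base_means["Naive"] * genes["length_bp"] / 1000.0
    keep = mu > 5
    z = (m_a - m_b)[keep] / np.sqrt(mu[keep])  # Var(mean of 2) = mu/2, diff = mu
    assert abs(z.mean()) < 0.05
    assert (np.abs(z) > 5).mean() < 0.001


def test_planted_su_genes_have_highest_subtype_mean(atlas):
    """For >= 95% of planted SU genes the empirical mean normalized count is
    highest in the planted subtype."""
    truth, expr, samples = atlas["truth"], atlas["expr"], atlas["samples"]
    by_subtype = {
        t: expr[list(g["sample_id"])].mean(axis=1)
        for t, g in samples.groupby("subtype", sort=False)
    }
    means = pd.DataFrame(by_subtype)
    wins = total = 0
    for t, planted in truth.planted_su.items():
        for g in planted:
            total += 1
            row = means.loc[g]
            wins += int(row[t] == row.max() and (row.drop(t) < row[t]).all())
    assert wins / total >= 0.95


def test_su_sets_pairwise_disjoint(atlas):
    truth = atlas["truth"]
    seen = set()
    for genes in truth.planted_su.values():
        assert not (seen & set(genes))
        seen |= set(genes)


def test_planted_psi_sums_to_one(atlas):
    for by_subtype in atlas["truth"].planted_psi.values():
        for psi in by_subtype.values():
            assert abs(sum(psi) - 1.0) < 1e-9


def test_counts_are_nonnegative_integers(small_atlas):
    vals = small_atlas["counts"].to_numpy()
    assert np.issubdtype(vals.dtype, np.integer)
    assert (vals >= 0).all()


def test_unambiguous_read_split_matches_psi_and_length():
    """With ambiguity 0, per-isoform read fractions follow psi*length."""
    config = ca.SimConfig(
        n_genes=60, su_per_subtype=0, n_switch_genes=0, ambiguity_rate=0.0,
        reads_per_gene=2000, seed=13,
    )
    counts, samples, genes, catalog, compat, truth = ca.generate_all(config)
    assert all(len(c) == 1 for c in compat.classes["isoform_ids"])
    lengths = dict(zip(catalog["isoform_id"], catalog["length_bp"]))
    iso_by_gene = {g: list(s["isoform_id"]) for g, s in catalog.groupby("gene_id")}
    sample, subtype = "Naive_r1", "Naive"
    checked = 0
    for g, isos in iso_by_gene.items():
        psi = np.asarray(truth.planted_psi[g][subtype])
        p = psi * np.array([lengths[i] for i in isos])
        p = p / p.sum()
        sub = compat.classes[
            (compat.classes["sample_id"] == sample) & (compat.classes["gene_id"] == g)
        ].set_index("isoform_ids")["n_reads"]
        obs = np.array([sub.get((i,), 0) for i in isos], dtype=float)
        n = obs.sum()
        if n < 500:
            continue
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(obs - n * p) <= 4 * sigma + 1)
        checked += 1
    assert checked > 5


def test_switch_genes_flip_estimated_major_isoform(atlas, atlas_psi):
    """Each planted switch gene's replicate-level top-PSI isoform differs
    between the flipped subtype and the others, in every replicate."""
    truth = atlas["truth"]
    sp = atlas_psi.sample_psi
    subtype_of = dict(zip(atlas["samples"]["sample_id"], atlas["samples"]["subtype"]))
    idx = sp.set_index(["sample_id", "gene_id", "isoform_id"])["psi"]
    flips = 0
    for gene, (a, b) in truth.planted_switches:
        tops = {}
        for sample, subtype in subtype_of.items():
            if subtype in (a, b):
                sub = sp[(sp.sample_id == sample) & (sp.gene_id == gene)]
                tops.setdefault(subtype, set()).add(sub.loc[sub.psi.idxmax(), "isoform_id"])
        if len(tops[a]) == 1 and len(tops[b]) == 1 and tops[a] != tops[b]:
            flips += 1
    assert flips / len(truth.planted_switches) >= 0.95


def test_no_switches_means_consistent_majors():
    config = ca.SimConfig(
        n_genes=80, su_per_subtype=0, n_switch_genes=0, reads_per_gene=2000,
        ambiguity_rate=0.2, seed=17,
    )
    counts, samples, genes, catalog, compat, truth = ca.generate_all(config)
    psi = ca.estimate_psi_table(compat, catalog, samples)
    majors = subtype_major_isoforms(psi)
    by_gene = {}
    for (subtype, gene), major in majors.items():
        by_gene.setdefault(gene, set()).add(major)
    assert by_gene, "expected multi-isoform genes"
    for gene, major_set in by_gene.items():
        assert len(major_set - {None}) <= 1


def test_switch_gene_counts_do_not_depend_on_psi_orientation(atlas):
    """Planted switch genes keep constant expected expression: they are
    drawn from non-SU genes, so base means are equal across subtypes."""
    truth = atlas["truth"]
    switch_genes = {g for g, _ in truth.planted_switches}
    bm = truth.base_means.loc[sorted(switch_genes)]
    assert np.allclose(bm.to_numpy(), bm.to_numpy()[:, [0]])


def test_fixture_round_trip(tmp_path, small_atlas):
    files = io.write_fixture(
        tmp_path,
        small_atlas["counts"],
        small_atlas["samples"],
        small_atlas["genes"],
        small_atlas["truth"],
        small_atlas["catalog"],
        small_atlas["compat"],
    )
    assert set(files) == {"counts", "samples", "genes", "isoforms", "compat", "truth"}
    counts = io.read_counts(files["counts"])
    pd.testing.assert_frame_equal(counts, small_atlas["counts"], check_names=False)
    samples = io.read_samples(files["samples"])
    pd.testing.assert_frame_equal(samples, small_atlas["samples"])
    genes = io.read_genes(files["genes"])
    pd.testing.assert_frame_equal(genes, small_atlas["genes"], check_names=False)
    catalog = io.read_isoforms(files["isoforms"])
    pd.testing.assert_frame_equal(catalog, small_atlas["catalog"])
    compat = io.read_compat(files["compat"], catalog)
    left = (
        compat.classes.sort_values(["sample_id", "gene_id", "isoform_ids"])
        .reset_index(drop=True)
    )
    right = (
        small_atlas["compat"].classes
        .sort_values(["sample_id", "gene_id", "isoform_ids"])
        .reset_index(drop=True)
    )
    pd.testing.assert_frame_equal(
        left[["sample_id", "gene_id", "isoform_ids", "n_reads"]].astype({"n_reads": int}),
        right.astype({"n_reads": int}),
    )
    truth = io.read_truth(files["truth"])
    assert truth.planted_su == small_atlas["truth"].planted_su
    assert truth.planted_switches == small_atlas["truth"].planted_switches
    pd.testing.assert_frame_equal(truth.base_means, small_atlas["truth"].base_means)


def test_empty_gene_set_writes_header_only_files(tmp_path):
    config = ca.SimConfig(
        n_genes=0, su_per_subtype=0, n_switch_genes=0, frac_multi_isoform=0.0, seed=1
    )
    counts, samples, genes, truth = ca.generate_atlas(config)
    files = io.write_fixture(tmp_path, counts, samples, genes, truth)
    assert io.read_counts(files["counts"]).empty
    assert len(io.read_samples(files["samples"])) == 12
    assert io.read_genes(files["genes"]).empty


@pytest.mark.parametrize(
    "kwargs, field",
    [
        (dict(he_weight=1.5), "he_weight"),
        (dict(dispersion=-0.1), "dispersion"),
        (dict(su_per_subtype=400, n_genes=100), "su_per_subtype"),
        (
            dict(n_switch_genes=50, n_genes=100, su_per_subtype=0, frac_multi_isoform=0.1),
            "n_switch_genes",
        ),
        (dict(depth_factors=(1.0,) * 3), "depth_factors"),
        (dict(ambiguity_rate=1.5), "ambiguity_rate"),
    ],
)
def test_invalid_config_names_field(kwargs, field):
    with pytest.raises(ConfigError, match=field):
        ca.generate_atlas(ca.SimConfig(**kwargs))


def test_truth_config_mismatch_raises(small_atlas):
    other = ca.SimConfig(n_genes=50, su_per_subtype=0, n_switch_genes=0, seed=2)
    with pytest.raises(ConsistencyError):
        ca.generate_isoform_data(other, small_atlas["truth"])


def test_gene_lengths_in_documented_range(small_atlas):
    lengths = small_atlas["genes"]["length_bp"]
    assert lengths.between(500, 10000).all()


def test_ambiguous_reads_touch_exactly_two_isoforms(small_atlas):
    sizes = small_atlas["compat"].classes["isoform_ids"].map(len)
    assert set(sizes.unique()) <= {1, 2}
    assert (sizes == 2).any()
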