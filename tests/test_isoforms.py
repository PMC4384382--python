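"""PSI EM, major isoforms, switch detection, grouped PSI."""

import numpy as np
import pandas as pd
import pytest

import cd4atlas as ca
from cd4atlas.differential_expression import DETable
from cd4atlas.errors import DataError, ValidationError
from cd4atlas.isoforms import (
    PSITable,
    detect_switches,
    estimate_psi,
    group_psi,
    major_isoform,
    switch_fold_change,
)


def test_equal_length_closed_form():
    psi = estimate_psi([(("i1",), 30), (("i2",), 70)], ["i1", "i2"], [1000, 1000])
    assert np.allclose(psi, [0.3, 0.7], atol=1e-8)


def test_length_corrected_closed_form():
    psi = estimate_psi([(("i1",), 30), (("i2",), 70)], ["i1", "i2"], [1000, 2000])
    assert np.allclose(psi, [6 / 13, 7 / 13], atol=1e-8)


def test_unambiguous_converges_in_one_step():
    psi, trace = estimate_psi(
        [(("i1",), 30), (("i2",), 70)], ["i1", "i2"], [1000, 2000], return_trace=True
    )
    # the first M-step already lands on the closed form
    assert len(trace) <= 3


def test_fully_ambiguous_equal_lengths_stays_uniform():
    psi = estimate_psi([(("i1", "i2", "i3"), 90)], ["i1", "i2", "i3"], [500, 500, 500])
    assert np.allclose(psi, 1 / 3, atol=1e-12)


def test_likelihood_non_decreasing_with_ambiguity(rng):
    for _ in range(10):
        k = int(rng.integers(2, 5))
        ids = [f"i{j}" for j in range(k)]
        lengths = rng.uniform(500, 5000, k)
        classes = [((ids[j],), int(rng.integers(1, 100))) for j in range(k)]
        classes += [
            (tuple(sorted(rng.choice(ids, 2, replace=False))), int(rng.integers(1, 60)))
            for _ in range(3)
        ]
        _, trace = estimate_psi(classes, ids, lengths, return_trace=True)
        assert np.all(np.diff(trace) >= -1e-9)


def test_psi_sums_to_one_on_atlas(atlas_psi):
    sums = atlas_psi.sample_psi.groupby(["sample_id", "gene_id"])["psi"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_unknown_isoform_in_class_raises():
    with pytest.raises(DataError, match="iX"):
        estimate_psi([(("iX",), 5)], ["i1"], [1000])


def test_no_reads_raises():
    with pytest.raises(DataError):
        estimate_psi([], ["i1"], [1000])


def make_psi_table(rep_psi):
    """rep_psi: {sample: {(gene, isoform): psi}} over subtype A with 2 reps."""
    rows = [
        (sample, gene, iso, value)
        for sample, entries in rep_psi.items()
        for (gene, iso), value in entries.items()
    ]
    samples = pd.DataFrame(
        {
            "sample_id": sorted(rep_psi),
            "subtype": ["A"] * len(rep_psi),
            "replicate": list(range(1, len(rep_psi) + 1)),
        }
    )
    return PSITable(
        sample_psi=pd.DataFrame(rows, columns=["sample_id", "gene_id", "isoform_id", "psi"]),
        samples=samples,
    )


def test_major_isoform_agreement():
    table = make_psi_table(
        {
            "a1": {("g", "i1"): 0.7, ("g", "i2"): 0.3},
            "a2": {("g", "i1"): 0.6, ("g", "i2"): 0.4},
        }
    )
    assert major_isoform(table, "A", "g") == "i1"


def test_major_isoform_disagreement_undefined():
    table = make_psi_table(
        {
            "a1": {("g", "i1"): 0.7, ("g", "i2"): 0.3},
            "a2": {("g", "i1"): 0.4, ("g", "i2"): 0.6},
        }
    )
    assert major_isoform(table, "A", "g") is None


def test_major_isoform_tie_undefined():
    table = make_psi_table(
        {
            "a1": {("g", "i1"): 0.5, ("g", "i2"): 0.5},
            "a2": {("g", "i1"): 0.6, ("g", "i2"): 0.4},
        }
    )
    assert major_isoform(table, "A", "g") is None


def test_switch_fold_change_planted_configuration():
    fold, flagged = switch_fold_change([0.8, 0.2], [0.2, 0.8], 0, 1)
    assert fold == 4.0
    assert not flagged


def test_switch_fold_change_mixed_example():
    fold, _ = switch_fold_change([0.6, 0.4], [0.45, 0.55], 0, 1)
    assert np.isclose(fold, 0.55 / 0.45)


def test_switch_fold_symmetric_psi():
    fold_ab, _ = switch_fold_change([0.7, 0.3], [0.3, 0.7], 0, 1)
    fold_ba, _ = switch_fold_change([0.3, 0.7], [0.7, 0.3], 1, 0)
    assert np.isclose(fold_ab, fold_ba)


def test_switch_fold_zero_denominator_flagged():
    fold, flagged = switch_fold_change([1.0, 0.0], [0.0, 1.0], 0, 1)
    assert np.isinf(fold)
    assert flagged


def test_switch_fold_requires_different_majors():
    with pytest.raises(ValidationError):
        switch_fold_change([0.6, 0.4], [0.7, 0.3], 0, 0)


def switch_scenario(padj=0.5, class_a="HE", class_b="HE"):
    """Two subtypes, one gene with a clean planted switch."""
    rows = []
    for sample, top in [("a1", 0.8), ("a2", 0.8), ("b1", 0.2), ("b2", 0.2)]:
        rows += [(sample, "g", "i1", top), (sample, "g", "i2", 1 - top)]
    samples = pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "b2"],
            "subtype": ["A", "A", "B", "B"],
            "replicate": [1, 2, 1, 2],
        }
    )
    psi = PSITable(
        sample_psi=pd.DataFrame(rows, columns=["sample_id", "gene_id", "isoform_id", "psi"]),
        samples=samples,
    )
    frame = pd.DataFrame(
        {"log2fc": [0.1], "se": [0.1], "wald": [1.0], "p": [padj], "padj": [padj]},
        index=["g"],
    )
    table = DETable(pairs={("A", "B"): frame})
    classes = pd.DataFrame({"A": [class_a], "B": [class_b]}, index=["g"])
    catalog = pd.DataFrame(
        {
            "gene_id": ["g", "g"],
            "isoform_id": ["i1", "i2"],
            "length_bp": [1000, 1000],
            "group": ["functional", "truncated"],
        }
    )
    return psi, table, classes, catalog


def test_clean_switch_detected_with_fold_four():
    events = detect_switches(*switch_scenario())
    assert len(events) == 1
    e = events[0]
    assert {e.major_a, e.major_b} == {"i1", "i2"}
    assert np.isclose(e.fold, 4.0)
    assert e.two_fold


def test_significant_de_excludes_switch():
    events = detect_switches(*switch_scenario(padj=0.001))
    assert events == []


def test_le_class_excludes_switch():
    events = detect_switches(*switch_scenario(class_a="LE"))
    assert events == []
    events = detect_switches(*switch_scenario(class_b="NE"))
    assert events == []


def test_planted_switch_recovery(atlas):
    recall, precision = ca.evaluation.switch_recovery(atlas)
    assert recall >= 0.8
    assert precision >= 0.9


def test_major_isoform_dominance_shape(atlas_psi):
    mean_psi = atlas_psi.subtype_mean()
    majors = mean_psi.groupby(["subtype", "gene_id"])["psi"].max()
    assert majors.median() > 0.5


def test_group_psi_single_group():
    psi, _, _, catalog = switch_scenario()
    catalog["group"] = "functional"
    grouped = group_psi(psi, catalog)
    assert np.allclose(grouped["psi"], 1.0)


def test_group_psi_hand_sum():
    rows = [("a1", "g", "i1", 0.5), ("a1", "g", "i2", 0.3), ("a1", "g", "i3", 0.2)]
    samples = pd.DataFrame(
        {"sample_id": ["a1"], "subtype": ["A"], "replicate": [1]}
    )
    psi = PSITable(
        sample_psi=pd.DataFrame(rows, columns=["sample_id", "gene_id", "isoform_id", "psi"]),
        samples=samples,
    )
    catalog = pd.DataFrame(
        {
            "gene_id": ["g"] * 3,
            "isoform_id": ["i1", "i2", "i3"],
            "length_bp": [1000] * 3,
            "group": ["functional", "functional", "truncated"],
        }
    )
    grouped = group_psi(psi, catalog).set_index("group")["psi"]
    assert np.isclose(grouped["functional"], 0.8)
    assert np.isclose(grouped["truncated"], 0.2)


def test_group_psi_conserves_mass(atlas_psi, atlas):
    grouped = group_psi(atlas_psi, atlas["catalog"])
    sums = grouped.groupby(["subtype", "gene_id"])["psi"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_group_psi_missing_catalog_entry_raises(atlas_psi, atlas):
    broken = atlas["catalog"].iloc[1:]
    with pytest.raises(DataError):
        group_psi(atlas_psi, broken)
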