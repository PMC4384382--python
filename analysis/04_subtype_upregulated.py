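#!/usr/bin/env python
"""Subtype-upregulated (SU) gene calling and category breakdown.

A gene is SU for a subtype when it is significantly up (padj <= 0.01,
log2FC > 0) versus every other subtype and in the INT/HE class there.
Scores the calls against the planted truth.
"""

from pathlib import Path

import cd4atlas as ca
from cd4atlas import io
from cd4atlas.su_genes import categorize_su, su_table

ROOT = Path(__file__).resolve().parents[1]
ATLAS = ROOT / "results" / "atlas"
OUT = ROOT / "results"


def main() -> None:
    counts = io.read_counts(ATLAS / "counts.tsv")
    samples = io.read_samples(ATLAS / "samples.tsv")
    genes = io.read_genes(ATLAS / "genes.tsv")
    truth = io.read_truth(ATLAS / "truth.json")

    sf = ca.size_factors(counts)
    expr = ca.normalize(counts, sf, genes)
    fits = ca.fit_subtype_mixtures(expr, samples)
    classes = ca.assign_classes(expr, samples, fits)
    table = ca.pairwise_de(counts, samples, sf)
    sets = ca.call_all_su_genes(table, classes, genes)

    su_table(sets).to_csv(OUT / "su_genes.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
    categorize_su(sets).to_csv(OUT / "su_categories.tsv", sep="\t", index=False)

    tp = fp = planted = 0
    for t, su in sets.items():
        p = truth.planted_su[t]
        hit = len(set(su.genes) & p)
        tp += hit
        fp += len(su.genes) - hit
        planted += len(p)
        print(f"{t:>6}: {len(su):3d} SU genes ({hit} of {len(p)} planted recovered)")
    recall = tp / planted if planted else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    print(f"overall recall {recall:.3f}, precision {precision:.3f}")
    cats = categorize_su(sets).groupby("category")["n"].sum()
    print("SU genes by category:", cats[cats > 0].to_dict())


if __name__ == "__main__":
    main()
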