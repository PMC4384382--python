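#!/usr/bin/env python
"""Sample/gene clustering and PCA on moderated log expression.

Transforms counts with log2(K/s + 1), clusters samples and the top-variance
half of genes with complete-linkage Euclidean clustering, and projects
samples onto principal components.
"""

from pathlib import Path

import cd4atlas as ca
from cd4atlas import io

ROOT = Path(__file__).resolve().parents[1]
ATLAS = ROOT / "results" / "atlas"
OUT = ROOT / "results"


def main() -> None:
    counts = io.read_counts(ATLAS / "counts.tsv")
    samples = io.read_samples(ATLAS / "samples.tsv")
    sf = ca.size_factors(counts)
    transformed = ca.rlog_surrogate(counts, sf)

    dendro = ca.hierarchical_cluster(transformed, axis="samples")
    (OUT / "dendrogram_samples.newick").write_text(dendro.to_newick() + "\n")
    top = ca.top_variance_genes(transformed, 0.5)
    gene_dendro = ca.hierarchical_cluster(transformed.loc[top], axis="genes")
    (OUT / "dendrogram_genes.newick").write_text(gene_dendro.to_newick() + "\n")

    subtype_of = dict(zip(samples["sample_id"], samples["subtype"]))
    nearest = dendro.cophenetic_nearest()
    sisters = sum(subtype_of[a] == subtype_of[b] for a, b in nearest.items())
    print(f"replicates whose nearest leaf is their sister: {sisters}/{len(nearest)}")
    cut = dendro.cut(samples["subtype"].nunique())
    rand = ca.evaluation.rand_index(
        [subtype_of[s] for s in dendro.labels], [cut[s] for s in dendro.labels]
    )
    print(f"Rand index of 6-way cut vs subtype labels: {rand:.3f}")

    res = ca.pca(transformed)
    scores = res.scores.copy()
    scores.columns = [f"{c} ({f:.4f})" for c, f in zip(scores.columns, res.explained)]
    io.write_matrix(scores, OUT / "pca.tsv", index_label="sample_id")
    print(
        f"PC1 explains {res.explained[0]:.1%}, PC2 {res.explained[1]:.1%} "
        f"of between-sample variance"
    )


if __name__ == "__main__":
    main()
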