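#!/usr/bin/env python
"""Pairwise NB Wald differential expression across all 15 subtype pairs.

Writes one table per pair under results/de/ and the significant-gene counts
at fold-change cutoffs 0, 2 and 5 (padj <= 0.01) to results/de_counts.tsv.
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
    table = ca.pairwise_de(counts, samples, sf)
    de_dir = OUT / "de"
    de_dir.mkdir(parents=True, exist_ok=True)
    for (a, b), frame in table.pairs.items():
        io.write_matrix(frame, de_dir / f"{a}_vs_{b}.tsv")
    de_counts = ca.count_de(table)
    de_counts.to_csv(OUT / "de_counts.tsv", sep="\t", index=False)
    print(f"{len(table.pairs)} pairwise comparisons -> {de_dir}")
    wide = de_counts.pivot(index="pair", columns="cutoff", values="n")
    print("significant genes (padj <= 0.01) per pair at fold-change cutoffs:")
    print(wide.to_string())
    print(f"mean per pair at cutoff 0: {wide[0.0].mean():.1f}")


if __name__ == "__main__":
    main()
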