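#!/usr/bin/env python
"""Generate the synthetic CD4+ atlas used by the downstream analyses.

Six subtypes (Naive, Th1, Th2, Th17, Treg, iTreg) x two replicates, 2000
genes with bimodal log2 expression, 50 planted subtype-upregulated genes
per subtype at +3 log2 units, NB dispersion 0.05, and 30 planted isoform
switches.  Writes the count-level fixture (counts, sample sheet, gene
annotation, ground truth) under results/atlas/; the isoform-level data are
regenerated deterministically from the same seed by 06_isoform_switching.py.
"""

from pathlib import Path

import cd4atlas as ca
from cd4atlas import io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "atlas"
SEED = 11


def main() -> None:
    config = ca.SimConfig(seed=SEED)
    counts, samples, genes, truth = ca.generate_atlas(config)
    io.write_fixture(OUT, counts, samples, genes, truth)
    n_su = sum(len(v) for v in truth.planted_su.values())
    print(f"atlas: {counts.shape[0]} genes x {counts.shape[1]} samples -> {OUT}")
    print(f"planted SU genes: {n_su} ({n_su // len(truth.planted_su)} per subtype)")
    he = sum(1 for v in truth.planted_component.values() if v == "HE")
    print(f"expression components: {he} HE / {len(truth.planted_component) - he} LE")


if __name__ == "__main__":
    main()
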