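"""Subtype-upregulated (SU) gene calling and functional-category breakdown.

An SU gene for subtype *t* is significantly upregulated (padj <= 0.01 and
log2 fold change > 0) in *t* versus **every** other subtype, and belongs to
the INT or HE expression class in *t*.  Genes untestable in any comparison
fail that comparison; the rule is conjunctive, so SU sets are pairwise
disjoint across subtypes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential_expression import DETable
from .errors import IncompleteInputError


@dataclass
class SUGeneSet:
    """SU genes for one subtype with per-gene evidence."""

    subtype: str
    genes: list[str]
    evidence: pd.DataFrame  # index gene_id; min_log2fc, max_padj, category

    def __len__(self) -> int:
        return len(self.genes)


def call_su_genes(
    table: DETable,
    classes: pd.DataFrame,
    subtype: str,
    genes: pd.DataFrame | None = None,
    alpha: float | None = None,
) -> SUGeneSet:
    """Identify the SU genes of ``subtype``.

    ``classes`` is the gene x subtype class frame; ``genes`` optionally
    provides a ``category`` column for the evidence table.
    """
    alpha = table.alpha if alpha is None else alpha
    others = [t for t in table.subtypes if t != subtype]
    if subtype not in table.subtypes:
        raise IncompleteInputError(f"no DE results involve subtype {subtype!r}")
    if subtype not in classes.columns:
        raise IncompleteInputError(f"no class assignment for subtype {subtype!r}")

    passing: pd.Series | None = None
    min_fc: pd.Series | None = None
    max_padj: pd.Series | None = None
    for other in others:
        frame = table.get(other, subtype)  # log2fc > 0 == up in `subtype`
        ok = (frame["padj"] <= alpha) & (frame["log2fc"] > 0)
        ok = ok.fillna(False) & frame["p"].notna()
        passing = ok if passing is None else (passing & ok)
        min_fc = frame["log2fc"] if min_fc is None else np.minimum(min_fc, frame["log2fc"])
        max_padj = frame["padj"] if max_padj is None else np.maximum(max_padj, frame["padj"])
    in_class = classes[subtype].isin(["INT", "HE"])
    members = passing & in_class.reindex(passing.index, fill_value=False)
    gene_ids = list(members.index[members])
    evidence = pd.DataFrame(
        {"min_log2fc": min_fc[members], "max_padj": max_padj[members]}
    )
    if genes is not None and "category" in genes.columns:
        evidence["category"] = genes["category"].reindex(evidence.index, fill_value="other")
    else:
        evidence["category"] = "other"
    return SUGeneSet(subtype=subtype, genes=gene_ids, evidence=evidence)


def call_all_su_genes(
    table: DETable, classes: pd.DataFrame, genes: pd.DataFrame | None = None
) -> dict[str, SUGeneSet]:
    return {t: call_su_genes(table, classes, t, genes) for t in table.subtypes}


def categorize_su(sets: dict[str, SUGeneSet]) -> pd.DataFrame:
    """Per-subtype counts of SU genes by functional category.

    Returns a frame with one row per (subtype, category) including zero
    rows for categories absent from a subtype's set; category counts sum
    to the set size.
    """
    categories = ["TF", "cytokine", "receptor", "lncRNA", "other"]
    rows = []
    for subtype, su in sets.items():
        counts = su.evidence["category"].value_counts()
        for cat in categories:
            rows.append((subtype, cat, int(counts.get(cat, 0))))
        extra = set(counts.index) - set(categories)
        for cat in sorted(extra):
            rows.append((subtype, cat, int(counts[cat])))
    return pd.DataFrame(rows, columns=["subtype", "category", "n"])


def su_table(sets: dict[str, SUGeneSet]) -> pd.DataFrame:
    """Flat per-gene SU table for serialization."""
    rows = []
    for subtype, su in sets.items():
        for g in su.genes:
            ev = su.evidence.loc[g]
            rows.append((subtype, g, ev["category"], ev["min_log2fc"], ev["max_padj"]))
    return pd.DataFrame(
        rows, columns=["subtype", "gene_id", "category", "min_log2fc", "max_padj"]
    )
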