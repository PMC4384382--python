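"""Isoform PSI estimation by EM, major isoforms, and transcript switching.

PSI (percent spliced in) is the proportion of a gene's transcripts
attributable to each isoform.  Reads are modelled as drawn from isoform i
with probability proportional to ``psi_i * length_i`` with uniform position,
so a read's membership posterior over its compatibility class is
proportional to ``psi_i`` and the M-step converts expected read fractions
back to transcript fractions by dividing by length and renormalizing.  With
no ambiguous reads the EM reaches the length-corrected closed form in one
step.

A subtype's *major isoform* is the argmax-PSI isoform when it is the same
in every biological replicate (ties or disagreement leave it undefined and
exclude the gene downstream).  A *transcript switch* between two subtypes
requires differing major isoforms, no significant differential expression
of the gene in that pair, and INT/HE expression class in both subtypes; its
fold change is the minimum of the two orientation PSI ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .differential_expression import DETable
from .errors import AnnotationError, DataError, IncompleteInputError, ValidationError
from .simulate import CompatibilityData

EM_TOL = 1e-10
EM_MAX_ITER = 2000


def estimate_psi(
    classes: list[tuple[tuple[str, ...], int]],
    isoform_ids: list[str],
    lengths,
    return_trace: bool = False,
):
    """EM point estimate of the PSI vector for one sample and gene.

    ``classes`` holds (isoform-id tuple, read count) compatibility classes.
    Iterates from a uniform start until the largest PSI change is below
    1e-10 (or 2000 iterations).  Optionally returns the observed-data
    log-likelihood trace, which is non-decreasing.
    """
    lengths = np.asarray(lengths, dtype=float)
    k = len(isoform_ids)
    if k == 0 or lengths.size != k or (lengths <= 0).any():
        raise AnnotationError("estimate_psi: invalid isoform catalog entry")
    index = {iso: i for i, iso in enumerate(isoform_ids)}
    counts = []
    members = []
    total = 0
    for isos, n in classes:
        if n <= 0:
            continue
        try:
            idx = [index[i] for i in isos]
        except KeyError as exc:
            raise DataError(
                f"estimate_psi: read class {isos!r} references isoform {exc.args[0]!r} "
                "absent from the catalog"
            ) from exc
        if not idx:
            raise DataError("estimate_psi: a read has an empty compatibility set")
        members.append(np.asarray(idx))
        counts.append(n)
        total += n
    if total == 0:
        raise DataError("estimate_psi: no reads")
    counts = np.asarray(counts, dtype=float)

    psi = np.full(k, 1.0 / k)
    trace = []
    for _ in range(EM_MAX_ITER):
        # observed-data log-likelihood of the length-aware model
        class_mass = np.array([psi[m].sum() for m in members])
        loglik = float((counts * np.log(class_mass)).sum() - counts.sum() * np.log(psi @ lengths))
        trace.append(loglik)
        # E-step: responsibilities proportional to psi over the class
        reads = np.zeros(k)
        for m, n, mass in zip(members, counts, class_mass):
            reads[m] += n * psi[m] / mass
        # M-step: read fractions -> transcript fractions via lengths
        new = (reads / total) / lengths
        new /= new.sum()
        if np.max(np.abs(new - psi)) < EM_TOL:
            psi = new
            break
        psi = new
    if return_trace:
        return psi, np.asarray(trace)
    return psi


@dataclass
class PSITable:
    """Per-sample and per-subtype (replicate-mean) PSI values."""

    sample_psi: pd.DataFrame  # sample_id, gene_id, isoform_id, psi
    samples: pd.DataFrame  # sample sheet

    def vector(self, sample_id: str, gene_id: str, isoform_ids: list[str]) -> np.ndarray:
        sub = self.sample_psi[
            (self.sample_psi["sample_id"] == sample_id)
            & (self.sample_psi["gene_id"] == gene_id)
        ]
        psi = dict(zip(sub["isoform_id"], sub["psi"]))
        return np.array([psi.get(i, 0.0) for i in isoform_ids])

    def subtype_mean(self) -> pd.DataFrame:
        """Replicate-averaged PSI: subtype, gene_id, isoform_id, psi."""
        merged = self.sample_psi.merge(
            self.samples[["sample_id", "subtype"]], on="sample_id"
        )
        return (
            merged.groupby(["subtype", "gene_id", "isoform_id"], sort=False)["psi"]
            .mean()
            .reset_index()
        )


def estimate_psi_table(
    compat: CompatibilityData, catalog: pd.DataFrame, samples: pd.DataFrame
) -> PSITable:
    """Run the PSI EM for every (sample, gene) with compatibility data."""
    lengths_by_gene = {
        g: (list(sub["isoform_id"]), sub["length_bp"].to_numpy(float))
        for g, sub in catalog.groupby("gene_id", sort=False)
    }
    rows = []
    for (sample_id, gene_id), sub in compat.classes.groupby(
        ["sample_id", "gene_id"], sort=False
    ):
        if gene_id not in lengths_by_gene:
            raise DataError(f"gene {gene_id!r} has reads but no catalog entry")
        iso_ids, lengths = lengths_by_gene[gene_id]
        classes = list(zip(sub["isoform_ids"], sub["n_reads"]))
        psi = estimate_psi(classes, iso_ids, lengths)
        for iso, v in zip(iso_ids, psi):
            rows.append((sample_id, gene_id, iso, float(v)))
    return PSITable(
        sample_psi=pd.DataFrame(
            rows, columns=["sample_id", "gene_id", "isoform_id", "psi"]
        ),
        samples=samples,
    )


def sample_major_isoforms(psi: PSITable) -> pd.Series:
    """Argmax-PSI isoform per (sample, gene); exact ties map to None."""
    sp = psi.sample_psi
    if sp.empty:
        return pd.Series(dtype=object)
    mx = sp.groupby(["sample_id", "gene_id"], sort=False)["psi"].transform("max")
    top = sp[sp["psi"] == mx]
    grouped = top.groupby(["sample_id", "gene_id"], sort=False)["isoform_id"]
    majors = grouped.first().astype(object)
    majors[grouped.nunique() > 1] = None
    return majors


def subtype_major_isoforms(psi: PSITable) -> dict[tuple[str, str], str | None]:
    """Replicate-consistent major isoform per (subtype, gene).

    None when any replicate ties internally or replicates disagree; raises
    when a replicate lacks a PSI estimate for a gene other replicates have.
    """
    per_sample = sample_major_isoforms(psi)
    subtype_of = dict(zip(psi.samples["sample_id"], psi.samples["subtype"]))
    n_reps = psi.samples.groupby("subtype")["sample_id"].nunique()
    votes: dict[tuple[str, str], list] = {}
    for (sample_id, gene_id), major in per_sample.items():
        votes.setdefault((subtype_of[sample_id], gene_id), []).append(major)
    out: dict[tuple[str, str], str | None] = {}
    for (subtype, gene_id), majors in votes.items():
        if len(majors) != int(n_reps[subtype]):
            raise IncompleteInputError(
                f"gene {gene_id!r}: PSI missing in a replicate of {subtype!r}"
            )
        if None in majors or len(set(majors)) != 1:
            out[(subtype, gene_id)] = None
        else:
            out[(subtype, gene_id)] = majors[0]
    return out


def major_isoform(psi: PSITable, subtype: str, gene_id: str) -> str | None:
    """The subtype's major isoform, or None when replicates disagree or tie."""
    reps = list(psi.samples.loc[psi.samples["subtype"] == subtype, "sample_id"])
    if not reps:
        raise IncompleteInputError(f"subtype {subtype!r} has no samples")
    majors = []
    for sample_id in reps:
        sub = psi.sample_psi[
            (psi.sample_psi["sample_id"] == sample_id)
            & (psi.sample_psi["gene_id"] == gene_id)
        ]
        if sub.empty:
            raise IncompleteInputError(
                f"no PSI estimate for gene {gene_id!r} in replicate {sample_id!r}"
            )
        values = sub["psi"].to_numpy()
        top = values.max()
        winners = sub["isoform_id"][values == top]
        if len(winners) != 1:  # exact tie -> undefined
            return None
        majors.append(winners.iloc[0])
    return majors[0] if len(set(majors)) == 1 else None


def switch_fold_change(psi_a, psi_b, major_a: int, major_b: int):
    """Minimum of the two orientation ratios between the switching majors.

    ``ratio_A = psi_A[major_A] / psi_A[major_B]`` and symmetrically for B;
    a zero denominator yields +inf with a flag.
    """
    if major_a == major_b:
        raise ValidationError("switch_fold_change: majors must differ")
    psi_a = np.asarray(psi_a, dtype=float)
    psi_b = np.asarray(psi_b, dtype=float)
    flagged = False
    if psi_a[major_b] == 0 or psi_b[major_a] == 0:
        return float("inf"), True
    ratio_a = psi_a[major_a] / psi_a[major_b]
    ratio_b = psi_b[major_b] / psi_b[major_a]
    return float(min(ratio_a, ratio_b)), flagged


@dataclass(frozen=True)
class SwitchEvent:
    gene_id: str
    pair: tuple[str, str]
    major_a: str
    major_b: str
    fold: float
    two_fold: bool


def detect_switches(
    psi: PSITable,
    table: DETable,
    classes: pd.DataFrame,
    catalog: pd.DataFrame,
    alpha: float | None = None,
    two_fold_threshold: float = 2.0,
) -> list[SwitchEvent]:
    """Find transcript switches across all subtype pairs.

    For each pair and multi-isoform gene: both subtypes must have a defined
    (replicate-consistent) major isoform, the majors must differ, the gene
    must not be significantly DE in that pair (padj > alpha), and its class
    must be INT or HE in both subtypes.  The fold change uses the
    replicate-mean PSI vectors.
    """
    alpha = table.alpha if alpha is None else alpha
    subtypes = [t for t in table.subtypes if t in set(psi.samples["subtype"])]
    iso_by_gene = {
        g: list(sub["isoform_id"]) for g, sub in catalog.groupby("gene_id", sort=False)
    }
    genes = [g for g in iso_by_gene if len(iso_by_gene[g]) > 1]

    majors = subtype_major_isoforms(psi)
    mean_psi = psi.subtype_mean()
    mean_lookup = {
        (row.subtype, row.gene_id, row.isoform_id): row.psi
        for row in mean_psi.itertuples(index=False)
    }

    events = []
    for a, b in combinations(subtypes, 2):
        frame = table.get(a, b)
        for g in genes:
            ma, mb = majors.get((a, g)), majors.get((b, g))
            if ma is None or mb is None or ma == mb:
                continue
            padj = frame["padj"].get(g, np.nan)
            if np.isfinite(padj) and padj <= alpha:
                continue  # significantly DE in this pair
            cls_a = classes[a].get(g, "NE") if a in classes.columns else "NE"
            cls_b = classes[b].get(g, "NE") if b in classes.columns else "NE"
            if cls_a not in ("INT", "HE") or cls_b not in ("INT", "HE"):
                continue
            iso_ids = iso_by_gene[g]
            vec_a = np.array([mean_lookup.get((a, g, i), 0.0) for i in iso_ids])
            vec_b = np.array([mean_lookup.get((b, g, i), 0.0) for i in iso_ids])
            ia, ib = iso_ids.index(ma), iso_ids.index(mb)
            fold, _ = switch_fold_change(vec_a, vec_b, ia, ib)
            events.append(
                SwitchEvent(
                    gene_id=g,
                    pair=(a, b),
                    major_a=ma,
                    major_b=mb,
                    fold=fold,
                    two_fold=fold >= two_fold_threshold,
                )
            )
    return events


def switches_table(events: list[SwitchEvent]) -> pd.DataFrame:
    rows = [
        (f"{e.pair[0]}_vs_{e.pair[1]}", e.gene_id, e.major_a, e.major_b, e.fold, e.two_fold)
        for e in events
    ]
    return pd.DataFrame(
        rows, columns=["pair", "gene_id", "major_A", "major_B", "fold", "two_fold"]
    )


def group_psi(psi: PSITable, catalog: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate-mean PSI within isoform groups per (subtype, gene).

    Groups are the catalog's functional labels (functional / truncated /
    non_coding); each grouped vector sums to 1.
    """
    if catalog["group"].isna().any():
        bad = catalog.loc[catalog["group"].isna(), "isoform_id"].iloc[0]
        raise AnnotationError(f"isoform {bad!r} has no group label")
    mean_psi = psi.subtype_mean()
    merged = mean_psi.merge(catalog[["isoform_id", "group"]], on="isoform_id", how="left")
    if merged["group"].isna().any():
        bad = merged.loc[merged["group"].isna(), "isoform_id"].iloc[0]
        raise AnnotationError(f"isoform {bad!r} is missing from the catalog")
    return (
        merged.groupby(["subtype", "gene_id", "group"], sort=False)["psi"]
        .sum()
        .reset_index()
    )
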