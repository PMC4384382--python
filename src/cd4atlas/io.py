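"""TSV/JSON readers and writers for every pipeline artefact.

All tables are plain tab-separated text with a header row; floats are
written with ``%.10g`` so that reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import CompatibilityData, SimTruth

FLOAT_FORMAT = "%.10g"


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise DataError(f"cannot parse {path}: {exc}") from exc


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col="gene_id")
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate gene identifiers")
    if not df.empty:
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise DataError(f"{path}: counts must be integers")
        if (vals < 0).any():
            raise DataError(f"{path}: counts must be non-negative")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"sample_id", "subtype", "replicate"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicate sample identifiers")
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index_label="gene_id")


def read_genes(path) -> pd.DataFrame:
    df = _read_tsv(path, index_col="gene_id")
    if "length_bp" not in df.columns:
        raise DataError(f"{path}: expected a length_bp column")
    if "category" not in df.columns:
        df["category"] = "other"
    return df


def write_isoforms(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_isoforms(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"gene_id", "isoform_id", "length_bp", "group"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    if df["isoform_id"].duplicated().any():
        raise DataError(f"{path}: duplicate isoform identifiers")
    return df


def write_compat(compat: CompatibilityData, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tread_id\tisoform_id\n")
        for sample_id, read_id, isoform_id in compat.iter_reads():
            fh.write(f"{sample_id}\t{read_id}\t{isoform_id}\n")


def read_compat(path, catalog: pd.DataFrame) -> CompatibilityData:
    """Rebuild compatibility classes from per-read triplets."""
    df = _read_tsv(path)
    required = {"sample_id", "read_id", "isoform_id"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    gene_of = dict(zip(catalog["isoform_id"], catalog["gene_id"]))
    if df.empty:
        return CompatibilityData(
            classes=pd.DataFrame(columns=["sample_id", "gene_id", "isoform_ids", "n_reads"])
        )
    unknown = set(df["isoform_id"]) - set(gene_of)
    if unknown:
        bad = df[df["isoform_id"].isin(unknown)].iloc[0]
        raise DataError(
            f"{path}: read {bad.read_id!r} is compatible with unknown isoform "
            f"{bad.isoform_id!r}"
        )
    grouped = (
        df.groupby(["sample_id", "read_id"])["isoform_id"]
        .apply(lambda s: tuple(sorted(s)))
        .reset_index(name="isoform_ids")
    )
    grouped["gene_id"] = grouped["isoform_ids"].map(lambda t: gene_of[t[0]])
    for isoforms, gene in zip(grouped["isoform_ids"], grouped["gene_id"]):
        if any(gene_of[i] != gene for i in isoforms):
            raise DataError(f"{path}: a read is compatible with isoforms of different genes")
    classes = (
        grouped.groupby(["sample_id", "gene_id", "isoform_ids"])
        .size()
        .reset_index(name="n_reads")
    )
    return CompatibilityData(classes=classes[["sample_id", "gene_id", "isoform_ids", "n_reads"]])


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "subtypes": list(truth.subtypes),
        "planted_su": {t: sorted(g) for t, g in truth.planted_su.items()},
        "planted_component": truth.planted_component,
        "planted_psi": {
            g: {t: list(psi) for t, psi in by_t.items()}
            for g, by_t in truth.planted_psi.items()
        },
        "planted_switches": sorted([g, list(pair)] for g, pair in truth.planted_switches),
        "base_means": {
            "index": list(truth.base_means.index),
            "columns": list(truth.base_means.columns),
            "values": truth.base_means.to_numpy().tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    bm = payload["base_means"]
    return SimTruth(
        subtypes=tuple(payload["subtypes"]),
        planted_su={t: frozenset(g) for t, g in payload["planted_su"].items()},
        planted_component=payload["planted_component"],
        base_means=pd.DataFrame(bm["values"], index=bm["index"], columns=bm["columns"]),
        planted_psi={
            g: {t: tuple(psi) for t, psi in by_t.items()}
            for g, by_t in payload["planted_psi"].items()
        },
        planted_switches={(g, tuple(pair)) for g, pair in payload["planted_switches"]},
    )


def write_fixture(
    directory,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    truth: SimTruth | None = None,
    catalog: pd.DataFrame | None = None,
    compat: CompatibilityData | None = None,
) -> dict[str, Path]:
    """Serialize a generated data set to ``directory``; returns the file map.

    Output round-trips losslessly through the matching readers.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise DataError(f"cannot write to {directory}: {exc}") from exc
    files = {}
    write_counts(counts, directory / "counts.tsv")
    files["counts"] = directory / "counts.tsv"
    write_samples(samples, directory / "samples.tsv")
    files["samples"] = directory / "samples.tsv"
    write_genes(genes, directory / "genes.tsv")
    files["genes"] = directory / "genes.tsv"
    if catalog is not None:
        write_isoforms(catalog, directory / "isoforms.tsv")
        files["isoforms"] = directory / "isoforms.tsv"
    if compat is not None:
        write_compat(compat, directory / "compat.tsv")
        files["compat"] = directory / "compat.tsv"
    if truth is not None:
        write_truth(truth, directory / "truth.json")
        files["truth"] = directory / "truth.json"
    return files


def write_matrix(df: pd.DataFrame, path, index_label="gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FORMAT)


def read_matrix(path, index_col="gene_id") -> pd.DataFrame:
    return _read_tsv(path, index_col=index_col)
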