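"""Median-of-ratios size factors and length-normalized expression.

Size factors follow the median-of-ratios convention: each sample's factor is
the median, over genes with non-zero counts in every sample, of the ratio of
that gene's count to its geometric mean across samples.  Normalized
expression divides counts by the size factor and by gene length in
kilobases, giving an RPKM-equivalent measure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnnotationError, DataError, NormalizationError


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise DataError("duplicate gene identifiers in count matrix")
    if counts.columns.has_duplicates:
        raise DataError("duplicate sample identifiers in count matrix")
    vals = counts.to_numpy()
    if vals.size and ((vals < 0).any() or not np.allclose(vals, np.round(vals))):
        raise DataError("counts must be non-negative integers")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors by the median-of-ratios method.

    Genes with a zero count in any sample are excluded from the reference,
    which keeps the estimate robust to differential expression of a few
    high-count genes.  Raises :class:`NormalizationError` when no gene is
    positive in every sample.
    """
    _validate_counts(counts)
    vals = counts.to_numpy(dtype=float)
    usable = (vals > 0).all(axis=1) if vals.size else np.zeros(0, bool)
    if not usable.any():
        raise NormalizationError(
            "no gene has a non-zero count in every sample; size factors undefined"
        )
    logs = np.log(vals[usable])
    log_gmean = logs.mean(axis=1, keepdims=True)
    ratios = np.exp(logs - log_gmean)
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series, genes: pd.DataFrame) -> pd.DataFrame:
    """Size-factor-adjusted, length-normalized expression (RPKM-equivalent).

    ``value[g, j] = K[g, j] / (s_j * length_kb[g])``.  Zero counts map to
    exactly zero.
    """
    missing = counts.index.difference(genes.index)
    if len(missing):
        raise AnnotationError(f"no length annotation for gene {missing[0]!r}")
    lengths = genes.loc[counts.index, "length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        bad = counts.index[lengths <= 0][0]
        raise AnnotationError(f"non-positive length for gene {bad!r}")
    s = sf.reindex(counts.columns).to_numpy(dtype=float)
    if np.isnan(s).any() or (s <= 0).any():
        raise NormalizationError("size factors must be positive for every sample")
    values = counts.to_numpy(dtype=float) / (s[None, :] * (lengths[:, None] / 1000.0))
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)
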