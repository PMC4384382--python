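"""Pairwise negative-binomial Wald tests with BH correction.

The test is a transparent NB Wald test on size-factor-normalized counts:
group means on the normalized scale, an NB variance model
``Var(q_ij) = m / s_j + alpha * m^2``, a delta-method standard error for
``log2(m + 0.5)`` (the 0.5 pseudocount keeps one-sided zeros finite), and a
two-sided normal p-value.  Per-gene dispersions are estimated by the method
of moments and, for the pairwise tables, smoothed with a binned
mean–dispersion trend: with only two replicates per group the raw per-gene
estimate has two degrees of freedom, which makes the Wald statistic heavy-
tailed wherever the dispersion term dominates the variance; sharing the
estimate across genes of similar expression restores near-nominal type-I
error.  BH adjustment is applied within each pairwise comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, IncompleteInputError, ValidationError
from .normalization import size_factors as _size_factors

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
DEFAULT_ALPHA = 0.01
DEFAULT_FC_CUTOFFS = (0.0, 2.0, 5.0)


def _normalized(counts: np.ndarray, sf: np.ndarray) -> np.ndarray:
    return counts / sf


def estimate_dispersion(counts_a, counts_b, sf_a, sf_b) -> float:
    """Per-gene method-of-moments NB dispersion for one gene, two groups.

    ``alpha = max(0, (v - m) / m^2)`` with *m*, *v* the pooled within-group
    mean and variance of the size-factor-normalized counts, floored at
    1e-8.  Returns NaN (untestable) for an all-zero gene.
    """
    qa = _normalized(np.asarray(counts_a, float), np.asarray(sf_a, float))
    qb = _normalized(np.asarray(counts_b, float), np.asarray(sf_b, float))
    if qa.size < 2 or qb.size < 2:
        raise ConfigError("estimate_dispersion: need >= 2 replicates per group")
    if (qa == 0).all() and (qb == 0).all():
        return float("nan")
    m = np.concatenate([qa, qb]).mean()
    v = (qa.var(ddof=1) + qb.var(ddof=1)) / 2.0
    return max((v - m) / m**2, DISPERSION_FLOOR)


def _raw_dispersions(qa: np.ndarray, qb: np.ndarray):
    """Vectorized untruncated moment estimates (trend input) and means."""
    m = np.concatenate([qa, qb], axis=1).mean(axis=1)
    v = (qa.var(axis=1, ddof=1) + qb.var(axis=1, ddof=1)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m) / m**2
    return m, raw


def dispersion_trend(means: np.ndarray, raw: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Smooth raw per-gene dispersion estimates with a binned-mean trend.

    Genes are binned by log mean into quantile bins; the *mean* of the raw
    (untruncated) moment estimates per bin is an unbiased estimate of the
    local dispersion, and each gene receives the value interpolated at its
    own mean, floored at 1e-8.
    """
    means = np.asarray(means, float)
    raw = np.asarray(raw, float)
    ok = np.isfinite(raw) & (means > 0)
    if ok.sum() < 2:
        return np.where(np.isfinite(raw), np.maximum(raw, DISPERSION_FLOOR), np.nan)
    lm = np.log(means[ok])
    n_bins = max(1, min(n_bins, ok.sum() // 25)) or 1
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, lm, side="right") - 1, 0, n_bins - 1)
    centers, levels = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            centers.append(lm[sel].mean())
            levels.append(raw[ok][sel].mean())
    out = np.full(means.shape, np.nan)
    with np.errstate(divide="ignore"):
        out[means > 0] = np.interp(np.log(means[means > 0]), centers, levels)
    return np.maximum(out, DISPERSION_FLOOR)


def nb_wald_test(counts_a, counts_b, sf_a, sf_b, alpha_g):
    """NB Wald test for one gene (or a vector of genes, row-wise).

    Returns a dict of arrays: log2fc (log2 of the B/A ratio of pseudocounted
    group means), se, wald, p.  Genes with zero counts in both groups get
    NaN p-values and are excluded from BH downstream.
    """
    qa = _normalized(np.atleast_2d(np.asarray(counts_a, float)), np.asarray(sf_a, float))
    qb = _normalized(np.atleast_2d(np.asarray(counts_b, float)), np.asarray(sf_b, float))
    alpha_g = np.atleast_1d(np.asarray(alpha_g, float))
    sa = np.asarray(sf_a, float)
    sb = np.asarray(sf_b, float)
    ma, mb = qa.mean(axis=1), qb.mean(axis=1)

    def se_log2(m, s, n, alpha):
        # plug-in variance at the pseudocounted mean: a zero-count group has
        # sampling uncertainty, not zero variance
        mp = m[:, None] + PSEUDOCOUNT
        var_m = (mp / s[None, :] + alpha[:, None] * mp**2).sum(axis=1) / n**2
        return np.sqrt(var_m) / ((m + PSEUDOCOUNT) * np.log(2.0))

    se_a = se_log2(ma, sa, qa.shape[1], alpha_g)
    se_b = se_log2(mb, sb, qb.shape[1], alpha_g)
    log2fc = np.log2(mb + PSEUDOCOUNT) - np.log2(ma + PSEUDOCOUNT)
    se = np.sqrt(se_a**2 + se_b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * norm.sf(np.abs(wald))
    untestable = (qa == 0).all(axis=1) & (qb == 0).all(axis=1)
    p = np.where(untestable, np.nan, p)
    wald = np.where(untestable, np.nan, wald)
    return {"log2fc": log2fc, "se": se, "wald": wald, "p": p}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, NaNs passed through.

    ``q_(i) = min_{k >= i} p_(k) * m / k`` capped at 1, returned in input
    order; *m* counts only the defined p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    pv = p[defined]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[defined] = adj
    return out


@dataclass
class DETable:
    """All pairwise DE results: one frame per unordered subtype pair."""

    pairs: dict[tuple[str, str], pd.DataFrame]
    alpha: float = DEFAULT_ALPHA
    fc_cutoffs: tuple[float, ...] = DEFAULT_FC_CUTOFFS

    def get(self, a: str, b: str) -> pd.DataFrame:
        """Results oriented so log2fc > 0 means higher in ``b``."""
        if (a, b) in self.pairs:
            return self.pairs[(a, b)]
        if (b, a) in self.pairs:
            flipped = self.pairs[(b, a)].copy()
            flipped["log2fc"] = -flipped["log2fc"]
            flipped["wald"] = -flipped["wald"]
            return flipped
        raise IncompleteInputError(f"no DE results for pair ({a}, {b})")

    @property
    def subtypes(self) -> list[str]:
        seen: list[str] = []
        for a, b in self.pairs:
            for t in (a, b):
                if t not in seen:
                    seen.append(t)
        return seen


def de_pair(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sf: pd.Series,
    subtype_a: str,
    subtype_b: str,
    trend: bool = True,
) -> pd.DataFrame:
    """Test one subtype pair for every gene; BH within the comparison."""
    cols_a = list(samples.loc[samples["subtype"] == subtype_a, "sample_id"])
    cols_b = list(samples.loc[samples["subtype"] == subtype_b, "sample_id"])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ConfigError(
            f"subtypes {subtype_a}/{subtype_b} need >= 2 replicates each"
        )
    ka = counts[cols_a].to_numpy(float)
    kb = counts[cols_b].to_numpy(float)
    sa = sf[cols_a].to_numpy(float)
    sb = sf[cols_b].to_numpy(float)
    qa, qb = ka / sa, kb / sb
    means, raw = _raw_dispersions(qa, qb)
    if trend:
        disp = dispersion_trend(means, raw)
    else:
        disp = np.maximum(np.nan_to_num(raw, nan=0.0), DISPERSION_FLOOR)
    disp = np.where(np.isfinite(disp), disp, DISPERSION_FLOOR)
    res = nb_wald_test(ka, kb, sa, sb, disp)
    frame = pd.DataFrame(
        {
            "log2fc": res["log2fc"],
            "se": res["se"],
            "wald": res["wald"],
            "p": res["p"],
            "padj": bh_adjust(res["p"]),
        },
        index=counts.index,
    )
    return frame


def pairwise_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sf: pd.Series | None = None,
    alpha: float = DEFAULT_ALPHA,
    fc_cutoffs=DEFAULT_FC_CUTOFFS,
    trend: bool = True,
) -> DETable:
    """Run the NB Wald test for every unordered subtype pair.

    Results are oriented as log2(mean_B / mean_A) for the pair (A, B) in
    sample-sheet subtype order; BH is applied within each pair.
    """
    subtypes = list(samples["subtype"].unique())
    if len(subtypes) < 2:
        raise ConfigError("pairwise_de: need at least 2 subtypes")
    cutoffs = tuple(float(c) for c in fc_cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValidationError("fc_cutoffs must be strictly increasing")
    if sf is None:
        sf = _size_factors(counts)
    tables = {}
    for a, b in combinations(subtypes, 2):
        tables[(a, b)] = de_pair(counts, samples, sf, a, b, trend=trend)
    return DETable(pairs=tables, alpha=alpha, fc_cutoffs=cutoffs)


def count_de(table: DETable) -> pd.DataFrame:
    """Count significant genes per pair at each |fold-change| cutoff.

    A gene counts at cutoff ``c`` when ``padj <= alpha`` and
    ``|log2fc| >= log2(c)``; cutoff 0 imposes no fold-change filter.
    """
    rows = []
    for (a, b), frame in table.pairs.items():
        sig = frame["padj"] <= table.alpha
        for c in table.fc_cutoffs:
            if c > 0:
                n = int((sig & (frame["log2fc"].abs() >= np.log2(c))).sum())
            else:
                n = int(sig.sum())
            rows.append((f"{a}_vs_{b}", c, n))
    return pd.DataFrame(rows, columns=["pair", "cutoff", "n"])
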