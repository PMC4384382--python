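"""Bimodal expression classes: two-component Gaussian mixture + FDR boundaries.

Per subtype, the distribution of log2 replicate-mean normalized expression
(zero counts excluded) is bimodal: a low-expressed (LE) and a high-expressed
(HE) component.  A two-component univariate Gaussian mixture is fitted by
EM, and class boundaries are derived from the component posterior at a
chosen contamination level ``alpha`` (default 0.01): a gene is called HE
only where the LE posterior is <= alpha, LE only where the HE posterior is
<= alpha, and INT in between.  Genes with zero counts in every replicate of
a subtype are NE (not expressed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigError, FitError, InsufficientDataError, ValidationError

CLASS_LABELS = ("NE", "LE", "INT", "HE")


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture on log2 expression, labelled LE < HE."""

    mu_le: float
    sd_le: float
    mu_he: float
    sd_he: float
    weight_he: float
    loglik_trace: np.ndarray
    converged: bool

    def posterior_le(self, x):
        """P(component = LE | x)."""
        x = np.asarray(x, dtype=float)
        log_le = np.log1p(-self.weight_he) + norm.logpdf(x, self.mu_le, self.sd_le)
        log_he = np.log(self.weight_he) + norm.logpdf(x, self.mu_he, self.sd_he)
        m = np.maximum(log_le, log_he)
        return np.exp(log_le - m) / (np.exp(log_le - m) + np.exp(log_he - m))

    def posterior_he(self, x):
        return 1.0 - self.posterior_le(x)


@dataclass
class ClassBoundaries:
    """log2-expression thresholds separating LE / INT / HE at FDR ``alpha``."""

    alpha: float
    b_low: float
    b_high: float
    low_warning: bool = False
    high_warning: bool = False


def fit_mixture(log_values, tol: float = 1e-8, max_iter: int = 1000) -> MixtureFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    Initialization is deterministic: the sample is split at its median and
    each half provides one component's moments.  Iteration stops when the
    log-likelihood improves by less than ``tol`` or after ``max_iter``
    rounds; components are returned ordered by mean (LE first).
    """
    x = np.asarray(log_values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.isfinite(x).all():
        raise ValidationError("fit_mixture: input must contain only finite values")
    n = x.size
    if n < 20:
        raise InsufficientDataError(f"fit_mixture: need at least 20 values, got {n}")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # all values tied at the median
        lo, hi = x[: n // 2], x[n // 2 :]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])
    w = np.array([lo.size / n, hi.size / n])

    trace = []
    converged = False
    for _ in range(max_iter):
        logp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        m = logp.max(axis=0)
        log_mix = m + np.log(np.exp(logp - m).sum(axis=0))
        loglik = float(log_mix.sum())
        resp = np.exp(logp - log_mix)  # 2 x n responsibilities
        if trace and loglik - trace[-1] < tol:
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        nk = resp.sum(axis=1)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ x**2) / nk - mu**2
        if (var < 1e-6).any():
            raise FitError("fit_mixture: degenerate component variance (< 1e-6)")
        sd = np.sqrt(var)

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    return MixtureFit(
        mu_le=float(mu[0]),
        sd_le=float(sd[0]),
        mu_he=float(mu[1]),
        sd_he=float(sd[1]),
        weight_he=float(w[1]),
        loglik_trace=np.asarray(trace),
        converged=converged,
    )


def class_boundaries(fit: MixtureFit, alpha: float = 0.01) -> ClassBoundaries:
    """FDR-style class boundaries from the component posterior.

    ``b_high`` is the smallest x at which the LE posterior drops to
    ``alpha`` (HE calls above it carry <= alpha LE contamination);
    ``b_low`` is the largest x at which the HE posterior is <= alpha.
    When the posterior never crosses ``alpha`` the boundary is +/-inf with
    a warning flag.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"class_boundaries: alpha must be in (0, 1), got {alpha}")
    span = 12.0 * max(fit.sd_le, fit.sd_he)
    grid = np.linspace(fit.mu_le - span, fit.mu_he + span, 4001)
    post_le = fit.posterior_le(grid)

    def crossing(target: float) -> float | None:
        """First x (left to right) where posterior_le - target changes sign."""
        f = post_le - target
        sign_change = np.nonzero(np.diff(np.sign(f)) != 0)[0]
        if len(sign_change) == 0:
            return None
        i = sign_change[0]
        return brentq(lambda x: float(fit.posterior_le(x) - target), grid[i], grid[i + 1])

    # b_high: posterior_le falls to alpha; b_low: posterior_he rises to alpha,
    # i.e. posterior_le falls to 1 - alpha.
    high = crossing(alpha)
    low = crossing(1.0 - alpha)
    return ClassBoundaries(
        alpha=alpha,
        b_low=float(low) if low is not None else -np.inf,
        b_high=float(high) if high is not None else np.inf,
        low_warning=low is None,
        high_warning=high is None,
    )


def subtype_mean_expression(expr: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean normalized expression per subtype (genes x subtypes)."""
    missing = set(samples["sample_id"]) - set(expr.columns)
    if missing:
        raise ConfigError(f"samples missing from expression matrix: {sorted(missing)}")
    out = {}
    for subtype, grp in samples.groupby("subtype", sort=False):
        out[subtype] = expr[list(grp["sample_id"])].mean(axis=1)
    return pd.DataFrame(out)


def fit_subtype_mixtures(
    expr: pd.DataFrame, samples: pd.DataFrame, alpha: float = 0.01
) -> dict[str, tuple[MixtureFit, ClassBoundaries]]:
    """Fit the mixture and boundaries per subtype on replicate-mean values.

    Zeros (all-replicate-zero genes) are excluded before the log transform,
    matching the convention of omitting genes with zero read counts.
    """
    means = subtype_mean_expression(expr, samples)
    fits = {}
    for subtype in means.columns:
        v = means[subtype].to_numpy()
        v = v[v > 0]
        fit = fit_mixture(np.log2(v))
        fits[subtype] = (fit, class_boundaries(fit, alpha))
    return fits


def assign_classes(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    fits: dict[str, tuple[MixtureFit, ClassBoundaries]],
) -> pd.DataFrame:
    """Assign each gene a class per subtype: NE, LE, INT or HE.

    NE iff expression is zero in every replicate; otherwise the log2
    replicate mean is compared against the subtype's boundaries.
    """
    subtypes = samples["subtype"].unique()
    missing = [t for t in subtypes if t not in fits]
    if missing:
        raise ConfigError(f"no mixture fit for subtype(s) {missing}")
    out = {}
    for subtype, grp in samples.groupby("subtype", sort=False):
        cols = list(grp["sample_id"])
        sub = expr[cols]
        mean = sub.mean(axis=1)
        _, bounds = fits[subtype]
        with np.errstate(divide="ignore"):
            logm = np.log2(mean.to_numpy())
        cls = np.where(
            (sub.to_numpy() == 0).all(axis=1),
            "NE",
            np.where(logm < bounds.b_low, "LE", np.where(logm > bounds.b_high, "HE", "INT")),
        )
        out[subtype] = pd.Series(cls, index=expr.index)
    return pd.DataFrame(out)
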