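"""Planted-truth scoring and calibration metrics.

Every function here recomputes a quantity from scratch by running the
pipeline on freshly generated synthetic data, so the same code backs both
the test suite and the reproducibility script.  Oracles (brute-force
median-of-ratios, the step-up rule, closed-form PSI) are deliberately
written in the most literal way possible, independent of the vectorized
implementations they check.
"""

from __future__ import annotations

import statistics
from itertools import combinations

import numpy as np
import pandas as pd

from .clustering import hierarchical_cluster, rlog_surrogate
from .differential_expression import bh_adjust, de_pair, pairwise_de
from .expression_classes import class_boundaries, fit_mixture
from .isoforms import detect_switches, estimate_psi, estimate_psi_table
from .normalization import size_factors
from .simulate import SimConfig, generate_all, generate_atlas
from .su_genes import call_all_su_genes


# ---------------------------------------------------------------------------
# normalization

def brute_force_size_factors(counts: pd.DataFrame) -> list[float]:
    """Literal median-of-ratios: python loops, statistics.median."""
    genes = list(counts.index)
    usable = [g for g in genes if all(counts.loc[g, s] > 0 for s in counts.columns)]
    out = []
    for s in counts.columns:
        ratios = []
        for g in usable:
            row = [float(counts.loc[g, c]) for c in counts.columns]
            gmean = np.exp(sum(np.log(v) for v in row) / len(row))
            ratios.append(float(counts.loc[g, s]) / gmean)
        out.append(statistics.median(ratios))
    return out


def size_factor_oracle_error(n_matrices: int, seed: int, shape=(20, 4)) -> float:
    """Max |size_factors - brute force| over random count matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        counts = pd.DataFrame(
            rng.poisson(rng.uniform(1, 200), size=shape).astype(int),
            index=[f"g{i}" for i in range(shape[0])],
            columns=[f"s{j}" for j in range(shape[1])],
        )
        counts.iloc[0] += 1  # guarantee one all-positive gene
        sf = size_factors(counts)
        oracle = brute_force_size_factors(counts)
        worst = max(worst, float(np.max(np.abs(sf.to_numpy() - np.asarray(oracle)))))
    return worst


# ---------------------------------------------------------------------------
# mixture recovery

def mixture_recovery(n_seeds: int, seed: int, n: int = 5000):
    """Fit the two-component EM on 0.5 N(1,1) + 0.5 N(8,1) draws.

    Returns (mean absolute error of recovered means, worst trace decrease,
    fraction of runs whose FDR-0.01 boundaries bracket the midpoint 4.5).
    """
    errors, bracket, worst_drop = [], 0, 0.0
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, k])
        comp = rng.random(n) < 0.5
        x = np.where(comp, rng.normal(8, 1, n), rng.normal(1, 1, n))
        fit = fit_mixture(x)
        errors.extend([abs(fit.mu_le - 1.0), abs(fit.mu_he - 8.0)])
        worst_drop = min(worst_drop, float(np.min(np.diff(fit.loglik_trace))))
        b = class_boundaries(fit, alpha=0.01)
        bracket += int(b.b_low < 4.5 < b.b_high)
    return float(np.mean(errors)), worst_drop, bracket / n_seeds


# ---------------------------------------------------------------------------
# differential expression

def null_type1_error(seed: int, n_genes: int = 5000, nominal: float = 0.05):
    """Type-I error of the NB Wald test on a no-effect atlas (2 x 2+2)."""
    config = SimConfig(
        n_subtypes=2,
        n_genes=n_genes,
        su_per_subtype=0,
        frac_multi_isoform=0.0,
        n_switch_genes=0,
        dispersion=0.05,
        seed=seed,
    )
    counts, samples, genes, _ = generate_atlas(config)
    sf = size_factors(counts)
    a, b = samples["subtype"].unique()[:2]
    frame = de_pair(counts, samples, sf, a, b)
    p = frame["p"].to_numpy()
    tested = np.isfinite(p)
    return float(np.mean(p[tested] <= nominal)), int(tested.sum())


def brute_force_bh(pvalues) -> np.ndarray:
    """Literal step-up: q_(i) = min_{k >= i} p_(k) * m / k, capped at 1."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for rank_pos, i in enumerate(order):
        q = min(min(p[order[k]] * m / (k + 1) for k in range(rank_pos, m)), 1.0)
        out[i] = q
    return np.asarray(out)


def bh_oracle_error(n_vectors: int, seed: int, max_len: int = 40) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, max_len)))
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - brute_force_bh(p)))))
    return worst


def planted_de_power(seed: int, log2fc: float, n_genes: int = 2000) -> float:
    """Recall of planted SU genes as padj <= 0.01 calls in their pairs."""
    config = SimConfig(n_genes=n_genes, su_log2fc=log2fc, seed=seed)
    counts, samples, genes, truth = generate_atlas(config)
    sf = size_factors(counts)
    table = pairwise_de(counts, samples, sf)
    hits = total = 0
    order = list(truth.subtypes)
    for t in order:
        for other in order:
            if other == t:
                continue
            frame = table.get(other, t)
            for g in truth.planted_su[t]:
                total += 1
                padj = frame["padj"].get(g, np.nan)
                hits += int(np.isfinite(padj) and padj <= 0.01 and frame["log2fc"].get(g, 0) > 0)
    return hits / total


def de_truth_fdr(counts, samples, sf, truth, alpha: float = 0.01):
    """Empirical FDR of padj <= alpha calls against the planted SU truth."""
    table = pairwise_de(counts, samples, sf)
    order = list(truth.subtypes)
    true_de = {
        (g, truth.canonical_pair(t, other))
        for t in order
        for g in truth.planted_su[t]
        for other in order
        if other != t
    }
    calls = false_calls = 0
    for (a, b), frame in table.pairs.items():
        sig = frame.index[(frame["padj"] <= alpha).fillna(False)]
        for g in sig:
            calls += 1
            false_calls += int((g, (a, b)) not in true_de)
    return (false_calls / calls if calls else 0.0), calls


# ---------------------------------------------------------------------------
# full-atlas recoveries

def run_atlas(seed: int, **overrides):
    """Generate the default atlas and run normalization/classes/DE once."""
    from .expression_classes import assign_classes, fit_subtype_mixtures
    from .normalization import normalize

    config = SimConfig(seed=seed, **overrides)
    counts, samples, genes, catalog, compat, truth = generate_all(config)
    sf = size_factors(counts)
    expr = normalize(counts, sf, genes)
    fits = fit_subtype_mixtures(expr, samples)
    classes = assign_classes(expr, samples, fits)
    table = pairwise_de(counts, samples, sf)
    return {
        "config": config,
        "counts": counts,
        "samples": samples,
        "genes": genes,
        "catalog": catalog,
        "compat": compat,
        "truth": truth,
        "sf": sf,
        "expr": expr,
        "fits": fits,
        "classes": classes,
        "table": table,
    }


def su_recovery(atlas: dict):
    """(recall, precision) of SU calling against the planted truth."""
    sets = call_all_su_genes(atlas["table"], atlas["classes"], atlas["genes"])
    truth = atlas["truth"]
    tp = fp = planted = 0
    for t, su in sets.items():
        p = truth.planted_su[t]
        planted += len(p)
        tp += len(set(su.genes) & p)
        fp += len(set(su.genes) - p)
    recall = tp / planted if planted else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    return recall, precision


def clustering_metrics(atlas: dict):
    """(all-sister flag, Rand index of the 6-way cut vs subtype labels)."""
    transformed = rlog_surrogate(atlas["counts"], atlas["sf"])
    dendro = hierarchical_cluster(transformed, axis="samples")
    subtype_of = dict(zip(atlas["samples"]["sample_id"], atlas["samples"]["subtype"]))
    nearest = dendro.cophenetic_nearest()
    all_sisters = all(subtype_of[a] == subtype_of[b] for a, b in nearest.items())
    k = atlas["samples"]["subtype"].nunique()
    cut = dendro.cut(k)
    labels_true = [subtype_of[s] for s in dendro.labels]
    labels_cut = [cut[s] for s in dendro.labels]
    return all_sisters, rand_index(labels_true, labels_cut)


def rand_index(labels_a, labels_b) -> float:
    """Plain Rand index: fraction of agreeing pairs."""
    n = len(labels_a)
    agree = total = 0
    for i, j in combinations(range(n), 2):
        total += 1
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        agree += int(same_a == same_b)
    return agree / total if total else 1.0


def switch_recovery(atlas: dict):
    """(recall, precision) of switch events against planted switches."""
    psi = estimate_psi_table(atlas["compat"], atlas["catalog"], atlas["samples"])
    events = detect_switches(psi, atlas["table"], atlas["classes"], atlas["catalog"])
    detected = {(e.gene_id, e.pair) for e in events}
    planted = atlas["truth"].planted_switches
    tp = len(detected & planted)
    recall = tp / len(planted) if planted else 1.0
    precision = tp / len(detected) if detected else 1.0
    return recall, precision


# ---------------------------------------------------------------------------
# PSI oracle

def closed_form_psi(read_counts, lengths) -> np.ndarray:
    """Length-corrected closed form for unambiguous reads."""
    f = np.asarray(read_counts, float) / np.sum(read_counts)
    psi = f / np.asarray(lengths, float)
    return psi / psi.sum()


def psi_oracle_error() -> float:
    """Max |EM - closed form| over the two canonical unambiguous cases."""
    worst = 0.0
    for counts, lengths in [((30, 70), (1000.0, 1000.0)), ((30, 70), (1000.0, 2000.0))]:
        classes = [(("i1",), counts[0]), (("i2",), counts[1])]
        est = estimate_psi(classes, ["i1", "i2"], lengths)
        worst = max(worst, float(np.max(np.abs(est - closed_form_psi(counts, lengths)))))
    return worst
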