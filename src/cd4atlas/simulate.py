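"""Synthetic CD4+ T-cell atlas generator with planted, recoverable structure.

Emulates the design of the real atlas — six subtypes (Naive, Th1, Th2, Th17,
Treg, iTreg) with two biological replicates each — as a negative-binomial
count matrix over a bimodal (low/high) log2 expression distribution, with
planted subtype-upregulated (SU) genes, multi-isoform genes, and planted
major-isoform switches, plus read–isoform compatibility records for PSI
estimation.  Every planted effect is recorded in :class:`SimTruth` so each
downstream stage can be scored against ground truth.

Key modelling choices (see docs/methods.md for rationale):

* Each gene's base log2 expression is drawn once from the LE/HE mixture and
  shared across subtypes; planted SU effects are therefore the only
  systematic between-subtype differences, which makes truth-based FDR and
  precision estimates well defined.
* Planted SU genes and switch genes are drawn from high-expressed (HE
  component) genes, because the corresponding callers require INT/HE class
  membership by definition; switch genes are never SU genes, so their total
  gene expression is constant across subtypes.
* Non-switch multi-isoform genes have a dominant major isoform (major PSI
  uniform on [0.6, 0.95]), mirroring the major-isoform dominance observed in
  real transcriptomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, DataError

SUBTYPE_NAMES = ("Naive", "Th1", "Th2", "Th17", "Treg", "iTreg")

GENE_CATEGORIES = ("TF", "cytokine", "receptor", "lncRNA", "other")
_CATEGORY_PROBS = (0.05, 0.03, 0.07, 0.10, 0.75)

ISOFORM_GROUPS = ("functional", "truncated", "non_coding")

#: planted PSI of a switch gene: (major, minor) in the reference orientation,
#: reversed in the flipped subtype.
SWITCH_PSI = (0.8, 0.2)

GENE_LENGTH_RANGE_BP = (500, 10_000)


def default_subtype_names(n: int) -> tuple[str, ...]:
    if n <= len(SUBTYPE_NAMES):
        return SUBTYPE_NAMES[:n]
    extra = tuple(f"Sub{i + 1}" for i in range(len(SUBTYPE_NAMES), n))
    return SUBTYPE_NAMES + extra


def _per_subtype(value, n: int, name: str) -> tuple:
    """Broadcast a scalar or per-subtype sequence to a length-``n`` tuple."""
    if np.isscalar(value):
        return (value,) * n
    value = tuple(value)
    if len(value) != n:
        raise ConfigError(f"{name}: expected scalar or {n} values, got {len(value)}")
    return value


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic atlas.

    Defaults reproduce the study design: 6 subtypes x 2 replicates, a
    bimodal log2 expression distribution with components N(1, 1) (LE) and
    N(8, 1) (HE), 50 planted SU genes per subtype at +3 log2 units, mild NB
    overdispersion, and 30 planted isoform switches.
    """

    n_subtypes: int = 6
    n_replicates: int = 2
    n_genes: int = 2000
    le_mean: float = 1.0
    le_sd: float = 1.0
    he_mean: float = 8.0
    he_sd: float = 1.0
    he_weight: float = 0.5
    su_per_subtype: int | Sequence[int] = 50
    su_log2fc: float | Sequence[float] = 3.0
    dispersion: float = 0.05
    depth_factors: Sequence[float] | None = None
    frac_multi_isoform: float = 0.3
    n_switch_genes: int = 30
    reads_per_gene: float = 500.0
    ambiguity_rate: float = 0.3
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_subtypes * self.n_replicates

    @property
    def subtype_names(self) -> tuple[str, ...]:
        return default_subtype_names(self.n_subtypes)

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(
            f"{t}_r{r + 1}"
            for t in self.subtype_names
            for r in range(self.n_replicates)
        )

    def su_counts(self) -> tuple[int, ...]:
        return _per_subtype(self.su_per_subtype, self.n_subtypes, "su_per_subtype")

    def su_effects(self) -> tuple[float, ...]:
        return _per_subtype(self.su_log2fc, self.n_subtypes, "su_log2fc")

    def validate(self) -> None:
        for name in ("n_subtypes", "n_replicates", "n_genes", "n_switch_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name}: must be a non-negative integer, got {v!r}")
        if self.n_subtypes < 1 or self.n_replicates < 1:
            raise ConfigError("n_subtypes/n_replicates: must be >= 1")
        if not 0.0 < self.he_weight < 1.0:
            raise ConfigError(f"he_weight: must be in (0, 1), got {self.he_weight}")
        for name in ("le_sd", "he_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion: must be >= 0, got {self.dispersion}")
        if self.depth_factors is not None:
            df = np.asarray(self.depth_factors, dtype=float)
            if df.shape != (self.n_samples,):
                raise ConfigError(
                    f"depth_factors: expected {self.n_samples} values, got {df.shape}"
                )
            if not np.all(df > 0):
                raise ConfigError("depth_factors: all values must be > 0")
        su_counts = self.su_counts()
        if any(c < 0 for c in su_counts):
            raise ConfigError("su_per_subtype: counts must be >= 0")
        if sum(su_counts) > self.n_genes:
            raise ConfigError(
                f"su_per_subtype: {sum(su_counts)} planted SU genes exceed "
                f"n_genes={self.n_genes}"
            )
        if not 0.0 <= self.frac_multi_isoform <= 1.0:
            raise ConfigError("frac_multi_isoform: must be in [0, 1]")
        if self.n_switch_genes > self.frac_multi_isoform * self.n_genes:
            raise ConfigError(
                "n_switch_genes: exceeds the number of multi-isoform genes "
                f"({self.frac_multi_isoform} x {self.n_genes})"
            )
        if self.reads_per_gene < 0:
            raise ConfigError("reads_per_gene: must be >= 0")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ConfigError("ambiguity_rate: must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth planted by the generator.

    ``planted_component`` maps each gene to its mixture component label
    (constant across subtypes by construction).  ``planted_switches`` holds
    (gene_id, (subtype_a, subtype_b)) pairs in canonical subtype order.
    """

    subtypes: tuple[str, ...]
    planted_su: dict[str, frozenset[str]]
    planted_component: dict[str, str]
    base_means: pd.DataFrame  # genes x subtypes, expected normalized mean
    planted_psi: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)
    planted_switches: set[tuple[str, tuple[str, str]]] = field(default_factory=set)

    def canonical_pair(self, a: str, b: str) -> tuple[str, str]:
        order = {t: i for i, t in enumerate(self.subtypes)}
        return (a, b) if order[a] < order[b] else (b, a)

    def validate(self) -> None:
        seen: set[str] = set()
        for t, genes in self.planted_su.items():
            if seen & set(genes):
                raise ConsistencyError(f"planted SU sets overlap at subtype {t}")
            seen |= set(genes)
        for g, by_subtype in self.planted_psi.items():
            for t, psi in by_subtype.items():
                if abs(sum(psi) - 1.0) > 1e-9:
                    raise ConsistencyError(f"planted PSI for {g}/{t} does not sum to 1")


@dataclass
class CompatibilityData:
    """Read–isoform compatibility, aggregated into compatibility classes.

    ``classes`` has one row per (sample, gene, isoform-set): the isoform ids
    a group of reads is compatible with, and how many reads fall in the
    class.  Per-read triplets are materialized only on serialization.
    """

    classes: pd.DataFrame  # sample_id, gene_id, isoform_ids (tuple), n_reads

    def for_sample_gene(self, sample_id: str, gene_id: str) -> list[tuple[tuple[str, ...], int]]:
        sub = self.classes[
            (self.classes["sample_id"] == sample_id)
            & (self.classes["gene_id"] == gene_id)
        ]
        return list(zip(sub["isoform_ids"], sub["n_reads"]))

    def iter_reads(self):
        """Yield (sample_id, read_id, isoform_id) triplets, one per pairing."""
        counters: dict[str, int] = {}
        for row in self.classes.itertuples(index=False):
            start = counters.get(row.sample_id, 0)
            for k in range(row.n_reads):
                read_id = f"{row.sample_id}.read{start + k:07d}"
                for iso in row.isoform_ids:
                    yield row.sample_id, read_id, iso
            counters[row.sample_id] = start + row.n_reads


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + a*mu^2); a = 0 degrades to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_atlas(config: SimConfig):
    """Generate the synthetic count atlas.

    Returns ``(counts, samples, genes, truth)`` where *counts* is a
    genes x samples integer DataFrame, *samples* the sample sheet,
    *genes* the gene annotation (length_bp, category), and *truth* the
    planted ground truth.  Identical configs (including seed) give
    bitwise-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n_genes, n_sub, n_rep = config.n_genes, config.n_subtypes, config.n_replicates
    subtypes = config.subtype_names
    samples = config.sample_names
    width = max(4, len(str(max(n_genes - 1, 0))))
    gene_ids = [f"G{i:0{width}d}" for i in range(n_genes)]

    lo, hi = GENE_LENGTH_RANGE_BP
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes)).round().astype(int)
    categories = rng.choice(GENE_CATEGORIES, size=n_genes, p=_CATEGORY_PROBS)

    is_he = rng.random(n_genes) < config.he_weight
    base_log2 = np.where(
        is_he,
        rng.normal(config.he_mean, config.he_sd, n_genes),
        rng.normal(config.le_mean, config.le_sd, n_genes),
    )

    # plant SU genes among HE-component genes (the SU rule requires INT/HE)
    su_counts = config.su_counts()
    su_effects = config.su_effects()
    he_pool = [g for g, h in zip(gene_ids, is_he) if h]
    if sum(su_counts) > len(he_pool):
        raise ConfigError(
            f"su_per_subtype: {sum(su_counts)} planted SU genes exceed the "
            f"{len(he_pool)} high-expressed genes available"
        )
    chosen = rng.choice(len(he_pool), size=sum(su_counts), replace=False)
    planted_su: dict[str, frozenset[str]] = {}
    offset = 0
    for t, c in zip(subtypes, su_counts):
        planted_su[t] = frozenset(he_pool[i] for i in chosen[offset : offset + c])
        offset += c

    # expected normalized mean per (gene, subtype): 2^(base + planted effect)
    log2_mean = np.tile(base_log2[:, None], (1, n_sub))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for j, t in enumerate(subtypes):
        for g in planted_su[t]:
            log2_mean[gene_index[g], j] += su_effects[j]
    base_means = pd.DataFrame(2.0 ** log2_mean, index=gene_ids, columns=list(subtypes))

    if config.depth_factors is not None:
        depth = np.asarray(config.depth_factors, dtype=float)
    else:
        depth = np.exp(rng.uniform(np.log(0.5), np.log(2.0), config.n_samples))

    length_kb = lengths / 1000.0
    mu = np.empty((n_genes, config.n_samples))
    for j, _ in enumerate(samples):
        mu[:, j] = base_means.iloc[:, j // n_rep].to_numpy() * depth[j] * length_kb
    counts = pd.DataFrame(
        _nb_draw(rng, mu, config.dispersion), index=gene_ids, columns=list(samples)
    )

    sample_sheet = pd.DataFrame(
        {
            "sample_id": list(samples),
            "subtype": [t for t in subtypes for _ in range(n_rep)],
            "replicate": [r + 1 for _ in subtypes for r in range(n_rep)],
        }
    )
    gene_ann = pd.DataFrame(
        {"length_bp": lengths, "category": categories},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth = SimTruth(
        subtypes=tuple(subtypes),
        planted_su=planted_su,
        planted_component={g: ("HE" if h else "LE") for g, h in zip(gene_ids, is_he)},
        base_means=base_means,
    )
    truth.validate()
    return counts, sample_sheet, gene_ann, truth


def generate_isoform_data(config: SimConfig, truth: SimTruth):
    """Generate the isoform catalog and read–isoform compatibility data.

    Multi-isoform genes get per-subtype planted PSI vectors; switch genes a
    different top-PSI isoform in one subtype versus all others.  Reads come
    from isoform i with probability proportional to PSI x length at a
    uniform position; a fraction of each gene's sequence (controlled by
    ``ambiguity_rate``) is shared pairwise between isoforms, and reads
    falling there are compatible with both isoforms of the pair.

    Returns ``(catalog, compat, truth)`` with *truth* updated in place.
    """
    config.validate()
    if truth.base_means.shape != (config.n_genes, config.n_subtypes) or tuple(
        truth.base_means.columns
    ) != config.subtype_names:
        raise ConsistencyError(
            "truth does not match config: expected base_means of shape "
            f"{(config.n_genes, config.n_subtypes)} over {config.subtype_names}"
        )
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = list(truth.base_means.index)
    subtypes = list(truth.subtypes)
    n_multi = int(round(config.frac_multi_isoform * config.n_genes))

    su_all = set().union(*truth.planted_su.values()) if truth.planted_su else set()
    he_pool = [
        g
        for g in gene_ids
        if truth.planted_component.get(g) == "HE" and g not in su_all
    ]
    if config.n_switch_genes > len(he_pool):
        raise DataError(
            f"n_switch_genes={config.n_switch_genes} exceeds the "
            f"{len(he_pool)} eligible high-expressed non-SU genes"
        )
    switch_genes = list(rng.choice(he_pool, size=config.n_switch_genes, replace=False))
    remaining = [g for g in gene_ids if g not in set(switch_genes)]
    n_other = n_multi - config.n_switch_genes
    other_multi = list(rng.choice(remaining, size=n_other, replace=False))
    multi_genes = sorted(switch_genes + other_multi, key=gene_ids.index)
    switch_set = set(switch_genes)

    lo, hi = GENE_LENGTH_RANGE_BP
    rows = []
    psi_by_gene: dict[str, dict[str, tuple[float, ...]]] = {}
    planted_switches: set[tuple[str, tuple[str, str]]] = set()
    for g in multi_genes:
        k = 2 if g in switch_set else int(rng.integers(2, 5))
        iso_lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), k)).round().astype(int)
        groups = ["functional"] + list(rng.choice(ISOFORM_GROUPS, size=k - 1))
        iso_ids = [f"{g}.{i + 1}" for i in range(k)]
        for iid, L, grp in zip(iso_ids, iso_lengths, groups):
            rows.append((g, iid, int(L), grp))
        if g in switch_set:
            flip = subtypes[int(rng.integers(len(subtypes)))]
            fwd, rev = SWITCH_PSI, SWITCH_PSI[::-1]
            psi_by_gene[g] = {t: (rev if t == flip else fwd) for t in subtypes}
            for t in subtypes:
                if t != flip:
                    planted_switches.add((g, truth.canonical_pair(flip, t)))
        else:
            major = rng.uniform(0.6, 0.95)
            rest = rng.dirichlet(np.ones(k - 1)) * (1.0 - major) if k > 1 else []
            psi = np.concatenate([[major], rest])
            psi = psi[rng.permutation(k)]
            psi /= psi.sum()
            psi_by_gene[g] = {t: tuple(psi) for t in subtypes}

    catalog = pd.DataFrame(rows, columns=["gene_id", "isoform_id", "length_bp", "group"])

    # Read simulation.  Each gene is partitioned into segments: a unique
    # segment per isoform plus a shared segment per isoform pair (ambiguous
    # reads are compatible with exactly 2 isoforms).  A read picks an
    # isoform with probability psi * length and a uniform position, so a
    # segment of physical width w and compatibility set c receives reads
    # with probability w * sum(psi_c) / sum(psi * length) — the same
    # generative model the PSI EM inverts.  Shared widths are
    # ambiguity_rate * min(length_i, length_j) / (k - 1), which keeps every
    # unique segment positive.
    sample_ids = config.sample_names
    subtype_of = {
        s: t for s, t in zip(sample_ids, [t for t in subtypes for _ in range(config.n_replicates)])
    }
    segments_by_gene: dict[str, tuple[list[tuple[str, ...]], np.ndarray, dict]] = {}
    for g in multi_genes:
        sub = catalog[catalog["gene_id"] == g]
        iso_ids = list(sub["isoform_id"])
        lengths = sub["length_bp"].to_numpy(float)
        k = len(iso_ids)
        classes: list[tuple[str, ...]] = [(i,) for i in iso_ids]
        widths = list(lengths)
        if k > 1 and config.ambiguity_rate > 0:
            for i in range(k):
                for j in range(i + 1, k):
                    w = config.ambiguity_rate * min(lengths[i], lengths[j]) / (k - 1)
                    classes.append(tuple(sorted((iso_ids[i], iso_ids[j]))))
                    widths.append(w)
                    widths[i] -= w
                    widths[j] -= w
        index = {iso: m for m, iso in enumerate(iso_ids)}
        segments_by_gene[g] = (classes, np.asarray(widths), index)
    crows = []
    for s in sample_ids:
        t = subtype_of[s]
        for g in multi_genes:
            n_reads = int(rng.poisson(config.reads_per_gene))
            if n_reads == 0:
                continue
            classes, widths, index = segments_by_gene[g]
            psi = np.asarray(psi_by_gene[g][t])
            p = np.array([w * psi[[index[i] for i in c]].sum() for c, w in zip(classes, widths)])
            p = p / p.sum()
            per_class = rng.multinomial(n_reads, p)
            for c, n_c in zip(classes, per_class):
                if n_c > 0:
                    crows.append((s, g, c, int(n_c)))
    compat = CompatibilityData(
        classes=pd.DataFrame(
            crows, columns=["sample_id", "gene_id", "isoform_ids", "n_reads"]
        )
    )
    truth.planted_psi = psi_by_gene
    truth.planted_switches = planted_switches
    truth.validate()
    return catalog, compat, truth


def generate_all(config: SimConfig):
    """Convenience wrapper: atlas plus isoform data in one call."""
    counts, samples, genes, truth = generate_atlas(config)
    catalog, compat, truth = generate_isoform_data(config, truth)
    return counts, samples, genes, catalog, compat, truth
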