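"""End-to-end pipeline orchestration from a flat key=value config file.

Stages run in order: simulate (or load) -> normalize -> classify -> de ->
su -> cluster -> psi -> switches.  All outputs are deterministic functions
of the configuration (including the seed), so a rerun with the same config
is byte-identical.  Stage outputs are the documented TSVs, so any stage can
be re-entered from files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .clustering import hierarchical_cluster, pca, rlog_surrogate, top_variance_genes
from .differential_expression import count_de, pairwise_de
from .errors import AtlasError, ConfigError
from .expression_classes import assign_classes, fit_subtype_mixtures
from .isoforms import detect_switches, estimate_psi_table, group_psi, switches_table
from .normalization import normalize, size_factors
from .simulate import SimConfig, generate_atlas, generate_isoform_data
from .su_genes import call_all_su_genes, categorize_su, su_table

log = logging.getLogger("cd4atlas")

INPUT_KEYS = ("counts", "samples", "genes", "isoforms", "compat")


@dataclass
class PipelineConfig:
    """Run configuration: either file inputs or a simulation block."""

    out_dir: str = "results/run"
    simulate: SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    padj_alpha: float = 0.01
    class_alpha: float = 0.01
    fc_cutoffs: tuple[float, ...] = (0.0, 2.0, 5.0)
    variance_fraction: float = 0.5
    two_fold_threshold: float = 2.0
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        has_inputs = bool(self.inputs)
        if has_inputs == (self.simulate is not None):
            raise ConfigError(
                "config must provide exactly one of: input paths, or a simulate block"
            )
        if has_inputs:
            missing = [k for k in ("counts", "samples", "genes") if k not in self.inputs]
            if missing:
                raise ConfigError(f"missing input path(s): {missing}")
            if ("isoforms" in self.inputs) != ("compat" in self.inputs):
                raise ConfigError("isoforms and compat paths must be given together")
        for name in ("padj_alpha", "class_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}: must be in (0, 1), got {v}")
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ConfigError("variance_fraction: must be in (0, 1]")
        if self.two_fold_threshold < 1.0:
            raise ConfigError("two_fold_threshold: must be >= 1")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file ('#' starts a comment)."""
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        return cls.from_mapping(values, **overrides)

    @classmethod
    def from_mapping(cls, values: dict[str, str], **overrides) -> "PipelineConfig":
        kw: dict = {}
        sim_kw: dict = {}
        simulate_flag = values.pop("simulate", "false").lower() in ("1", "true", "yes")
        inputs = {k: values.pop(k) for k in list(values) if k in INPUT_KEYS}
        sim_fields = {f.name: f.type for f in dataclasses.fields(SimConfig)}
        for key, value in values.items():
            if key.startswith("sim."):
                name = key[4:]
                if name not in sim_fields:
                    raise ConfigError(f"unknown simulate key: {key}")
                sim_kw[name] = _parse_value(value)
            elif key == "fc_cutoffs":
                kw["fc_cutoffs"] = tuple(float(v) for v in value.split(","))
            elif key in ("padj_alpha", "class_alpha", "variance_fraction", "two_fold_threshold"):
                kw[key] = float(value)
            elif key in ("seed", "verbosity"):
                kw[key] = int(value)
            elif key in ("out_dir", "out"):
                kw["out_dir"] = value
            else:
                raise ConfigError(f"unknown config key: {key}")
        kw["inputs"] = inputs
        if simulate_flag or sim_kw:
            if "seed" in kw:
                sim_kw.setdefault("seed", kw["seed"])
            kw["simulate"] = SimConfig(**sim_kw)
        kw.update(overrides)
        if "seed" in overrides and kw.get("simulate") is not None:
            kw["simulate"] = dataclasses.replace(kw["simulate"], seed=overrides["seed"])
        config = cls(**kw)
        config.validate()
        return config


def _parse_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if "," in text:
        return tuple(_parse_value(v) for v in text.split(","))
    return text


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all outputs plus a run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    report: dict = {
        "versions": {
            "cd4atlas": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": {
            "padj_alpha": config.padj_alpha,
            "class_alpha": config.class_alpha,
            "fc_cutoffs": list(config.fc_cutoffs),
            "variance_fraction": config.variance_fraction,
            "two_fold_threshold": config.two_fold_threshold,
        },
        "stages": {},
    }
    stage = "setup"
    try:
        if config.simulate is not None:
            stage = "simulate"
            log.info("stage=%s generating synthetic atlas", stage)
            counts, samples, genes, truth = generate_atlas(config.simulate)
            catalog, compat, truth = generate_isoform_data(config.simulate, truth)
            io.write_fixture(out, counts, samples, genes, truth, catalog, compat)
            report["stages"]["simulate"] = {
                "n_genes": int(counts.shape[0]),
                "n_samples": int(counts.shape[1]),
                "n_multi_isoform_genes": int(catalog["gene_id"].nunique()),
            }
        else:
            stage = "load"
            log.info("stage=%s reading inputs", stage)
            counts = io.read_counts(config.inputs["counts"])
            samples = io.read_samples(config.inputs["samples"])
            genes = io.read_genes(config.inputs["genes"])
            catalog = compat = None
            if "isoforms" in config.inputs:
                catalog = io.read_isoforms(config.inputs["isoforms"])
                compat = io.read_compat(config.inputs["compat"], catalog)
            report["stages"]["load"] = {
                "n_genes": int(counts.shape[0]),
                "n_samples": int(counts.shape[1]),
            }

        stage = "normalize"
        log.info("stage=%s size factors + length normalization", stage)
        sf = size_factors(counts)
        expr = normalize(counts, sf, genes)
        sf.to_frame().to_csv(out / "size_factors.tsv", sep="\t", float_format=io.FLOAT_FORMAT)
        io.write_matrix(expr, out / "normalized.tsv")
        report["stages"]["normalize"] = {
            "size_factors": {k: round(float(v), 6) for k, v in sf.items()}
        }

        stage = "classify"
        log.info("stage=%s mixture fits + class assignment", stage)
        fits = fit_subtype_mixtures(expr, samples, alpha=config.class_alpha)
        classes = assign_classes(expr, samples, fits)
        fit_rows = [
            (
                t,
                f.mu_le,
                f.sd_le,
                f.mu_he,
                f.sd_he,
                f.weight_he,
                b.b_low,
                b.b_high,
            )
            for t, (f, b) in fits.items()
        ]
        pd.DataFrame(
            fit_rows,
            columns=[
                "subtype",
                "mu_le",
                "sd_le",
                "mu_he",
                "sd_he",
                "weight_he",
                "b_low",
                "b_high",
            ],
        ).to_csv(out / "mixture_fits.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
        classes.stack().rename("class").rename_axis(["gene_id", "subtype"]).reset_index().to_csv(
            out / "classes.tsv", sep="\t", index=False
        )
        report["stages"]["classify"] = {
            t: dict(classes[t].value_counts().sort_index()) for t in classes.columns
        }
        report["stages"]["classify"] = {
            t: {k: int(v) for k, v in d.items()}
            for t, d in report["stages"]["classify"].items()
        }

        stage = "de"
        log.info("stage=%s pairwise NB Wald tests", stage)
        table = pairwise_de(
            counts, samples, sf, alpha=config.padj_alpha, fc_cutoffs=config.fc_cutoffs
        )
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        for (a, b), frame in table.pairs.items():
            io.write_matrix(frame, de_dir / f"{a}_vs_{b}.tsv")
        de_counts = count_de(table)
        de_counts.to_csv(out / "de_counts.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
        report["stages"]["de"] = {"n_pairs": len(table.pairs)}

        stage = "su"
        log.info("stage=%s subtype-upregulated gene calling", stage)
        su_sets = call_all_su_genes(table, classes, genes)
        su_table(su_sets).to_csv(
            out / "su_genes.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
        )
        categorize_su(su_sets).to_csv(out / "su_categories.tsv", sep="\t", index=False)
        report["stages"]["su"] = {t: len(s) for t, s in su_sets.items()}

        stage = "cluster"
        log.info("stage=%s rlog surrogate, clustering, PCA", stage)
        transformed = rlog_surrogate(counts, sf)
        dendro_samples = hierarchical_cluster(transformed, axis="samples")
        (out / "dendrogram_samples.newick").write_text(dendro_samples.to_newick() + "\n")
        top = top_variance_genes(transformed, config.variance_fraction)
        dendro_genes = hierarchical_cluster(transformed.loc[top], axis="genes")
        (out / "dendrogram_genes.newick").write_text(dendro_genes.to_newick() + "\n")
        pca_res = pca(transformed)
        scores = pca_res.scores.copy()
        scores.columns = [
            f"{c} ({frac:.4f})" for c, frac in zip(scores.columns, pca_res.explained)
        ]
        io.write_matrix(scores, out / "pca.tsv", index_label="sample_id")
        report["stages"]["cluster"] = {
            "n_top_variance_genes": int(len(top)),
            "pc1_explained": round(float(pca_res.explained[0]), 6),
        }

        if catalog is not None and compat is not None and len(compat.classes):
            stage = "psi"
            log.info("stage=%s isoform PSI estimation", stage)
            psi = estimate_psi_table(compat, catalog, samples)
            psi.sample_psi.to_csv(
                out / "psi.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
            )
            group_psi(psi, catalog).to_csv(
                out / "psi_groups.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
            )
            report["stages"]["psi"] = {
                "n_genes": int(psi.sample_psi["gene_id"].nunique())
            }

            stage = "switches"
            log.info("stage=%s transcript-switch detection", stage)
            events = detect_switches(
                psi,
                table,
                classes,
                catalog,
                alpha=config.padj_alpha,
                two_fold_threshold=config.two_fold_threshold,
            )
            sw = switches_table(events)
            sw.to_csv(out / "switches.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT)
            per_pair = sw.groupby("pair").size() if len(sw) else pd.Series(dtype=int)
            n_pairs = len(table.pairs)
            report["stages"]["switches"] = {
                "n_events": int(len(sw)),
                "n_two_fold": int(sw["two_fold"].sum()) if len(sw) else 0,
                "mean_per_pair": round(float(len(sw)) / n_pairs, 4) if n_pairs else 0.0,
                "per_pair": {k: int(v) for k, v in per_pair.items()},
            }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        log.error("stage=%s failed: %s", stage, exc)
        if isinstance(exc, AtlasError):
            exc.stage = stage  # type: ignore[attr-defined]
        raise

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", report_path)
    return report
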