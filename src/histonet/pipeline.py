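"""End-to-end orchestration: quantify -> regress -> pcnet -> combos -> crosscell.

A single :class:`RunConfig` drives the whole analysis, either on annotation
and read files or on a named synthetic preset; every stochastic stage takes
an explicit seed derived from the master seed, so a repeated run writes
byte-identical outputs.  Defaults are the analysis constants: pseudocount
0.01, 100 bp read extension, 4,001 bp promoter window, 10 CV folds, 100
permutations, 20% BIC-difference fraction.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import combos, crosscell, pcnet, quantify, regress, synth
from .intervals import read_alt_events, read_bed6_reads, read_gene_models

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(slots=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: Path
    preset: str | None = "small"
    m: int | None = None
    annotation: Path | None = None
    annotation_format: str = "refFlat"
    alt_table: Path | None = None
    rna_reads: Path | None = None
    chip_reads: dict[str, Path] = field(default_factory=dict)
    pseudocount: float = quantify.DEFAULT_PSEUDOCOUNT
    extension: int = quantify.DEFAULT_EXTENSION
    promoter_window: int = quantify.DEFAULT_PROMOTER_WINDOW
    cv_folds: int = 10
    n_perm: int = 100
    bic_fraction: float = 0.2
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        out_dir = Path(raw.pop("out_dir"))
        cfg = cls(out_dir=out_dir)
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"config: unknown key {key!r}")
            if key in ("annotation", "alt_table", "rna_reads"):
                value = Path(value)
            elif key == "chip_reads":
                value = {k: Path(v) for k, v in value.items()}
            setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        if self.preset is None:
            for name, path in (
                ("annotation", self.annotation),
                ("alt_table", self.alt_table),
                ("rna_reads", self.rna_reads),
            ):
                if path is None:
                    raise PipelineError(f"config: {name} path required when no preset is named")
                if not Path(path).exists():
                    raise PipelineError(f"config: {name} path {path} does not exist")
            if not self.chip_reads:
                raise PipelineError("config: at least one chip_reads track required")
            for feat, path in self.chip_reads.items():
                if not Path(path).exists():
                    raise PipelineError(f"config: chip_reads[{feat}] path {path} does not exist")
        elif self.preset not in synth.PRESETS:
            raise PipelineError(f"config: unknown preset {self.preset!r}")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def _quantify_stage(cfg: RunConfig, out: Path) -> tuple[pd.DataFrame, dict]:
    """Produce the per-exon analysis matrix and the quantification report section."""
    if cfg.preset is not None:
        # Read-level round trip on a toy genome drawn from the preset model.
        genome = synth.GenomeSpec(n_genes=20, exons_per_gene=5, exon_len=400)
        data, _ = synth.scenario(cfg.preset, m=genome.n_exons, seed=cfg.seed + 11)
        feature_cols = [c for c in data.columns if c not in (synth.GENE_COL, synth.EXON_COL)]
        signals = synth.scale_to_density(data[feature_cols])
        if synth.EXON_COL in data.columns:
            expr = synth.scale_to_density(data[synth.EXON_COL])
        else:
            expr = pd.Series(-1.0, index=data.index)
        sim = synth.make_read_level(
            signals, expr, out / "readlevel", genome=genome,
            pseudocount=cfg.pseudocount, seed=cfg.seed + 13,
        )
        genes = read_gene_models(sim.annotation, "refFlat")
        exons = quantify.classify_exons(genes, read_alt_events(sim.alt_table))
        chip = {f: read_bed6_reads(p) for f, p in sim.chip_reads.items()}
        qr = quantify.quantify_dataset(
            genes, exons, chip, read_bed6_reads(sim.rna_reads),
            cfg.pseudocount, cfg.extension, cfg.promoter_window,
        )
        # recovery: generated vs recovered log2 densities on analyzable exons
        truth_rows = signals.copy()
        truth_rows.index = [sim.exon_of_row[r] for r in signals.index]
        common = qr.exon_signals.index.intersection(truth_rows.index)
        rho = stats.spearmanr(
            truth_rows.loc[common].to_numpy().ravel(),
            qr.exon_signals.loc[common, truth_rows.columns].to_numpy().ravel(),
        )[0]
        section = {
            "mode": "synthetic_read_level",
            "n_genes": len(genes),
            "n_internal_exons": len(exons),
            "n_cassette": len(qr.exon_set("cassette")),
            "n_constitutive": len(qr.exon_set("constitutive")),
            "recovery_spearman": round(float(rho), 6),
        }
        matrix, _ = synth.scenario(cfg.preset, m=cfg.m, seed=cfg.seed)
    else:
        genes = read_gene_models(cfg.annotation, cfg.annotation_format)
        exons = quantify.classify_exons(genes, read_alt_events(cfg.alt_table))
        chip = {f: read_bed6_reads(p) for f, p in cfg.chip_reads.items()}
        qr = quantify.quantify_dataset(
            genes, exons, chip, read_bed6_reads(cfg.rna_reads),
            cfg.pseudocount, cfg.extension, cfg.promoter_window,
        )
        gene_of_exon = qr.gene_of_exon
        matrix = qr.exon_signals.copy()
        matrix[synth.GENE_COL] = [
            qr.gene_expression[gene_of_exon[e]] for e in matrix.index
        ]
        matrix[synth.EXON_COL] = qr.exon_expression
        section = {
            "mode": "files",
            "n_genes": len(genes),
            "n_internal_exons": len(exons),
            "n_cassette": len(qr.exon_set("cassette")),
            "n_constitutive": len(qr.exon_set("constitutive")),
        }
    _write_tsv(qr.exon_signals, out / "exon_signals.tsv")
    _write_tsv(qr.gene_signals, out / "gene_signals.tsv")
    _write_tsv(qr.promoter_signals, out / "promoter_signals.tsv")
    _write_tsv(matrix, out / "analysis_matrix.tsv")
    return matrix, section


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Returns the report dict (also written as ``report.json``) with sections
    quantify, cross_validation, transfer, network_threshold, network_edges,
    bins, stepwise_bic.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "preset": config.preset}

    stage = "quantify"
    try:
        matrix, report["quantify"] = _quantify_stage(config, out)

        stage = "regress"
        features = [c for c in matrix.columns if c != synth.EXON_COL]
        X, y = matrix[features], matrix[synth.EXON_COL]
        cv_single = regress.cross_validate(X, y, k=config.cv_folds, seed=config.seed)
        cv_inter = regress.cross_validate(
            X, y, k=config.cv_folds, seed=config.seed, interactions=True
        )
        shuffled = regress.shuffle_control(X, y, k=config.cv_folds, seed=config.seed)
        fit = regress.fit_linear(X, y, interactions=True)
        _write_tsv(fit.coefficient_table(), out / "coefficients.tsv")
        report["cross_validation"] = {
            "r_singleton": round(cv_single.mean_r, 6),
            "r_interaction": round(cv_inter.mean_r, 6),
            "improvement_ratio": round(
                regress.improvement_ratio(cv_single.mean_r, cv_inter.mean_r), 6
            ),
            "r_shuffled": round(shuffled.mean_r, 6),
            "n_significant_interactions": int(
                sum(":" in t for t in fit.significant(0.001))
            ),
        }

        stage = "pcnet"
        pcors = pcnet.pairwise_partial_correlations(matrix)
        trace = pcnet.bic_trace(matrix, pcors)
        threshold = pcnet.select_threshold(trace, config.bic_fraction)
        perm = pcnet.permutation_null(
            matrix, threshold, n_perm=config.n_perm, seed=config.seed + 1
        )
        net = pcnet.build_network(pcors, threshold, response=synth.EXON_COL)
        _write_tsv(pcors, out / "partial_correlations.tsv")
        _write_tsv(trace.to_frame(), out / "bic_trace.tsv", index=False)
        _write_tsv(net.edges, out / "edges.tsv", index=False)
        report["network_threshold"] = {
            "threshold": round(threshold, 6),
            "n_edges": int(net.graph.number_of_edges()),
            "z": round(perm.z, 4),
            "max_null_pcor": round(perm.max_abs_null, 6),
            "n_perm": config.n_perm,
        }
        report["network_edges"] = [
            [a, b, round(float(pcors.loc[a, b]), 6)] for a, b in trace.selected_edges()
        ]

        stage = "combos"
        pc_resp = pcors[synth.EXON_COL].drop(synth.EXON_COL).drop(
            synth.GENE_COL, errors="ignore"
        )
        order = list(pc_resp.abs().sort_values(ascending=False).index)
        f1, f2 = order[0], order[1]
        bins = combos.median_bins(matrix[f1], matrix[f2])
        summary, pairwise = combos.bin_summary(bins, y)
        _write_tsv(summary, out / "bin_summary.tsv")
        _write_tsv(pairwise, out / "bin_tests.tsv", index=False)
        steps = combos.stepwise_bic_by_pcor(matrix, synth.EXON_COL, order)
        _write_tsv(steps, out / "stepwise_bic.tsv", index=False)
        clustered, feat_order = combos.cluster_matrix_export(matrix[order], y)
        _write_tsv(clustered, out / "clustered_matrix.tsv")
        net_tests = combos.network_combination_tests(net, matrix, k=config.cv_folds, seed=config.seed)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "response": c.response,
                        "features": ",".join(c.features),
                        "r_singleton": c.p_singleton,
                        "r_interaction": c.p_interaction,
                        "improvement_ratio": c.improvement_ratio,
                    }
                    for c in net_tests
                ]
            ),
            out / "network_combination_tests.tsv",
            index=False,
        )
        report["bins"] = {
            "pair": [f1, f2],
            "bin_means": {k: round(v, 6) for k, v in summary["mean"].items()},
        }
        report["stepwise_bic"] = [
            [row.added, round(row.bic, 4)] for row in steps.itertuples()
        ]

        stage = "crosscell"
        if config.preset is not None:
            data2, shifted, affine = synth.make_second_cell(
                matrix,
                synth.scenario(config.preset, m=config.m, seed=config.seed)[1],
                affine_spec={c: (1.2, 0.3) for c in matrix.columns},
                fold=2.0,
                shift_fraction=0.1,
                seed=config.seed + 2,
            )
            cc = crosscell.cross_cell_pipeline(
                data2[features], data2[synth.EXON_COL], X, y
            )
            report["transfer"] = {
                "r_all": round(cc.r_all, 6),
                "r_by_fold": {
                    str(int(f)): (None if r is None else round(r, 6))
                    for f, r in cc.r_by_fold.items()
                },
                "n_by_fold": {str(int(f)): n for f, n in cc.n_by_fold.items()},
                "n_shifted": len(shifted),
            }
        else:
            report["transfer"] = {"skipped": "no second cell type provided"}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    lines = ["# histonet pipeline report", ""]
    for section in (
        "quantify", "cross_validation", "transfer",
        "network_threshold", "network_edges", "bins", "stepwise_bic",
    ):
        lines.append(f"## {section}")
        lines.append("```json")
        lines.append(json.dumps(report[section], indent=2, sort_keys=True))
        lines.append("```")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
    return report
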