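#!/usr/bin/env python
"""Generate the synthetic study datasets used by the downstream analyses.

Writes bulk data (matrices, read files) under scratch/sim/ and a compact
summary under results/sim/:
  * the default per-exon feature/expression matrix ("small" preset: 10
    marks + gene + exon expression, m = 2000) and its generating truth;
  * the 10-node Gaussian-graphical-model matrix for network recovery;
  * a read-level toy genome (30 genes x 5 exons, 5 marks + RNA) whose read
    densities realize the small preset's signals;
  * a distorted second cell type with 10% of exons shifted >= 2-fold.
"""

import argparse
import json
from pathlib import Path

from histonet import synth

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    out = ROOT / "scratch" / "sim"
    out.mkdir(parents=True, exist_ok=True)
    res = ROOT / "results" / "sim"
    res.mkdir(parents=True, exist_ok=True)

    data, truth = synth.scenario("small", seed=seed)
    data.to_csv(out / "small_matrix.tsv", sep="\t", float_format="%.8g")
    truth.true_pcor().to_csv(out / "small_true_pcor.tsv", sep="\t", float_format="%.8g")
    print(f"small preset: {data.shape[0]} exons x {data.shape[1]} variables")
    print(f"  exon-expression drivers: {sorted(truth.exon_coeffs)} + gene_expr")

    ggm, ggm_truth = synth.scenario("ggm10", seed=seed)
    ggm.to_csv(out / "ggm10_matrix.tsv", sep="\t", float_format="%.8g")
    print(f"ggm10 preset: {len(ggm_truth.true_edges())} true edges among 10 marks")

    genome = synth.GenomeSpec(n_genes=30, exons_per_gene=5, exon_len=400)
    rl_data, rl_truth = synth.scenario("small", m=genome.n_exons, seed=seed + 100)
    feats = rl_truth.feature_names[:5]
    signals = synth.scale_to_density(rl_data[feats])
    expr = synth.scale_to_density(rl_data["exon_expr"])
    sim = synth.make_read_level(signals, expr, out / "readlevel", genome=genome, seed=seed + 101)
    signals.to_csv(out / "readlevel_true_signals.tsv", sep="\t", float_format="%.8g")
    (out / "readlevel_exon_map.json").write_text(json.dumps(sim.exon_of_row, indent=0))
    n_reads = sum(1 for p in sim.chip_reads.values() for _ in open(p))
    print(f"read level: {genome.n_genes} genes, {genome.n_exons} exons, {n_reads} ChIP reads")

    cell2, shifted, _ = synth.make_second_cell(
        data, truth,
        affine_spec={c: (1.3, 0.5) for c in data.columns},
        fold=2.0, shift_fraction=0.1, seed=seed + 200,
    )
    cell2.to_csv(out / "second_cell_matrix.tsv", sep="\t", float_format="%.8g")
    (out / "second_cell_shifted_ids.json").write_text(json.dumps(shifted, indent=0))
    print(f"second cell: affine 1.3x+0.5 on every variable, {len(shifted)} exons shifted >= 2-fold")
    (res / "summary.json").write_text(
        json.dumps(
            {
                "small": {"m": len(data), "variables": list(data.columns)},
                "ggm10_true_edges": len(ggm_truth.true_edges()),
                "readlevel": {"genes": genome.n_genes, "exons": genome.n_exons, "chip_reads": n_reads},
                "second_cell_shifted": len(shifted),
                "data_dir": str(out),
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
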