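"""Synthetic data with known ground truth for every analysis stage.

Three generators, all pure functions of (parameters, seed):

* :func:`make_feature_scenario` draws per-exon chromatin-feature vectors
  from a Gaussian graphical model with a declared precision matrix, then
  optionally wires a gene-expression column (linear in a few features) and
  an exon-expression column (linear in gene expression plus designated
  "driver" marks, optionally with product interaction terms).  The returned
  :class:`SyntheticTruth` carries the implied joint precision matrix, so
  true full-conditional partial correlations and the true edge set are
  available in closed form.

* :func:`make_read_level` inverts the quantification pipeline on a toy
  genome: per-region read counts are Poisson with rate
  ``region_bp * (2**signal - pseudocount)``, and 25 bp stranded reads are
  placed uniformly inside each exon, so extend -> count -> normalize -> log
  recovers the generating signals.

* :func:`make_second_cell` produces a related cell type: the same exons
  with jittered latent feature values, per-variable affine distortions, and
  a designated subset of exons whose expression is shifted by at least
  log2(fold).

The default mark names and driver pair (H3K36me3, H4K20me1) mirror the
marks that dominate exon-expression prediction in CD4+ T-cell data; the
generator makes no attempt to model nucleosome positioning, peak shape or
mappability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import DEFAULT_PSEUDOCOUNT

__all__ = [
    "SyntheticTruth",
    "GenomeSpec",
    "make_feature_scenario",
    "make_read_level",
    "make_second_cell",
    "scenario",
    "scale_to_density",
    "PRESETS",
]

DEFAULT_MARKS = [
    "H3K36me3",
    "H4K20me1",
    "H3K4me1",
    "H3K4me3",
    "H3K79me1",
    "H3K79me2",
    "H2BK5me1",
    "H3K9me3",
    "H3K27me3",
    "RNAPII",
]

GENE_COL = "gene_expr"
EXON_COL = "exon_expr"


def _precision_from_edges(
    n: int, edges: list[tuple[int, int, float]]
) -> np.ndarray:
    """Unit-diagonal precision matrix with off-diagonals set to -pcor.

    With a unit diagonal the implied partial correlation of a declared edge
    equals its requested value exactly.
    """
    omega = np.eye(n)
    for i, j, pcor in edges:
        omega[i, j] = omega[j, i] = -pcor
    w = np.linalg.eigvalsh(omega)
    if w[0] <= 0:
        raise ValueError(f"precision matrix not positive definite (min eigenvalue {w[0]:.4g})")
    return omega


def append_linear_child(omega: np.ndarray, beta: np.ndarray, noise_var: float) -> np.ndarray:
    """Joint precision after adding child = beta'Z + noise to parents with precision ``omega``."""
    n = omega.shape[0]
    out = np.empty((n + 1, n + 1))
    out[:n, :n] = omega + np.outer(beta, beta) / noise_var
    out[:n, n] = -beta / noise_var
    out[n, :n] = -beta / noise_var
    out[n, n] = 1.0 / noise_var
    return out


@dataclass(slots=True)
class SyntheticTruth:
    """Generating parameters of a feature scenario, sufficient to score recovery.

    ``precision`` is the joint precision over all emitted columns (None when
    interaction terms make the joint non-Gaussian); ``true_pcor`` and
    ``true_edges`` derive from it.
    """

    variables: list[str]
    feature_names: list[str]
    feature_precision: np.ndarray
    gene_coeffs: dict[str, float] | None
    gene_noise_sd: float
    exon_coeffs: dict[str, float] | None
    exon_gene_coef: float
    exon_noise_sd: float
    interaction_coeffs: dict[tuple[str, str], float]
    precision: np.ndarray | None
    seed: int

    def true_pcor(self) -> pd.DataFrame:
        if self.precision is None:
            raise ValueError("joint precision unavailable (interaction terms present)")
        om = self.precision
        dd = np.sqrt(np.outer(np.diag(om), np.diag(om)))
        pc = -om / dd
        np.fill_diagonal(pc, 1.0)
        return pd.DataFrame(pc, index=self.variables, columns=self.variables)

    def true_edges(self, tol: float = 1e-9) -> set[frozenset[str]]:
        pc = self.true_pcor()
        cols = list(pc.columns)
        return {
            frozenset((a, b))
            for i, a in enumerate(cols)
            for b in cols[i + 1 :]
            if abs(pc.loc[a, b]) > tol
        }

    def regression_r(self) -> float:
        """Population correlation sqrt(R^2) of exon expression on all other columns.

        Closed form for linear scenarios: with predictor covariance S and
        generating coefficients beta, R^2 = beta'S beta / (beta'S beta + sd^2).
        """
        if self.precision is None:
            raise ValueError("no closed form with interaction terms")
        if self.exon_coeffs is None:
            raise ValueError("scenario has no exon-expression column")
        sigma = np.linalg.inv(self.precision)
        pred = [v for v in self.variables if v != EXON_COL]
        idx = [self.variables.index(v) for v in pred]
        beta = np.array(
            [
                self.exon_coeffs.get(v, 0.0) if v != GENE_COL else self.exon_gene_coef
                for v in pred
            ]
        )
        s = sigma[np.ix_(idx, idx)]
        signal = float(beta @ s @ beta)
        return math.sqrt(signal / (signal + self.exon_noise_sd**2))


def _draw(truth: SyntheticTruth, m: int, rng: np.random.Generator,
          latent: np.ndarray | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw m rows from the generative model; returns (data, latent features)."""
    n = len(truth.feature_names)
    if latent is None:
        cov = np.linalg.inv(truth.feature_precision)
        chol = np.linalg.cholesky(cov)
        latent = rng.standard_normal((m, n)) @ chol.T
    cols: dict[str, np.ndarray] = {
        name: latent[:, i] for i, name in enumerate(truth.feature_names)
    }
    if truth.gene_coeffs is not None:
        gene = sum(
            c * cols[f] for f, c in truth.gene_coeffs.items()
        ) + truth.gene_noise_sd * rng.standard_normal(m)
        cols[GENE_COL] = np.asarray(gene)
    if truth.exon_coeffs is not None:
        exon = sum(c * cols[f] for f, c in truth.exon_coeffs.items())
        exon = np.asarray(exon, dtype=float) if not np.isscalar(exon) else np.zeros(m)
        if truth.gene_coeffs is not None:
            exon = exon + truth.exon_gene_coef * cols[GENE_COL]
        for (fa, fb), c in truth.interaction_coeffs.items():
            exon = exon + c * cols[fa] * cols[fb]
        exon = exon + truth.exon_noise_sd * rng.standard_normal(m)
        cols[EXON_COL] = exon
    data = pd.DataFrame(cols, index=[f"exon_{i:05d}" for i in range(m)])
    data.index.name = "row_id"
    return data, latent


def make_feature_scenario(
    n_features: int = 10,
    m: int = 2000,
    seed: int = 0,
    feature_edges: list[tuple[int, int, float]] | None = None,
    feature_names: list[str] | None = None,
    gene_coeffs: dict[str, float] | None = None,
    gene_noise_sd: float = 0.7,
    exon_coeffs: dict[str, float] | None = None,
    exon_gene_coef: float = 0.0,
    exon_noise_sd: float = 0.6,
    interaction_coeffs: dict[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw an m x V data matrix from a declared Gaussian graphical model.

    Rows are i.i.d.; feature columns follow N(0, Omega^-1) for the precision
    implied by ``feature_edges`` (entries ``(i, j, pcor)``).  ``gene_coeffs``
    and ``exon_coeffs`` wire optional gene- and exon-expression columns as
    linear functions with Gaussian noise; ``interaction_coeffs`` adds product
    terms (and voids the closed-form joint precision).
    """
    if feature_names is None:
        base = list(DEFAULT_MARKS)
        while len(base) < n_features:
            base.append(f"mark{len(base) + 1:02d}")
        feature_names = base[:n_features]
    if len(feature_names) != n_features:
        raise ValueError("feature_names length mismatch")
    omega_f = _precision_from_edges(n_features, feature_edges or [])
    interaction_coeffs = dict(interaction_coeffs or {})

    variables = list(feature_names)
    precision: np.ndarray | None = omega_f
    if gene_coeffs is not None:
        beta_g = np.array([gene_coeffs.get(f, 0.0) for f in feature_names])
        precision = append_linear_child(precision, beta_g, gene_noise_sd**2)
        variables.append(GENE_COL)
    if exon_coeffs is not None:
        beta_e = np.array(
            [exon_coeffs.get(v, 0.0) for v in variables[:-1]]
            if gene_coeffs is not None
            else [exon_coeffs.get(v, 0.0) for v in variables]
        )
        beta_e = np.append(beta_e, exon_gene_coef) if gene_coeffs is not None else beta_e
        precision = append_linear_child(precision, beta_e, exon_noise_sd**2)
        variables.append(EXON_COL)
    if interaction_coeffs:
        precision = None  # joint is no longer Gaussian

    truth = SyntheticTruth(
        variables=variables,
        feature_names=list(feature_names),
        feature_precision=omega_f,
        gene_coeffs=gene_coeffs,
        gene_noise_sd=gene_noise_sd,
        exon_coeffs=exon_coeffs,
        exon_gene_coef=exon_gene_coef,
        exon_noise_sd=exon_noise_sd,
        interaction_coeffs=interaction_coeffs,
        precision=precision,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    data, _ = _draw(truth, m, rng)
    return data, truth


# ---------------------------------------------------------------------------
# Presets: the study conditions exercised by the analysis scripts and tests
# ---------------------------------------------------------------------------

_SMALL_EDGES = [
    (2, 3, 0.35),   # H3K4me1 - H3K4me3
    (4, 5, 0.40),   # H3K79me1 - H3K79me2
    (6, 2, 0.30),   # H2BK5me1 - H3K4me1
    (7, 8, 0.35),   # H3K9me3 - H3K27me3
    (3, 9, 0.30),   # H3K4me3 - RNAPII
]


def _preset_small(m: int, seed: int, interaction: float = 0.0):
    kwargs: dict = dict(
        n_features=10,
        m=m,
        seed=seed,
        feature_edges=_SMALL_EDGES,
        gene_coeffs={"H3K4me3": 0.5, "RNAPII": 0.4},
        gene_noise_sd=0.7,
        exon_coeffs={"H3K36me3": 0.7, "H4K20me1": 0.5},
        exon_gene_coef=0.6,
        exon_noise_sd=0.6,
    )
    if interaction:
        kwargs["interaction_coeffs"] = {("H3K36me3", "H4K20me1"): interaction}
    return make_feature_scenario(**kwargs)


def _preset_ggm10(m: int, seed: int):
    ring = [(i, (i + 1) % 10, 0.3) for i in range(10)]
    return make_feature_scenario(n_features=10, m=m, seed=seed, feature_edges=ring)


def _preset_single_driver(m: int, seed: int):
    return make_feature_scenario(
        n_features=10,
        m=m,
        seed=seed,
        exon_coeffs={"H3K36me3": 2.0},
        exon_noise_sd=0.5,
    )


def _preset_full_scale(m: int, seed: int):
    edges = [(i, i + 1, 0.3) for i in range(0, 38, 2)]
    return make_feature_scenario(
        n_features=39,
        m=m,
        seed=seed,
        feature_edges=edges,
        gene_coeffs={"H3K4me3": 0.5, "RNAPII": 0.4},
        exon_coeffs={"H3K36me3": 0.7, "H4K20me1": 0.5},
        exon_gene_coef=0.6,
    )


PRESETS: dict[str, dict] = {
    "small": {"builder": _preset_small, "m": 2000},
    "interaction": {"builder": lambda m, seed: _preset_small(m, seed, interaction=0.8), "m": 5000},
    "ggm10": {"builder": _preset_ggm10, "m": 2000},
    "single_driver": {"builder": _preset_single_driver, "m": 2000},
    "full_scale": {"builder": _preset_full_scale, "m": 17713},
}


def scenario(name: str, m: int | None = None, seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Build a named preset scenario; ``m`` overrides the preset sample size."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    preset = PRESETS[name]
    return preset["builder"](m or preset["m"], seed)


def scale_to_density(z: pd.Series | pd.DataFrame, mean_log2: float = -1.0, sd: float = 0.5):
    """Map standardized scenario values onto a realistic log2 read-density scale."""
    return mean_log2 + sd * z


# ---------------------------------------------------------------------------
# Read-level toy genome
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class GenomeSpec:
    """Layout of the toy genome: genes laid head-to-tail on one chromosome."""

    n_genes: int = 30
    exons_per_gene: int = 5
    exon_len: int = 400
    intron_len: int = 500
    gene_gap: int = 2000
    read_len: int = 25
    chrom: str = "chrS1"

    @property
    def n_exons(self) -> int:
        return self.n_genes * self.exons_per_gene


@dataclass(slots=True)
class ReadLevelData:
    """File paths and row mapping for a simulated read-level dataset."""

    annotation: Path          # refFlat
    alt_table: Path           # BED6+1, cassette rows
    rna_reads: Path           # BED6
    chip_reads: dict[str, Path]
    exon_of_row: dict[str, str]   # scenario row id -> genomic exon id
    genome: GenomeSpec


def _emit_reads(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    end: int,
    signal: float,
    read_len: int,
    pseudocount: float,
) -> list[tuple[int, int, str]]:
    region_bp = end - start
    rate = region_bp * (2.0**signal - pseudocount)
    if rate < 0:
        raise ValueError(
            f"signal {signal:.3f} implies negative read rate (below the pseudocount floor)"
        )
    count = rng.poisson(rate) if rate > 0 else 0
    reads = []
    for _ in range(count):
        s = int(rng.integers(start, end - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append((s, s + read_len, strand))
    return reads


def make_read_level(
    signals: pd.DataFrame,
    exon_expr: pd.Series,
    out_dir: str | Path,
    genome: GenomeSpec | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
) -> ReadLevelData:
    """Write a toy genome whose read densities realize the given log2 signals.

    ``signals`` has one row per exon (in genome order) and one column per
    chromatin feature; ``exon_expr`` gives per-exon RNA log2 density.  Every
    internal odd-ordinal exon is annotated as a cassette event so the
    classification step yields both exon classes.
    """
    genome = genome or GenomeSpec()
    if len(signals) != genome.n_exons:
        raise ValueError(
            f"signals has {len(signals)} rows but the genome has {genome.n_exons} exons"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # genome layout
    exon_coords: list[tuple[str, int, int]] = []  # (gene_id, start, end)
    gene_rows = []
    alt_rows = []
    pos = 1000
    for g in range(genome.n_genes):
        gene_id = f"gene{g:03d}"
        strand = "+" if g % 2 == 0 else "-"
        starts, ends = [], []
        for _ in range(genome.exons_per_gene):
            starts.append(pos)
            ends.append(pos + genome.exon_len)
            pos += genome.exon_len + genome.intron_len
        pos += genome.gene_gap
        for e in range(genome.exons_per_gene):
            exon_coords.append((gene_id, starts[e], ends[e]))
            if 0 < e < genome.exons_per_gene - 1 and e % 2 == 1:
                alt_rows.append(
                    f"{genome.chrom}\t{starts[e]}\t{ends[e]}\t{gene_id}:alt{e}\t0\t{strand}\tcassetteExon"
                )
        gene_rows.append(
            "\t".join(
                [
                    gene_id,
                    gene_id,
                    genome.chrom,
                    strand,
                    str(starts[0]),
                    str(ends[-1]),
                    str(starts[0]),
                    str(ends[-1]),
                    str(genome.exons_per_gene),
                    ",".join(map(str, starts)) + ",",
                    ",".join(map(str, ends)) + ",",
                ]
            )
        )

    annotation = out_dir / "genes.refflat"
    annotation.write_text("\n".join(gene_rows) + "\n")
    alt_table = out_dir / "alt_events.bed"
    alt_table.write_text("\n".join(alt_rows) + "\n")

    exon_of_row = {}
    exon_counter: dict[str, int] = {}
    for row_id, (gene_id, _, _) in zip(signals.index, exon_coords):
        ordinal = exon_counter.get(gene_id, 0)
        exon_counter[gene_id] = ordinal + 1
        exon_of_row[row_id] = f"{gene_id}:exon{ordinal}"

    def write_track(path: Path, per_exon: pd.Series, tag: str) -> None:
        lines = []
        for (row_id, sig), (gene_id, s, e) in zip(per_exon.items(), exon_coords):
            for rs, re_, strand in _emit_reads(
                rng, genome.chrom, s, e, float(sig), genome.read_len, pseudocount
            ):
                lines.append(f"{genome.chrom}\t{rs}\t{re_}\t{tag}\t0\t{strand}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))

    chip_paths = {}
    for feat in signals.columns:
        path = out_dir / f"chip_{feat}.bed"
        write_track(path, signals[feat], feat)
        chip_paths[feat] = path
    rna_path = out_dir / "rna.bed"
    write_track(rna_path, exon_expr, "rna")

    return ReadLevelData(
        annotation=annotation,
        alt_table=alt_table,
        rna_reads=rna_path,
        chip_reads=chip_paths,
        exon_of_row=exon_of_row,
        genome=genome,
    )


# ---------------------------------------------------------------------------
# Second cell type
# ---------------------------------------------------------------------------


def make_second_cell(
    data: pd.DataFrame,
    truth: SyntheticTruth,
    affine_spec: dict[str, tuple[float, float]] | None = None,
    fold: float = 2.0,
    shift_fraction: float = 0.0,
    cell_noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str], dict[str, tuple[float, float]]]:
    """Generate a related cell type from the same exons.

    The second cell keeps each exon's latent feature state up to fresh
    N(0, ``cell_noise_sd``) jitter, recomputes gene/exon expression with the
    same coefficients and fresh noise, applies per-variable affine
    distortions ``value -> slope*value + intercept``, and shifts a random
    ``shift_fraction`` of exons' expression by at least log2(``fold``)
    (magnitude drawn from log2(fold) * U(1.5, 2.5), random sign).

    Returns (second-cell data, shifted exon ids, affine spec used).
    """
    if not 0 <= shift_fraction <= 1:
        raise ValueError("shift_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    m = len(data)
    latent = data[truth.feature_names].to_numpy(dtype=float)
    latent2 = latent + cell_noise_sd * rng.standard_normal(latent.shape)
    data2, _ = _draw(truth, m, rng, latent=latent2)
    data2.index = data.index

    affine_spec = dict(affine_spec or {})
    for var in data2.columns:
        affine_spec.setdefault(var, (1.0, 0.0))
        slope, intercept = affine_spec[var]
        data2[var] = slope * data2[var] + intercept

    shifted_ids: list[str] = []
    if shift_fraction > 0 and EXON_COL in data2.columns:
        n_shift = int(round(shift_fraction * m))
        chosen = rng.choice(m, size=n_shift, replace=False)
        slope = affine_spec[EXON_COL][0]
        magnitudes = math.log2(fold) * rng.uniform(1.5, 2.5, size=n_shift)
        signs = rng.choice([-1.0, 1.0], size=n_shift)
        # shift on the distorted scale so the |log2 difference| after the
        # affine map back to the reference scale still clears log2(fold)
        data2.iloc[chosen, data2.columns.get_loc(EXON_COL)] += slope * signs * magnitudes
        shifted_ids = sorted(data.index[chosen])
    return data2, shifted_ids, affine_spec
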