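"""Synthetic grouped expression data with planted progression trajectories.

Emulates the two-phenotype, three-age, six-replicate bulk RNA-seq design the
pipeline targets. Gene blocks are planted with one of six trajectory patterns
(early / gradual / late onset, up or down), so every downstream stage — GAN
training, latent interpolation, curve classification, enrichment — has an
unambiguous ground truth.

Values are drawn directly on a variance-stabilized log2-like scale
(baseline + phenotype effect scaled by an age-dependent onset fraction +
Gaussian replicate noise). An optional count mode exponentiates the means and
draws Poisson counts, for exercising the size-factor normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GroupDesign

PATTERNS = ("P1", "P2", "P3", "P4", "P5", "P6")

#: fraction of the full phenotype effect present at (young, mid, old) ages
ONSET_FRACTIONS = {
    "early": (0.2, 0.9, 1.0),
    "gradual": (0.1, 0.5, 1.0),
    "late": (0.0, 0.1, 1.0),
}

#: pattern label -> (timing, direction sign)
PATTERN_DEFS = {
    "P1": ("early", +1),
    "P2": ("gradual", +1),
    "P3": ("late", +1),
    "P4": ("early", -1),
    "P5": ("gradual", -1),
    "P6": ("late", -1),
}


@dataclass
class TrajectorySpec:
    """Configuration of a planted-trajectory dataset.

    pattern_blocks lists ``(pattern_label_or_None, gene_count, effect_size)``
    where the effect size is in log2 units and applies (with the pattern's
    sign) to the disease phenotype at the oldest age.
    """

    gene_count: int
    pattern_blocks: list[tuple[str | None, int, float]]
    ages: tuple[str, ...] = ("2M", "4M", "7M")
    phenotypes: tuple[str, str] = ("WT", "AD")
    replicates_per_group: int = 6
    noise_sd: float = 0.1
    baseline_range: tuple[float, float] = (5.0, 12.0)
    seed: int = 0
    counts_mode: bool = False

    def __post_init__(self) -> None:
        if self.gene_count <= 0 or self.replicates_per_group <= 0:
            raise ValueError("gene_count and replicates_per_group must be positive")
        if len(self.ages) != len(next(iter(ONSET_FRACTIONS.values()))):
            raise ValueError("onset fractions are defined for exactly three ages")
        total = sum(n for _, n, _ in self.pattern_blocks)
        if total != self.gene_count:
            raise ValueError(
                f"block gene counts sum to {total}, expected gene_count={self.gene_count}"
            )
        for label, _, eff in self.pattern_blocks:
            if label is not None and label not in PATTERN_DEFS:
                raise ValueError(f"unknown pattern label {label!r}")
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


def _planted_table(spec: TrajectorySpec) -> pd.DataFrame:
    rows = []
    i = 0
    for label, n, eff in spec.pattern_blocks:
        for _ in range(n):
            rows.append((f"g{i:05d}", label if label is not None else "null", eff))
            i += 1
    return pd.DataFrame(rows, columns=["gene", "pattern", "effect"]).set_index("gene")


def generate_dataset(
    spec: TrajectorySpec,
) -> tuple[ExpressionMatrix, GroupDesign, pd.DataFrame]:
    """Generate a grouped expression matrix with planted trajectories.

    Returns the matrix (normalized scale, or counts in counts_mode), the
    group design, and the truth table (gene, pattern, effect).
    """
    rng = np.random.default_rng(spec.seed)
    truth = _planted_table(spec)
    genes = list(truth.index)
    n_genes = len(genes)

    # per-gene signed effect and onset profile across ages
    effect = np.zeros(n_genes)
    onset = np.zeros((n_genes, len(spec.ages)))
    for i, gene in enumerate(genes):
        label = truth.loc[gene, "pattern"]
        if label == "null":
            continue
        timing, sign = PATTERN_DEFS[label]
        effect[i] = sign * abs(truth.loc[gene, "effect"])
        onset[i] = ONSET_FRACTIONS[timing]

    baseline = rng.uniform(*spec.baseline_range, size=n_genes)

    wt, ad = spec.phenotypes
    columns: list[str] = []
    meta_rows: list[tuple[str, str, str]] = []
    means = []
    for phenotype in (wt, ad):
        for a_idx, age in enumerate(spec.ages):
            for rep in range(1, spec.replicates_per_group + 1):
                sample = f"{phenotype}{age}_r{rep}"
                columns.append(sample)
                meta_rows.append((sample, phenotype, age))
                mu = baseline.copy()
                if phenotype == ad:
                    mu = mu + effect * onset[:, a_idx]
                means.append(mu)
    mean_mat = np.column_stack(means)
    values = mean_mat + rng.normal(0.0, spec.noise_sd, size=mean_mat.shape)

    scale = "normalized"
    if spec.counts_mode:
        lam = np.exp2(values)
        values = rng.poisson(lam).astype(float)
        scale = "counts"

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=columns), scale=scale)
    design = GroupDesign(
        pd.DataFrame(meta_rows, columns=["sample", "phenotype", "age"]).set_index("sample")
    )
    return matrix, design, truth


def write_dataset(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    truth: pd.DataFrame,
    directory: str | Path,
) -> dict[str, Path]:
    """Write matrix / metadata / truth TSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "expression.tsv",
        "design": directory / "samples.tsv",
        "truth": directory / "truth.tsv",
    }
    matrix.to_tsv(paths["matrix"])
    design.to_tsv(paths["design"])
    truth.to_csv(paths["truth"], sep="\t", index_label="gene")
    return paths


def default_block_spec(
    genes_per_block: int = 50,
    effect: float = 2.0,
    null_genes: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> TrajectorySpec:
    """Study-design spec: one block per pattern P1..P6 plus a null block."""
    blocks: list[tuple[str | None, int, float]] = [
        (p, genes_per_block, effect) for p in PATTERNS
    ]
    if null_genes:
        blocks.append((None, null_genes, 0.0))
    total = genes_per_block * len(PATTERNS) + null_genes
    return TrajectorySpec(
        gene_count=total,
        pattern_blocks=blocks,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )
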