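"""Normalization and the two-step rescaling used as GAN input.

Counts are brought to a variance-stabilized log scale by median-of-ratios
size factors followed by log2(x + 1) (a lightweight stand-in for a
regularized-log transform; pre-normalized matrices are accepted directly).
The log-scale matrix is then standard-scaled per gene,

    SS[i, j] = (X[i, j] - mu[j]) / max_k sigma[k, j],

where mu[j] is the gene mean over all samples and sigma[k, j] the sample SD
within condition group k — dividing by the *maximum* per-condition SD rather
than the pooled SD avoids inflating genes whose between-group differences
dwarf their within-group spread — and finally mapped affinely so that about
95% of values land in [0, 1]:

    R = SS / (3.918 * sigma_SS) + 0.5,

with sigma_SS the SD of the whole standard-scaled matrix (3.918 = 2 * 1.959,
twice the Gaussian 95% quantile).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, GroupDesign

logger = logging.getLogger(__name__)

RESCALE_CONSTANT = 3.918


def size_factor_normalize(
    counts: ExpressionMatrix,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios size-factor normalization, then log2(x + 1).

    Returns the normalized-scale matrix and the per-sample size factors.
    Requires at least one gene with strictly positive counts in every sample
    (the geometric-mean reference genes).
    """
    if counts.scale != "counts":
        raise ValueError(f"expected a counts-scale matrix, got {counts.scale!r}")
    x = counts.to_numpy()
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has all-positive counts; cannot form the geometric-mean reference"
        )
    ref = np.exp(np.mean(np.log(x[all_positive]), axis=1))
    ratios = x[all_positive] / ref[:, None]
    size_factors = np.median(ratios, axis=0)
    normalized = np.log2(x / size_factors + 1.0)
    out = ExpressionMatrix(
        pd.DataFrame(normalized, index=counts.values.index, columns=counts.values.columns),
        scale="normalized",
    )
    return out, pd.Series(size_factors, index=counts.values.columns, name="size_factor")


@dataclass
class ScalingModel:
    """Per-gene standard-scaling plus global rescale to ~[0, 1]."""

    mean: pd.Series          # mu[j]
    scale: pd.Series         # s[j] = max_k sigma[k, j]
    sigma_ss: float          # SD of the full standard-scaled matrix
    constant: float = RESCALE_CONSTANT

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            bad = list(self.scale.index[self.scale <= 0])
            raise ValueError(f"nonpositive gene scales for {bad[:10]}")
        if not self.sigma_ss > 0:
            raise ValueError("sigma_ss must be positive")

    def _check_genes(self, matrix: ExpressionMatrix) -> None:
        if list(matrix.values.index) != list(self.mean.index):
            raise ValueError("gene set/order mismatch between matrix and scaling model")

    def standard_scale(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        self._check_genes(matrix)
        ss = matrix.values.sub(self.mean, axis=0).div(self.scale, axis=0)
        return ExpressionMatrix(ss, scale="standard")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": list(self.mean.index),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "sigma_ss": self.sigma_ss,
            "constant": self.constant,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingModel":
        d = json.loads(Path(path).read_text())
        idx = pd.Index(d["genes"], name="gene")
        return cls(
            mean=pd.Series(d["mean"], index=idx),
            scale=pd.Series(d["scale"], index=idx),
            sigma_ss=float(d["sigma_ss"]),
            constant=float(d["constant"]),
        )


def fit_scaling(
    normalized: ExpressionMatrix,
    design: GroupDesign,
    drop_zero_scale: bool = False,
) -> ScalingModel | tuple[ScalingModel, list[str]]:
    """Fit the per-gene standard-scaling model on a grouped matrix.

    ``s[j]`` is the maximum over condition groups of the within-group sample
    SD (ddof=1). Genes whose s[j] is zero raise, or are dropped with a warning
    when ``drop_zero_scale`` (then the dropped gene list is also returned).
    """
    df = normalized.values
    groups = design.groups()
    for grp, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"condition group {grp!r} has fewer than 2 samples")
    per_group_sd = pd.DataFrame(
        {grp: df[members].std(axis=1, ddof=1) for grp, members in groups.items()}
    )
    s = per_group_sd.max(axis=1)
    mu = df.mean(axis=1)

    zero = list(s.index[s <= 0])
    if zero and not drop_zero_scale:
        raise ValueError(
            f"{len(zero)} gene(s) have zero within-condition SD in every group: {zero[:10]}"
        )
    if zero:
        logger.warning("dropping %d zero-scale genes", len(zero))
        keep = s.index.difference(zero, sort=False)
        df = df.loc[keep]
        mu, s = mu.loc[keep], s.loc[keep]

    ss = df.sub(mu, axis=0).div(s, axis=0)
    sigma_ss = float(ss.to_numpy().std(ddof=1))
    model = ScalingModel(mean=mu, scale=s, sigma_ss=sigma_ss)
    if drop_zero_scale:
        return model, zero
    return model


def rescale(normalized: ExpressionMatrix, model: ScalingModel) -> ExpressionMatrix:
    """Map the normalized matrix to the GAN input scale (~95% within [0, 1])."""
    ss = model.standard_scale(normalized)
    r = ss.values / (model.constant * model.sigma_ss) + 0.5
    return ExpressionMatrix(r, scale="rescaled")


def inverse_rescale(rescaled: ExpressionMatrix, model: ScalingModel) -> ExpressionMatrix:
    """Exact affine inverse of :func:`rescale`, back to the normalized scale."""
    if list(rescaled.values.index) != list(model.mean.index):
        raise ValueError("gene set/order mismatch between matrix and scaling model")
    ss = (rescaled.values - 0.5) * (model.constant * model.sigma_ss)
    x = ss.mul(model.scale, axis=0).add(model.mean, axis=0)
    return ExpressionMatrix(x, scale="normalized")


def inverse_rescale_array(values: np.ndarray, model: ScalingModel) -> np.ndarray:
    """Array variant of :func:`inverse_rescale` (rows = genes in model order)."""
    ss = (np.asarray(values, dtype=float) - 0.5) * (model.constant * model.sigma_ss)
    return ss * model.scale.to_numpy()[:, None] + model.mean.to_numpy()[:, None]


def select_genes(
    normalized: ExpressionMatrix,
    design: GroupDesign,
    alpha: float = 0.05,
    min_mean: float = 0.0,
    age: str | None = None,
    gene_list: list[str] | None = None,
) -> list[str]:
    """Differential-expression gene filter (stand-in for an external DEG call).

    Welch two-sample t-test between the two phenotypes at the given age
    (default: last age), Benjamini-Hochberg adjusted p < alpha, and mean
    expression >= min_mean on the input scale. When ``gene_list`` is given
    the test is bypassed and the list is intersected with the matrix genes.
    """
    if gene_list is not None:
        present = set(normalized.values.index)
        return [g for g in gene_list if g in present]

    phenos = design.phenotypes()
    if len(phenos) != 2:
        raise ValueError(f"expected exactly two phenotypes, found {phenos}")
    age = age if age is not None else design.ages()[-1]
    tbl = design.table
    cols_a = [s for s in tbl.index if tbl.loc[s, "age"] == age and tbl.loc[s, "phenotype"] == phenos[0]]
    cols_b = [s for s in tbl.index if tbl.loc[s, "age"] == age and tbl.loc[s, "phenotype"] == phenos[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per phenotype at the tested age")

    a = normalized.values[cols_a].to_numpy()
    b = normalized.values[cols_b].to_numpy()
    _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    mean_ok = normalized.values.mean(axis=1).to_numpy() >= min_mean
    keep = (padj < alpha) & mean_ok
    return [g for g, k in zip(normalized.values.index, keep) if k]
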