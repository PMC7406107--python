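"""Resembled fakes: latent-space representatives of real samples.

For each target profile, a shared pool of generated profiles is ranked by
Pearson correlation with the target; the top-k latent vectors are averaged
and decoded, giving a "resembled fake" — the generator's stand-in for that
sample, anchored in latent space. Averaging in latent space (then decoding)
is not the same as averaging the decoded profiles unless the generator is
affine; both are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gan import LatentSampler, generate
from .nn import DenseNet


@dataclass
class ResembledFake:
    sample: str
    z_mean: np.ndarray              # averaged latent vector
    profile: np.ndarray             # G(<z>)
    decoded_mean: np.ndarray        # mean of the k decoded profiles (diagnostic)
    top_indices: np.ndarray         # pool indices, best first
    top_correlations: np.ndarray    # sorted descending
    epoch: int | None = None


@dataclass
class ResembleResult:
    fakes: list[ResembledFake]

    @property
    def samples(self) -> list[str]:
        return [f.sample for f in self.fakes]

    def latents(self) -> pd.DataFrame:
        """latent_dim x samples."""
        return pd.DataFrame(
            np.column_stack([f.z_mean for f in self.fakes]), columns=self.samples
        )

    def profiles(self, genes: list[str]) -> pd.DataFrame:
        """genes x samples."""
        return pd.DataFrame(
            np.column_stack([f.profile for f in self.fakes]),
            index=genes,
            columns=self.samples,
        )

    def match_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "epoch": [f.epoch for f in self.fakes],
                "best_r": [f.top_correlations[0] for f in self.fakes],
                "topk_mean_r": [f.top_correlations.mean() for f in self.fakes],
            }
        )


def _rowwise_standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant rows correlate 0 with everything
    return (x - mu) / sd


def correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows of a and rows of b."""
    za, zb = _rowwise_standardize(a), _rowwise_standardize(b)
    return (za @ zb.T) / a.shape[1]


def resemble(
    targets: pd.DataFrame,
    generator: DenseNet,
    sampler: LatentSampler,
    pool_size: int = 10000,
    k: int = 10,
    epoch: int | None = None,
    metric: str = "pearson",
) -> ResembleResult:
    """One resembled fake per target column (genes x samples DataFrame).

    The pool of ``pool_size`` generated profiles is shared by every target;
    ties in correlation are broken by pool index for reproducibility.
    """
    if not 1 <= k <= pool_size:
        raise ValueError(f"need 1 <= k <= pool_size, got k={k}, pool_size={pool_size}")
    if metric not in ("pearson", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    z_pool, x_pool = generate(generator, pool_size, sampler)

    t = targets.to_numpy(dtype=float).T  # samples x genes
    if metric == "pearson":
        corr = correlation_matrix(t, x_pool)
    else:
        na = t / np.linalg.norm(t, axis=1, keepdims=True)
        nb = x_pool / np.linalg.norm(x_pool, axis=1, keepdims=True)
        corr = na @ nb.T

    fakes = []
    for i, sample in enumerate(targets.columns):
        order = np.argsort(-corr[i], kind="stable")[:k]  # stable: ties by pool index
        z_mean = z_pool[order].mean(axis=0)
        profile = generator.forward(z_mean)[0]
        fakes.append(
            ResembledFake(
                sample=sample,
                z_mean=z_mean,
                profile=profile,
                decoded_mean=x_pool[order].mean(axis=0),
                top_indices=order,
                top_correlations=corr[i, order],
                epoch=epoch,
            )
        )
    return ResembleResult(fakes)


def similarity_report(
    reals: pd.DataFrame,
    fakes: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    bins: int = 50,
) -> dict:
    """Real/fake similarity summaries (value and correlation distributions).

    Returns within-real pairwise correlations (off-diagonal), real-to-fake
    pairwise correlations, the per-real-sample best-match r against the
    fakes, pooled value histograms on a shared grid, and per-condition sample
    counts when a grouping is supplied.
    """
    r = reals.to_numpy(dtype=float).T
    f = fakes.to_numpy(dtype=float).T

    within = correlation_matrix(r, r)
    iu = np.triu_indices(len(r), k=1)
    within_vals = within[iu]

    cross = correlation_matrix(r, f)

    lo = min(r.min(), f.min())
    hi = max(r.max(), f.max())
    edges = np.linspace(lo, hi, bins + 1)
    hist_real, _ = np.histogram(r.ravel(), bins=edges, density=False)
    hist_fake, _ = np.histogram(f.ravel(), bins=edges, density=False)

    report = {
        "within_real_correlations": within_vals,
        "real_to_fake_correlations": cross.ravel(),
        "best_match_r": cross.max(axis=1),
        "value_hist_edges": edges,
        "value_hist_real": hist_real,
        "value_hist_fake": hist_fake,
    }
    if groups is not None:
        report["per_condition_counts"] = {g: len(m) for g, m in groups.items()}
    return report


def total_variation_distance(
    a: np.ndarray, b: np.ndarray, bins: int = 50
) -> float:
    """TV distance between the histograms of two pooled value samples."""
    a, b = np.ravel(a), np.ravel(b)
    lo, hi = min(a.min(), b.min()), max(a.max(), b.max())
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    return 0.5 * float(np.abs(pa - pb).sum())
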