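"""WGAN with gradient penalty on rescaled expression profiles.

The generator maps a latent vector (default 100-dimensional) through two
fully connected hidden layers to a gene-expression profile; the critic maps a
profile to a scalar Wasserstein score. Leaky ReLU is used on every generator
layer including the output (the rescaled data deliberately spill slightly
outside [0, 1], so no saturating clamp), and on the critic's hidden layers.
The critic minimizes

    E[D(fake)] - E[D(real)] + lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2]

with xhat uniform convex combinations of paired real and fake profiles; the
generator minimizes -E[D(fake)]. Latent coordinates are sampled i.i.d. from
the empirical distribution of the rescaled training values (a Gaussian
fallback is available), matching the scale the generator must output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam, DenseNet

logger = logging.getLogger(__name__)


@dataclass
class GanConfig:
    gene_count: int
    latent_dim: int = 100
    gen_hidden: tuple[int, ...] = (250, 250)
    critic_hidden: tuple[int, ...] = (150, 150)
    init_half_range: float = 0.3
    leaky_slope: float = 0.2
    gp_lambda: float = 10.0
    critic_steps: int = 5
    lr: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.9
    batch_size: int = 32
    epochs: int = 2000
    checkpoint_every: int = 100
    latent_mode: str = "empirical"  # or "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_count <= 0 or self.latent_dim <= 0:
            raise ValueError("gene_count and latent_dim must be positive")
        if any(h <= 0 for h in self.gen_hidden + self.critic_hidden):
            raise ValueError("hidden widths must be positive")
        if self.gp_lambda < 0:
            raise ValueError("gradient-penalty weight must be nonnegative")

    @property
    def generator_sizes(self) -> tuple[int, ...]:
        return (self.latent_dim, *self.gen_hidden, self.gene_count)

    @property
    def critic_sizes(self) -> tuple[int, ...]:
        return (self.gene_count, *self.critic_hidden, 1)


class LatentSampler:
    """I.i.d. latent coordinates from the rescaled-data distribution.

    ``empirical`` draws coordinates uniformly from the pooled rescaled
    training values; ``gaussian`` uses N(0.5, (1/3.918)^2), the parametric
    shape the rescaling targets.
    """

    def __init__(
        self,
        training_values: np.ndarray | None = None,
        mode: str = "empirical",
        seed: int = 0,
    ) -> None:
        if mode not in ("empirical", "gaussian"):
            raise ValueError(f"unknown latent mode {mode!r}")
        if mode == "empirical":
            if training_values is None:
                raise ValueError("empirical mode requires the training values")
            self.pool: np.ndarray | None = np.sort(
                np.asarray(training_values, dtype=float).ravel()
            )
        else:
            self.pool = None
        self.mode = mode
        self.rng = np.random.default_rng(seed)

    def sample(self, n: int, dim: int) -> np.ndarray:
        if self.mode == "gaussian":
            return self.rng.normal(0.5, 1.0 / 3.918, size=(n, dim))
        # inverse-CDF on the sorted pool: uniform quantiles, linear interpolation
        u = self.rng.random(size=(n, dim))
        idx = u * (len(self.pool) - 1)
        lo = np.floor(idx).astype(int)
        frac = idx - lo
        hi = np.minimum(lo + 1, len(self.pool) - 1)
        return self.pool[lo] * (1 - frac) + self.pool[hi] * frac


@dataclass
class TrainingTrace:
    g_loss: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    checkpoints: dict[int, list[np.ndarray]] = field(default_factory=dict)
    aborted_at: int | None = None

    @property
    def checkpoint_epochs(self) -> list[int]:
        return sorted(self.checkpoints)

    def losses_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": range(1, len(self.g_loss) + 1), "g_loss": self.g_loss, "d_loss": self.d_loss}
        )


def build_networks(config: GanConfig, rng: np.random.Generator | None = None):
    """Generator and critic per the configured fully connected layout."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    generator = DenseNet(
        config.generator_sizes,
        leaky_slope=config.leaky_slope,
        output_activation="leaky",
        init=("uniform", config.init_half_range),
        rng=rng,
    )
    critic = DenseNet(
        config.critic_sizes,
        leaky_slope=config.leaky_slope,
        output_activation="linear",
        init=("glorot", None),
        rng=rng,
    )
    return generator, critic


def critic_loss(
    critic: DenseNet,
    real: np.ndarray,
    fake: np.ndarray,
    gp_lambda: float,
    rng: np.random.Generator,
):
    """Critic loss value, its parameter gradients, and the penalty term.

    Returns ``(loss, penalty, weight_grads, bias_grads)``. With
    ``gp_lambda == 0`` this is the plain Wasserstein critic loss.
    """
    real = np.atleast_2d(real)
    fake = np.atleast_2d(fake)
    if np.isnan(real).any() or np.isnan(fake).any():
        raise ValueError("NaN in critic inputs")
    if real.shape[1] != fake.shape[1]:
        raise ValueError("real/fake gene dimension mismatch")

    y_fake, c_fake = critic.forward(fake, cache=True)
    y_real, c_real = critic.forward(real, cache=True)
    wass = float(y_fake.mean() - y_real.mean())

    gw_f, gb_f, _ = critic.backprop(c_fake, np.full_like(y_fake, 1.0 / len(y_fake)))
    gw_r, gb_r, _ = critic.backprop(c_real, np.full_like(y_real, -1.0 / len(y_real)))
    gw = [a + b for a, b in zip(gw_f, gw_r)]
    gb = [a + b for a, b in zip(gb_f, gb_r)]

    penalty = 0.0
    if gp_lambda > 0:
        n = min(len(real), len(fake))
        eps = rng.random((n, 1))
        xhat = eps * real[:n] + (1.0 - eps) * fake[:n]
        penalty, gw_p, gb_p = critic.gradient_penalty(xhat)
        gw = [a + gp_lambda * b for a, b in zip(gw, gw_p)]
        gb = [a + gp_lambda * b for a, b in zip(gb, gb_p)]
    loss = wass + gp_lambda * penalty
    return loss, penalty, gw, gb


def _generator_step(generator: DenseNet, critic: DenseNet, z: np.ndarray, opt: Adam) -> float:
    fake, c_gen = generator.forward(z, cache=True)
    y, c_crit = critic.forward(fake, cache=True)
    loss = float(-y.mean())
    _, _, dfake = critic.backprop(c_crit, np.full_like(y, -1.0 / len(y)))
    gw, gb, _ = generator.backprop(c_gen, dfake)
    opt.step(gw, gb)
    return loss


def train(
    data: np.ndarray,
    config: GanConfig,
    sampler: LatentSampler | None = None,
) -> tuple[DenseNet, DenseNet, TrainingTrace]:
    """Train the WGAN-GP; returns (generator, critic, trace).

    ``data`` is samples x genes on the rescaled scale. One epoch is a full
    pass over the training set in mini-batches of critic updates; the
    generator is updated once per ``critic_steps`` critic updates. Training
    aborts (retaining the checkpoints taken so far) if a loss goes non-finite.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 1:
        raise ValueError("need at least one training sample")
    if data.shape[1] != config.gene_count:
        raise ValueError("data width != config.gene_count")

    rng = np.random.default_rng(config.seed)
    generator, critic = build_networks(config, rng)
    if sampler is None:
        sampler = LatentSampler(
            data, mode=config.latent_mode, seed=int(rng.integers(2**31 - 1))
        )
    g_opt = Adam(generator, config.lr, config.beta1, config.beta2)
    d_opt = Adam(critic, config.lr, config.beta1, config.beta2)

    trace = TrainingTrace()
    n = data.shape[0]
    bs = min(config.batch_size, n)
    steps_per_epoch = max(n // bs, 1)

    crit_counter = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for step in range(steps_per_epoch):
            batch = data[order[step * bs : (step + 1) * bs]]
            z = sampler.sample(len(batch), config.latent_dim)
            fake = generator.forward(z)
            loss, _, gw, gb = critic_loss(critic, batch, fake, config.gp_lambda, rng)
            d_opt.step(gw, gb)
            d_losses.append(loss)
            crit_counter += 1
            if crit_counter % config.critic_steps == 0:
                z = sampler.sample(bs, config.latent_dim)
                g_losses.append(_generator_step(generator, critic, z, g_opt))
        trace.d_loss.append(float(np.mean(d_losses)))
        trace.g_loss.append(float(np.mean(g_losses)) if g_losses else np.nan)
        if not (np.isfinite(trace.d_loss[-1]) and (np.isnan(trace.g_loss[-1]) or np.isfinite(trace.g_loss[-1]))):
            logger.error("non-finite loss at epoch %d; aborting", epoch)
            trace.aborted_at = epoch
            break
        if epoch % config.checkpoint_every == 0 or epoch == config.epochs:
            trace.checkpoints[epoch] = generator.get_parameters()
    return generator, critic, trace


def generate(
    generator: DenseNet,
    n: int,
    sampler: LatentSampler,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n latent vectors and decode them; returns (latents, profiles)."""
    latent_dim = generator.sizes[0]
    if n == 0:
        return np.empty((0, latent_dim)), np.empty((0, generator.sizes[-1]))
    z = sampler.sample(n, latent_dim)
    return z, generator.forward(z)


def restore_generator(config: GanConfig, params: list[np.ndarray]) -> DenseNet:
    generator, _ = build_networks(config, np.random.default_rng(0))
    generator.set_parameters(params)
    return generator


def gene_association(
    generator: DenseNet,
    genes: list[str],
    threshold: float = 0.4,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Gene-gene correlation of last-layer generator weights, plus clusters.

    Each gene's incoming weight vector in the generator's final layer is
    treated as its learned feature; the Pearson correlation matrix between
    those vectors is thresholded (|r| > cutoff on off-diagonals) and the
    connected components of the resulting graph are returned sorted by
    decreasing size (ties by first member).
    """
    w = generator.weights[-1]  # (hidden, genes)
    if w.shape[1] != len(genes):
        raise ValueError("gene list length != generator output width")
    corr = np.corrcoef(w.T)
    corr_df = pd.DataFrame(corr, index=genes, columns=genes)

    adj = np.abs(corr) > threshold
    np.fill_diagonal(adj, False)
    n = len(genes)
    seen = np.zeros(n, dtype=bool)
    clusters: list[list[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(adj[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        clusters.append([genes[i] for i in sorted(comp)])
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return corr_df, clusters


# -- checkpoint persistence ---------------------------------------------------


def save_checkpoints(trace: TrainingTrace, config: GanConfig, directory: str | Path) -> Path:
    """Write generator checkpoints (.npz per epoch) plus a JSON index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {"config": asdict(config), "epochs": {}}
    for epoch, params in trace.checkpoints.items():
        fname = f"generator_epoch{epoch:07d}.npz"
        np.savez(directory / fname, *params)
        index["epochs"][str(epoch)] = fname
    (directory / "index.json").write_text(json.dumps(index, default=list))
    trace.losses_frame().to_csv(directory / "losses.tsv", sep="\t", index=False)
    return directory / "index.json"


def load_checkpoints(directory: str | Path) -> tuple[GanConfig, dict[int, list[np.ndarray]]]:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    cfg_dict = index["config"]
    for key in ("gen_hidden", "critic_hidden"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = GanConfig(**cfg_dict)
    checkpoints = {}
    for epoch, fname in index["epochs"].items():
        with np.load(directory / fname) as npz:
            checkpoints[int(epoch)] = [npz[k] for k in npz.files]
    return config, checkpoints
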