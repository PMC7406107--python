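"""Latent-space interpolation between condition states: transition curves.

The progression coordinate t in [0, 1] moves each start-condition latent
vector along the condition difference vector

    Delta = mean(z_to) - mean(z_from),      z(t, i) = z_from(i) + t * Delta,

and the per-gene transition curve at one epoch checkpoint is the decoded
average T(t) = mean_i G(z(t, i)). Curves are averaged over a window of epoch
checkpoints (late training half by default), with the per-t SD across epochs
retained as an uncertainty band. Averaging over all of a condition's
resembled latents — not a single representative — damps the sensitivity of
Delta and the irregular behavior that single starting points can show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GroupDesign
from .gan import GanConfig, LatentSampler, restore_generator
from .normalize import ScalingModel, inverse_rescale_array
from .resemble import resemble

DEFAULT_T_GRID = np.round(np.linspace(0.0, 1.0, 101), 4)


@dataclass
class TransitionCurveSet:
    t_grid: np.ndarray
    mean: pd.DataFrame        # genes x t (column labels = t values)
    sd: pd.DataFrame          # genes x t, SD across epoch checkpoints
    from_cond: str
    to_cond: str
    epochs: list[int]
    scale: str = "rescaled"

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.mean.index:
            for j, t in enumerate(self.t_grid):
                rows.append(
                    (gene, t, self.mean.iat[self.mean.index.get_loc(gene), j],
                     self.sd.iat[self.sd.index.get_loc(gene), j])
                )
        df = pd.DataFrame(rows, columns=["gene", "t", "mean", "sd"])
        df["scale"] = self.scale
        df["from"] = self.from_cond
        df["to"] = self.to_cond
        return df


def condition_delta(
    latents_by_condition: dict[str, np.ndarray],
    from_cond: str,
    to_cond: str,
) -> np.ndarray:
    """Difference of condition latent centroids, mean(to) - mean(from)."""
    for cond in (from_cond, to_cond):
        if cond not in latents_by_condition or len(latents_by_condition[cond]) == 0:
            raise ValueError(f"no resembled latents for condition {cond!r}")
    z_from = np.atleast_2d(latents_by_condition[from_cond])
    z_to = np.atleast_2d(latents_by_condition[to_cond])
    return z_to.mean(axis=0) - z_from.mean(axis=0)


def epoch_window(checkpoint_epochs: list[int], fraction: float = 0.5) -> list[int]:
    """The last ``fraction`` of the available checkpoints (at least one)."""
    epochs = sorted(checkpoint_epochs)
    n = max(int(np.ceil(len(epochs) * fraction)), 1)
    return epochs[-n:]


def transition_curves(
    config: GanConfig,
    checkpoints: dict[int, list[np.ndarray]],
    epochs: list[int],
    targets: pd.DataFrame,
    design: GroupDesign,
    from_cond: str,
    to_cond: str,
    t_grid: np.ndarray = DEFAULT_T_GRID,
    pool_size: int = 10000,
    k: int = 10,
    seed: int = 0,
    scaling_model: ScalingModel | None = None,
    group_of: pd.Series | None = None,
) -> TransitionCurveSet:
    """Per-gene transition curves from one condition to another.

    For each requested epoch checkpoint the two conditions' samples are
    resembled against a fresh generated pool, the latent difference vector is
    formed from the condition centroids, and the start-condition latents are
    marched along it. The returned curve is the mean over epochs with its SD.

    ``targets`` is the rescaled genes x samples matrix whose columns cover at
    least the two conditions; ``group_of`` may override the design grouping
    (e.g. to use augmented samples). With a ``scaling_model`` the curves are
    back-transformed to the normalized scale.
    """
    if len(epochs) == 0:
        raise ValueError("empty epoch set")
    missing = [e for e in epochs if e not in checkpoints]
    if missing:
        raise ValueError(f"checkpoints missing for epochs {missing}")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or (np.diff(t_grid) <= 0).any() or t_grid[0] < 0 or t_grid[-1] > 1:
        raise ValueError("t grid must be strictly increasing within [0, 1]")

    labels = group_of if group_of is not None else design.group_labels
    cols_from = [s for s in targets.columns if labels.get(s) == from_cond]
    cols_to = [s for s in targets.columns if labels.get(s) == to_cond]
    if not cols_from or not cols_to:
        raise ValueError(f"no samples for condition {from_cond!r} or {to_cond!r}")
    sub = targets[cols_from + cols_to]

    per_epoch = []
    for i, epoch in enumerate(sorted(epochs)):
        generator = restore_generator(config, checkpoints[epoch])
        sampler = LatentSampler(
            targets.to_numpy(), mode=config.latent_mode, seed=seed + 1000003 * i
        )
        res = resemble(sub, generator, sampler, pool_size=pool_size, k=k, epoch=epoch)
        lat = res.latents()
        z_from = lat[cols_from].to_numpy().T    # samples x latent
        z_to = lat[cols_to].to_numpy().T
        delta = z_to.mean(axis=0) - z_from.mean(axis=0)

        curves = np.empty((len(targets.index), len(t_grid)))
        for j, t in enumerate(t_grid):
            profiles = generator.forward(z_from + t * delta)
            curves[:, j] = profiles.mean(axis=0)
        per_epoch.append(curves)

    stack = np.stack(per_epoch)  # epochs x genes x t
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(per_epoch) > 1 else np.zeros_like(mean)
    scale = "rescaled"
    if scaling_model is not None:
        mean = inverse_rescale_array(mean, scaling_model)
        sd = sd * (scaling_model.constant * scaling_model.sigma_ss) * \
            scaling_model.scale.to_numpy()[:, None]
        scale = "normalized"

    cols = [f"{t:g}" for t in t_grid]
    return TransitionCurveSet(
        t_grid=t_grid,
        mean=pd.DataFrame(mean, index=targets.index, columns=cols),
        sd=pd.DataFrame(sd, index=targets.index, columns=cols),
        from_cond=from_cond,
        to_cond=to_cond,
        epochs=sorted(epochs),
        scale=scale,
    )


def plot_curves(
    curves: TransitionCurveSet,
    genes: list[str],
    path: str | None = None,
    normalized: ExpressionMatrix | None = None,
    design: GroupDesign | None = None,
):
    """Plot per-gene transition curves with +-1 SD bands.

    When the observed matrix and design are given, the start/end condition
    groups' observed values are overlaid as points at t = 0 and t = 1.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for g in genes:
        mean = curves.mean.loc[g].to_numpy()
        sd = curves.sd.loc[g].to_numpy()
        (line,) = ax.plot(curves.t_grid, mean, label=g)
        ax.fill_between(curves.t_grid, mean - sd, mean + sd,
                        color=line.get_color(), alpha=0.15, linewidth=0)
        if normalized is not None and design is not None:
            for t, cond in ((0.0, curves.from_cond), (1.0, curves.to_cond)):
                obs = normalized.values.loc[g, design.samples_in(cond)]
                ax.scatter(np.full(len(obs), t), obs, s=10,
                           color=line.get_color(), alpha=0.6)
    ax.set_xlabel(f"progression t ({curves.from_cond} → {curves.to_cond})")
    ax.set_ylabel(f"expression ({curves.scale} scale)")
    ax.legend(fontsize=7, ncols=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def overlay_with_observations(
    curves: TransitionCurveSet,
    normalized: ExpressionMatrix,
    design: GroupDesign,
    genes: list[str],
) -> pd.DataFrame:
    """Curve endpoints against observed group statistics, per gene.

    Reports, for each requested gene, the curve start/end values, the
    observed mean and SD of the start and end condition groups, and the
    midpoint diagnostic |T(0) - observed start-group mean| (how close the
    interpolation anchors sit to the middle of the real data points).
    Requires curves on the normalized scale for comparability.
    """
    unknown = [g for g in genes if g not in curves.mean.index or g not in normalized.values.index]
    if unknown:
        raise ValueError(f"unknown gene(s): {unknown}")
    if not genes:
        return pd.DataFrame(
            columns=["gene", "t0", "t1", "from_mean", "from_sd", "to_mean", "to_sd",
                     "start_abs_error", "end_abs_error"]
        )
    from_cols = design.samples_in(curves.from_cond)
    to_cols = design.samples_in(curves.to_cond)
    rows = []
    for g in genes:
        curve = curves.mean.loc[g]
        t0, t1 = float(curve.iloc[0]), float(curve.iloc[-1])
        obs_from = normalized.values.loc[g, from_cols]
        obs_to = normalized.values.loc[g, to_cols]
        rows.append(
            (g, t0, t1, obs_from.mean(), obs_from.std(ddof=1),
             obs_to.mean(), obs_to.std(ddof=1),
             abs(t0 - obs_from.mean()), abs(t1 - obs_to.mean()))
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "t0", "t1", "from_mean", "from_sd", "to_mean", "to_sd",
                 "start_abs_error", "end_abs_error"],
    )
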