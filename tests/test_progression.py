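import numpy as np
import pandas as pd
import pytest

from ganprog.data import ExpressionMatrix, GroupDesign
from ganprog.gan import GanConfig, build_networks
from ganprog.progression import (
    condition_delta,
    epoch_window,
    overlay_with_observations,
    transition_curves,
)


class TestConditionDelta:
    def test_identical_latent_sets_give_zero(self):
        z = np.random.default_rng(0).normal(size=(5, 4))
        d = condition_delta({"a": z, "b": z.copy()}, "a", "b")
        assert np.allclose(d, 0.0)

    def test_two_point_case(self):
        d = condition_delta({"a": np.array([[0.0, 0.0]]),
                             "b": np.array([[1.0, 3.0]])}, "a", "b")
        assert np.allclose(d, [1.0, 3.0])

    def test_swapping_arguments_negates(self):
        rng = np.random.default_rng(1)
        lat = {"a": rng.normal(size=(3, 6)), "b": rng.normal(size=(4, 6))}
        assert np.allclose(condition_delta(lat, "a", "b"),
                           -condition_delta(lat, "b", "a"))

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="no resembled latents"):
            condition_delta({"a": np.ones((1, 2))}, "a", "zzz")


def _affine_setup(seed=0, genes=12, latent=4, n_per=6):
    """An exactly affine generator (leaky slope 1) plus a two-condition dataset."""
    cfg = GanConfig(gene_count=genes, latent_dim=latent, gen_hidden=(8,),
                    critic_hidden=(6,), leaky_slope=1.0, seed=seed)
    gen, _ = build_networks(cfg, np.random.default_rng(seed))
    checkpoints = {10: gen.get_parameters(), 20: gen.get_parameters()}
    rng = np.random.default_rng(seed + 1)
    cols, rows = [], []
    for cond in ("A1", "B1"):
        for i in range(n_per):
            cols.append(f"{cond}_{i}")
            rows.append((f"{cond}_{i}", cond[0], cond[1:]))
    base = rng.normal(0.5, 0.2, size=(genes, len(cols)))
    base[:, n_per:] += 0.5  # condition B shifted
    targets = pd.DataFrame(base, index=[f"g{i}" for i in range(genes)], columns=cols)
    design = GroupDesign(pd.DataFrame(rows, columns=["sample", "phenotype", "age"])
                         .set_index("sample"))
    return cfg, checkpoints, targets, design


class TestTransitionCurves:
    def test_affine_generator_yields_exactly_linear_curves(self):
        cfg, ckpts, targets, design = _affine_setup()
        curves = transition_curves(cfg, ckpts, [10, 20], targets, design, "A1", "B1",
                                   t_grid=np.linspace(0, 1, 11), pool_size=50, k=5,
                                   seed=3)
        vals = curves.mean.to_numpy()
        # second differences vanish for a linear-in-t curve
        assert np.abs(np.diff(vals, n=2, axis=1)).max() < 1e-9

    def test_same_condition_gives_flat_curves(self):
        cfg, ckpts, targets, design = _affine_setup(seed=5)
        curves = transition_curves(cfg, ckpts, [10], targets, design, "A1", "A1",
                                   t_grid=np.linspace(0, 1, 7), pool_size=40, k=4,
                                   seed=1)
        vals = curves.mean.to_numpy()
        assert np.allclose(vals, vals[:, [0]], atol=1e-12)

    def test_reversibility_exact_on_affine_generator(self):
        cfg, ckpts, targets, design = _affine_setup(seed=7)
        grid = np.linspace(0, 1, 9)
        fwd = transition_curves(cfg, ckpts, [10], targets, design, "A1", "B1",
                                t_grid=grid, pool_size=60, k=5, seed=11)
        rev = transition_curves(cfg, ckpts, [10], targets, design, "B1", "A1",
                                t_grid=grid, pool_size=60, k=5, seed=11)
        assert np.allclose(fwd.mean.to_numpy(),
                           rev.mean.to_numpy()[:, ::-1], atol=1e-9)

    def test_endpoint_equals_shifted_start_centroid_decode(self):
        """T(1) = G(mean z_from + Delta); for affine G this is the to-centroid decode."""
        cfg, ckpts, targets, design = _affine_setup(seed=9)
        from ganprog.gan import LatentSampler, restore_generator
        from ganprog.resemble import resemble

        grid = np.linspace(0, 1, 5)
        curves = transition_curves(cfg, ckpts, [10], targets, design, "A1", "B1",
                                   t_grid=grid, pool_size=80, k=6, seed=13)
        gen = restore_generator(cfg, ckpts[10])
        sampler = LatentSampler(targets.to_numpy(), mode=cfg.latent_mode,
                                seed=13 + 1000003 * 0)
        res = resemble(targets, gen, sampler, pool_size=80, k=6, epoch=10)
        lat = res.latents()
        z_to = lat[[c for c in lat.columns if c.startswith("B")]].to_numpy().T
        expected = gen.forward(z_to.mean(axis=0))[0]
        assert np.allclose(curves.mean.iloc[:, -1].to_numpy(), expected, atol=1e-9)

    def test_more_epochs_shrink_the_epoch_mean_uncertainty(self):
        """With stationary checkpoint jitter, the SEM of the epoch-mean curve
        shrinks as more checkpoints enter the average."""
        cfg, _, targets, design = _affine_setup(seed=17)
        base, _ = build_networks(cfg, np.random.default_rng(17))
        rng = np.random.default_rng(99)
        checkpoints = {}
        for epoch in range(10, 90, 10):  # 8 jittered copies of one generator
            params = [p + rng.normal(0, 0.02, size=p.shape)
                      for p in base.get_parameters()]
            checkpoints[epoch] = params
        epochs = sorted(checkpoints)
        kwargs = dict(t_grid=np.linspace(0, 1, 9), pool_size=60, k=5, seed=2)
        sub = transition_curves(cfg, checkpoints, epochs[:2], targets, design,
                                "A1", "B1", **kwargs)
        full = transition_curves(cfg, checkpoints, epochs, targets, design,
                                 "A1", "B1", **kwargs)
        sem_sub = (sub.sd.to_numpy() / np.sqrt(2)).mean()
        sem_full = (full.sd.to_numpy() / np.sqrt(len(epochs))).mean()
        assert sem_full < sem_sub

    def test_bad_grid_and_empty_epochs_rejected(self):
        cfg, ckpts, targets, design = _affine_setup()
        with pytest.raises(ValueError, match="epoch"):
            transition_curves(cfg, ckpts, [], targets, design, "A1", "B1")
        with pytest.raises(ValueError, match="grid"):
            transition_curves(cfg, ckpts, [10], targets, design, "A1", "B1",
                              t_grid=np.array([0.5, 0.2, 1.0]))


class TestEpochWindow:
    def test_last_half_of_checkpoints(self):
        assert epoch_window([100, 200, 300, 400], 0.5) == [300, 400]
        assert epoch_window([100, 200, 300], 0.5) == [200, 300]
        assert epoch_window([100], 0.5) == [100]


class TestOverlay:
    def _curveset(self):
        cfg, ckpts, targets, design = _affine_setup(seed=21)
        curves = transition_curves(cfg, ckpts, [10], targets, design, "A1", "B1",
                                   t_grid=np.linspace(0, 1, 5), pool_size=60, k=5,
                                   seed=4)
        matrix = ExpressionMatrix(targets, scale="normalized")
        return curves, matrix, design

    def test_empty_gene_list_gives_empty_table(self):
        curves, matrix, design = self._curveset()
        table = overlay_with_observations(curves, matrix, design, [])
        assert len(table) == 0

    def test_unknown_gene_rejected_by_name(self):
        curves, matrix, design = self._curveset()
        with pytest.raises(ValueError, match="zzz"):
            overlay_with_observations(curves, matrix, design, ["zzz"])

    def test_reports_endpoint_error_against_group_means(self):
        curves, matrix, design = self._curveset()
        table = overlay_with_observations(curves, matrix, design, ["g0", "g3"])
        assert list(table["gene"]) == ["g0", "g3"]
        row = table.iloc[0]
        expected = abs(row["t0"] - row["from_mean"])
        assert row["start_abs_error"] == pytest.approx(expected)


def test_plot_curves_writes_figure(tmp_path):
    from ganprog.progression import plot_curves

    cfg, ckpts, targets, design = _affine_setup(seed=31)
    curves = transition_curves(cfg, ckpts, [10, 20], targets, design, "A1", "B1",
                               t_grid=np.linspace(0, 1, 5), pool_size=40, k=4, seed=6)
    out = tmp_path / "curves.png"
    fig = plot_curves(curves, ["g0", "g1"], path=str(out),
                      normalized=ExpressionMatrix(targets), design=design)
    assert out.exists() and out.stat().st_size > 0
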