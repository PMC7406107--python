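import numpy as np
import pandas as pd
import pytest

from ganprog.augment import augment_all
from ganprog.data import GroupDesign
from ganprog.gan import GanConfig, train
from ganprog.normalize import fit_scaling, rescale
from ganprog.pipeline import _design_from_groups
from ganprog.synthetic import default_block_spec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """35 genes (5 per pattern block + 5 null), 6 groups of 6 samples."""
    spec = default_block_spec(genes_per_block=5, effect=2.0, null_genes=5,
                              noise_sd=0.1, seed=42)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_augmented(small_dataset):
    matrix, design, truth = small_dataset
    aug = augment_all(matrix, design, seed=42)
    aug_design = _design_from_groups(aug.provenance, design)
    return aug, aug_design


@pytest.fixture(scope="session")
def small_rescaled(small_augmented):
    aug, aug_design = small_augmented
    model = fit_scaling(aug.matrix, aug_design)
    return rescale(aug.matrix, model), model


@pytest.fixture(scope="session")
def tiny_trained_gan(small_rescaled):
    """A briefly trained WGAN-GP on the small augmented dataset (smoke-level)."""
    rescaled, _ = small_rescaled
    data = rescaled.values.to_numpy().T
    cfg = GanConfig(
        gene_count=data.shape[1], latent_dim=8, gen_hidden=(32, 32),
        critic_hidden=(24, 24), batch_size=64, epochs=60, checkpoint_every=10,
        lr=2e-4, seed=7,
    )
    generator, critic, trace = train(data, cfg)
    return cfg, generator, critic, trace


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
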