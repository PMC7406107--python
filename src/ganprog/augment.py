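"""Within-group pairwise linear-interpolation augmentation.

Each condition group of n samples contributes C(n, 2) unordered sample pairs;
every pair (S1, S2) yields nine interpolants x*S1 + (1-x)*S2 at
x = 0.1, 0.2, ..., 0.9. A six-group design with six replicates per group thus
grows from 36 to 36 + 6*15*9 = 846 samples. An alternative Gaussian mode fits
a per-group, per-gene normal distribution and samples from it instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GroupDesign

DEFAULT_X_GRID = tuple(np.round(np.arange(1, 10) * 0.1, 1))


@dataclass
class AugmentedSet:
    """Originals plus interpolants, with per-sample provenance.

    provenance columns: sample_id, group, origin ('original' | 'interpolant' |
    'gaussian'), parent1, parent2, x (mixing weight on parent1).
    """

    matrix: ExpressionMatrix
    provenance: pd.DataFrame

    @property
    def sample_count(self) -> int:
        return self.matrix.shape[1]

    def group_of(self) -> pd.Series:
        return self.provenance.set_index("sample_id")["group"]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, row in self.provenance.iterrows():
            out.setdefault(row["group"], []).append(row["sample_id"])
        return out

    def write_provenance(self, path: str | Path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)


def augment_group(
    samples: pd.DataFrame,
    x_grid: tuple[float, ...] = DEFAULT_X_GRID,
) -> pd.DataFrame:
    """Interpolants for one condition group (genes x samples DataFrame).

    Returns a genes x interpolants DataFrame; column names encode parents and
    mixing weight as ``parent1|parent2|x<value>``.
    """
    if samples.shape[1] < 2:
        raise ValueError("cannot augment a group with fewer than 2 samples")
    cols = {}
    for s1, s2 in combinations(samples.columns, 2):
        v1, v2 = samples[s1].to_numpy(), samples[s2].to_numpy()
        for x in x_grid:
            cols[f"{s1}|{s2}|x{x:g}"] = x * v1 + (1.0 - x) * v2
    return pd.DataFrame(cols, index=samples.index)


def augment_all(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    x_grid: tuple[float, ...] = DEFAULT_X_GRID,
    mode: str = "linear",
    gaussian_per_pair: int | None = None,
    seed: int = 0,
) -> AugmentedSet:
    """Augment every condition group; returns originals + interpolants.

    ``mode='gaussian'`` replaces pairwise interpolation with draws from
    per-group per-gene normal fits (the robustness-check variant); the number
    of draws per group defaults to the count linear mode would produce.
    """
    if mode not in ("linear", "gaussian"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    groups = design.groups()
    labels = design.group_labels

    pieces = [matrix.values]
    prov_rows = [
        (s, labels[s], "original", "", "", np.nan) for s in matrix.values.columns
    ]
    rng = np.random.default_rng(seed)
    for grp, members in groups.items():
        sub = matrix.values[members]
        if mode == "linear":
            interp = augment_group(sub, x_grid=x_grid)
            for col in interp.columns:
                p1, p2, xs = col.split("|")
                prov_rows.append((col, grp, "interpolant", p1, p2, float(xs[1:])))
            pieces.append(interp)
        else:
            n_pairs = len(members) * (len(members) - 1) // 2
            n_draws = gaussian_per_pair * n_pairs if gaussian_per_pair else n_pairs * len(x_grid)
            mu = sub.mean(axis=1).to_numpy()
            sd = sub.std(axis=1, ddof=1).to_numpy()
            draws = rng.normal(mu[:, None], sd[:, None], size=(len(mu), n_draws))
            names = [f"{grp}|gauss{i}" for i in range(n_draws)]
            pieces.append(pd.DataFrame(draws, index=sub.index, columns=names))
            prov_rows.extend((n, grp, "gaussian", "", "", np.nan) for n in names)

    combined = pd.concat(pieces, axis=1)
    provenance = pd.DataFrame(
        prov_rows, columns=["sample_id", "group", "origin", "parent1", "parent2", "x"]
    )
    return AugmentedSet(
        matrix=ExpressionMatrix(combined, scale=matrix.scale), provenance=provenance
    )


def split_train_test(
    augmented: AugmentedSet,
    test_count: int = 84,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-stratified random train/test split of the augmented samples.

    Test samples are allocated to condition groups proportionally (largest
    remainder), then drawn uniformly within each group. Returns the two
    genes x samples DataFrames; disjoint and exhaustive by construction.
    """
    total = augmented.sample_count
    if not 0 < test_count < total:
        raise ValueError(f"test_count must be in (0, {total}), got {test_count}")
    rng = np.random.default_rng(seed)
    groups = augmented.groups()

    sizes = {g: len(m) for g, m in groups.items()}
    exact = {g: test_count * n / total for g, n in sizes.items()}
    alloc = {g: int(np.floor(v)) for g, v in exact.items()}
    shortfall = test_count - sum(alloc.values())
    by_remainder = sorted(exact, key=lambda g: (-(exact[g] - alloc[g]), g))
    for g in by_remainder[:shortfall]:
        alloc[g] += 1

    test_samples: list[str] = []
    for g, members in groups.items():
        take = min(alloc[g], len(members))
        chosen = rng.choice(len(members), size=take, replace=False)
        test_samples.extend(members[i] for i in sorted(chosen))
    test_set = set(test_samples)
    train_samples = [s for s in augmented.matrix.values.columns if s not in test_set]
    df = augmented.matrix.values
    return df[train_samples], df[list(test_samples)]
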