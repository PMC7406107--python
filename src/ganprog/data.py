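"""Core containers: expression matrices and condition-group designs.

Matrices are pandas DataFrames (genes as rows, samples as columns) carrying a
scale tag so downstream stages can refuse input on the wrong scale. Designs
map each sample to a phenotype x age condition group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCALES = ("counts", "normalized", "standard", "rescaled")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag."""

    values: pd.DataFrame
    scale: str = "normalized"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "normalized") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, scale=scale)


@dataclass
class GroupDesign:
    """Sample metadata: phenotype and age labels defining condition groups.

    The condition group of a sample is the concatenation ``phenotype + age``
    (e.g. ``WT7M``), matching the usual naming of phenotype-by-age designs.
    """

    table: pd.DataFrame  # index: sample; columns: phenotype, age

    def __post_init__(self) -> None:
        missing = {"phenotype", "age"} - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in design")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def group_labels(self) -> pd.Series:
        return self.table["phenotype"].astype(str) + self.table["age"].astype(str)

    def groups(self) -> dict[str, list[str]]:
        """Condition group -> sample ids, in stable (first appearance) order."""
        out: dict[str, list[str]] = {}
        for sample, grp in self.group_labels.items():
            out.setdefault(grp, []).append(sample)
        return out

    def phenotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["phenotype"].astype(str)))

    def ages(self) -> list[str]:
        return list(dict.fromkeys(self.table["age"].astype(str)))

    def samples_in(self, group: str) -> list[str]:
        labels = self.group_labels
        return [s for s in self.table.index if labels[s] == group]

    def subset(self, samples: list[str]) -> "GroupDesign":
        return GroupDesign(self.table.loc[samples])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupDesign":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df)
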