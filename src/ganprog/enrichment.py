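"""Over-representation analysis of pattern gene lists against GMT gene sets.

One-sided hypergeometric test per gene set: with a universe of N genes of
which K belong to the set and a query list of n genes overlapping the set in
x genes, p = P[X >= x] for X ~ Hypergeom(N, K, n). The enrichment ratio is
ER = x / (n * K / N). P-values are Benjamini-Hochberg adjusted within each
query list's table (each list is its own testing family). The universe
defaults to the genes that entered the analysis (the DEG list), not the
genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .patterns import PATTERN_LABELS, PatternAssignment, members

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with the universe; drop sets that vanish."""
        kept, desc = {}, {}
        for name, genes in self.sets.items():
            inter = genes & universe
            if inter:
                kept[name] = inter
                desc[name] = self.descriptions.get(name, "")
            else:
                logger.warning("gene set %s has no genes in the universe; excluded", name)
        return GeneSetCollection(kept, desc)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated members)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: malformed GMT line (need >= 3 fields)")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            logger.warning("%s:%d: empty gene set %s dropped", path, lineno, name)
            continue
        sets[name] = set(genes)  # duplicates collapse
        descriptions[name] = desc
    if not sets:
        logger.warning("GMT file %s contained no nonempty gene sets", path)
    return GeneSetCollection(sets, descriptions)


def ora(
    gene_list: list[str],
    collection: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list.

    Returns one row per gene set: overlap, sizes, enrichment ratio,
    hypergeometric upper-tail p, and BH FDR across the tested sets, sorted by
    (FDR, p, name). Query genes outside the universe are dropped with a
    warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(gene_list)
    outside = query - uni
    if outside:
        logger.warning("%d query gene(s) not in universe dropped", len(outside))
        query &= uni

    N, n = len(uni), len(query)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & uni
        if not in_universe:
            logger.warning("gene set %s absent from universe; excluded", name)
            continue
        K = len(in_universe)
        x = len(in_universe & query)
        expected = n * K / N
        er = x / expected if expected > 0 else np.nan
        p = float(hypergeom.sf(x - 1, N, K, n)) if n else 1.0
        rows.append((name, x, K, n, N, er, p))
    df = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "list_size", "universe_size", "ER", "p"],
    )
    if len(df):
        _, fdr, _, _ = multipletests(df["p"], method="fdr_bh")
        df["FDR"] = fdr
        df = df.sort_values(["FDR", "p", "set"], kind="stable").reset_index(drop=True)
    else:
        df["FDR"] = []
    return df


def pattern_enrichment(
    assignments: list[PatternAssignment],
    collection: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """ORA for the eight standard lists: Up, Down, and P1..P6.

    Up is the union of P1-P3 members, Down of P4-P6. Returns a long-format
    table with a ``list`` column; FDR is computed within each list's table.
    Lists with no member genes yield no rows.
    """
    lists: dict[str, list[str]] = {lab: members(assignments, lab) for lab in PATTERN_LABELS}
    lists = {
        "Up": sorted(set(lists["P1"]) | set(lists["P2"]) | set(lists["P3"])),
        "Down": sorted(set(lists["P4"]) | set(lists["P5"]) | set(lists["P6"])),
        **lists,
    }
    pieces = []
    for name, genes in lists.items():
        if not genes:
            continue
        table = ora(genes, collection, universe)
        table.insert(0, "list", name)
        pieces.append(table)
    if not pieces:
        return pd.DataFrame(
            columns=["list", "set", "overlap", "set_size", "list_size",
                     "universe_size", "ER", "p", "FDR"]
        )
    return pd.concat(pieces, ignore_index=True)
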