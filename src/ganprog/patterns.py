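"""Transition-curve pattern classification.

Six reference templates cross onset timing (early / gradual / late) with
direction (up / down): P1-P3 rise, P4-P6 are their vertical mirrors. A curve
joins every pattern whose Pearson correlation with it exceeds a strict
threshold (default 0.95); failing that, it joins the best-correlated pattern
alone if that correlation reaches a laxer floor (default 0.90); otherwise it
stays unassigned. Membership can be one-to-many — curves intermediate
between two templates legitimately correlate highly with both.

Template shapes: the timing archetypes are logistic transitions centered at
the terciles of the progression axis — early completes most of its change in
the first third (center t = 1/3), late in the last third (center t = 2/3) —
and gradual is linear. Logistic (sigmoidal) archetypes reflect how latent
interpolation between two condition states actually changes expression: the
decoded path lingers near data-supported states and crosses between them in a
smooth step, so curves carry flat shoulders at both ends; purely concave or
convex archetypes would all be dominated by the linear one in correlation.
The shapes are config-overridable via a template TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATTERN_LABELS = ("P1", "P2", "P3", "P4", "P5", "P6")

#: logistic transition centers (terciles of the progression axis) and width
EARLY_CENTER = 1.0 / 3.0
LATE_CENTER = 2.0 / 3.0
TEMPLATE_WIDTH = 0.10


@dataclass
class PatternTemplate:
    label: str
    curve: np.ndarray     # on the shared t grid
    direction: str        # "up" | "down"
    timing: str           # "early" | "gradual" | "late"


@dataclass
class PatternAssignment:
    gene: str
    correlations: dict[str, float]
    assigned: tuple[str, ...]
    rule: str             # "strict" | "max" | "none"


def default_templates(t_grid: np.ndarray) -> list[PatternTemplate]:
    """The six reference curves evaluated on ``t_grid``."""
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 3 or (np.diff(t) <= 0).any():
        raise ValueError("t grid must be a strictly increasing 1-D grid")
    early = 1.0 / (1.0 + np.exp(-(t - EARLY_CENTER) / TEMPLATE_WIDTH))
    gradual = t.copy()
    late = 1.0 / (1.0 + np.exp(-(t - LATE_CENTER) / TEMPLATE_WIDTH))
    shapes = {"early": early, "gradual": gradual, "late": late}
    templates = []
    for label, (timing, up) in {
        "P1": ("early", True), "P2": ("gradual", True), "P3": ("late", True),
        "P4": ("early", False), "P5": ("gradual", False), "P6": ("late", False),
    }.items():
        base = shapes[timing]
        curve = base if up else -base
        templates.append(
            PatternTemplate(label, curve, "up" if up else "down", timing)
        )
    return templates


def templates_to_tsv(templates: list[PatternTemplate], t_grid: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame({"t": t_grid})
    for tpl in templates:
        df[tpl.label] = tpl.curve
    df.to_csv(path, sep="\t", index=False)


def templates_from_tsv(path: str | Path) -> tuple[np.ndarray, list[PatternTemplate]]:
    df = pd.read_csv(path, sep="\t")
    t = df["t"].to_numpy()
    meta = {tpl.label: (tpl.direction, tpl.timing) for tpl in default_templates(np.linspace(0, 1, 11))}
    templates = [
        PatternTemplate(lab, df[lab].to_numpy(), *meta.get(lab, ("up", "gradual")))
        for lab in df.columns
        if lab != "t"
    ]
    return t, templates


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def classify(
    curves: pd.DataFrame,
    templates: list[PatternTemplate],
    strict_r: float = 0.95,
    max_r: float = 0.90,
) -> list[PatternAssignment]:
    """Assign each curve (genes x t DataFrame rows) to pattern(s).

    Grid lengths of curves and templates must match. Constant (zero-variance)
    curves are unassigned with a logged note.
    """
    n_t = curves.shape[1]
    for tpl in templates:
        if len(tpl.curve) != n_t:
            raise ValueError(
                f"template {tpl.label} grid length {len(tpl.curve)} != curves {n_t}"
            )
    out = []
    values = curves.to_numpy(dtype=float)
    n_constant = 0
    for gene, row in zip(curves.index, values):
        corr = {tpl.label: _pearson(row, tpl.curve) for tpl in templates}
        if any(np.isnan(v) for v in corr.values()):
            n_constant += 1
            out.append(PatternAssignment(gene, corr, (), "none"))
            continue
        strict = tuple(lab for lab, r in corr.items() if r > strict_r)
        if strict:
            out.append(PatternAssignment(gene, corr, strict, "strict"))
            continue
        best = max(corr, key=lambda lab: (corr[lab], lab))
        if corr[best] >= max_r:
            out.append(PatternAssignment(gene, corr, (best,), "max"))
        else:
            out.append(PatternAssignment(gene, corr, (), "none"))
    if n_constant:
        logger.info("%d constant curve(s) left unassigned", n_constant)
    return out


def assignments_frame(assignments: list[PatternAssignment]) -> pd.DataFrame:
    labels = sorted({lab for a in assignments for lab in a.correlations})
    rows = []
    for a in assignments:
        rows.append(
            [a.gene] + [a.correlations.get(lab, np.nan) for lab in labels]
            + [",".join(a.assigned), a.rule]
        )
    return pd.DataFrame(rows, columns=["gene"] + [f"r_{lab}" for lab in labels] + ["assigned", "rule"])


def members(assignments: list[PatternAssignment], label: str) -> list[str]:
    return [a.gene for a in assignments if label in a.assigned]


def venn_counts(assignments: list[PatternAssignment]) -> dict:
    """Per-pattern counts, pairwise intersections, unassigned, up/down totals."""
    labels = list(PATTERN_LABELS)
    singles = {lab: 0 for lab in labels}
    pairwise: dict[str, int] = {}
    unassigned = 0
    up_genes, down_genes = set(), set()
    total_memberships = 0
    for a in assignments:
        if not a.assigned:
            unassigned += 1
            continue
        total_memberships += len(a.assigned)
        for lab in a.assigned:
            if lab in singles:
                singles[lab] += 1
            if lab in ("P1", "P2", "P3"):
                up_genes.add(a.gene)
            elif lab in ("P4", "P5", "P6"):
                down_genes.add(a.gene)
        for i, la in enumerate(a.assigned):
            for lb in a.assigned[i + 1:]:
                key = "&".join(sorted((la, lb)))
                pairwise[key] = pairwise.get(key, 0) + 1
    return {
        "pattern_counts": singles,
        "pairwise_intersections": pairwise,
        "unassigned": unassigned,
        "up_total": len(up_genes),
        "down_total": len(down_genes),
        "total_memberships": total_memberships,
        "assigned_genes": len(assignments) - unassigned,
    }
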