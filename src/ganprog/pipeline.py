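"""End-to-end orchestration: config-driven runs with a reproducibility manifest.

Stage order: (synthesize or load) -> normalize/select -> augment -> rescale ->
train WGAN-GP -> resemble -> transition curves -> pattern classification ->
enrichment. Every stage writes its outputs under the run directory; the
manifest records the config snapshot, seeds, input hashes and the numerical
conventions in force so a run can be reproduced bit-compatibly on the same
backend.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augment import augment_all, split_train_test
from .data import ExpressionMatrix, GroupDesign
from .enrichment import pattern_enrichment, read_gmt
from .gan import GanConfig, LatentSampler, generate, save_checkpoints, train
from .normalize import fit_scaling, rescale, select_genes, size_factor_normalize
from .patterns import (
    assignments_frame,
    classify,
    default_templates,
    templates_from_tsv,
    templates_to_tsv,
    venn_counts,
)
from .progression import epoch_window, transition_curves
from .resemble import resemble, similarity_report, total_variation_distance
from .synthetic import default_block_spec, generate_dataset, write_dataset

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "run",
    "synth": None,          # {genes_per_block, effect, null_genes, noise_sd, replicates}
    "input": None,          # {matrix, scale, design, deg_list}
    "select": {"enabled": False, "alpha": 0.05, "min_mean": 0.0},
    "augment": {"mode": "linear"},
    "split": {"test_fraction": 84 / 846},
    "gan": {},              # GanConfig overrides
    "resemble": {"pool_size": 10000, "k": 10, "originals_only": False},
    "progression": {"t_points": 101, "epoch_window": 0.5, "from": None, "to": None},
    "patterns": {"strict_r": 0.95, "max_r": 0.90, "template_tsv": None},
    "enrichment": {"gmt": None},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _design_from_groups(provenance: pd.DataFrame, design: GroupDesign) -> GroupDesign:
    """Design table for augmented samples, inheriting phenotype/age per group."""
    group_meta = {}
    labels = design.group_labels
    for s in design.samples:
        group_meta[labels[s]] = (design.table.loc[s, "phenotype"], design.table.loc[s, "age"])
    rows = {
        row["sample_id"]: group_meta[row["group"]]
        for _, row in provenance.iterrows()
    }
    tab = pd.DataFrame.from_dict(rows, orient="index", columns=["phenotype", "age"])
    return GroupDesign(tab)


def run(config: dict | str | Path) -> dict:
    """Execute the pipeline described by ``config``; returns artifact paths
    and key in-memory results (curves, assignments, summary metrics)."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("inputs", "checkpoints", "curves", "patterns", "enrichment"):
        (outdir / sub).mkdir(exist_ok=True)
    t_start = time.time()
    input_hashes = {}

    # ---- stage: inputs -----------------------------------------------------
    truth = None
    if config["synth"]:
        synth = dict(config["synth"])
        reps = synth.pop("replicates", 6)
        spec = default_block_spec(seed=seed, replicates_per_group=reps, **synth)
        matrix, design, truth = generate_dataset(spec)
        write_dataset(matrix, design, truth, outdir / "inputs")
        logger.info("synthesized %d genes x %d samples", *matrix.shape)
    elif config["input"]:
        inp = config["input"]
        if not inp.get("matrix") or not inp.get("design"):
            raise ConfigurationError("input block requires 'matrix' and 'design' paths")
        matrix = ExpressionMatrix.from_tsv(inp["matrix"], scale=inp.get("scale", "normalized"))
        design = GroupDesign.from_tsv(inp["design"])
        input_hashes["matrix"] = _sha256(Path(inp["matrix"]))
        input_hashes["design"] = _sha256(Path(inp["design"]))
    else:
        raise ConfigurationError("config needs either a 'synth' or an 'input' block")

    # ---- stage: normalize / select ----------------------------------------
    size_factors = None
    if matrix.scale == "counts":
        matrix, size_factors = size_factor_normalize(matrix)
        size_factors.to_csv(outdir / "inputs" / "size_factors.tsv", sep="\t")
        logger.info("size-factor normalized %d samples", len(size_factors))
    sel = config["select"]
    deg_list = None
    if config.get("input") and config["input"].get("deg_list"):
        deg_list = [
            line.strip()
            for line in Path(config["input"]["deg_list"]).read_text().splitlines()
            if line.strip()
        ]
    if sel.get("enabled") or deg_list is not None:
        genes = select_genes(
            matrix, design, alpha=sel["alpha"], min_mean=sel["min_mean"], gene_list=deg_list
        )
        if not genes:
            raise ConfigurationError("gene selection removed every gene")
        matrix = ExpressionMatrix(matrix.values.loc[genes], scale=matrix.scale)
        logger.info("selected %d genes", len(genes))

    # ---- stage: augment ----------------------------------------------------
    aug = augment_all(
        matrix, design, mode=config["augment"].get("mode", "linear"), seed=seed
    )
    aug.write_provenance(outdir / "inputs" / "provenance.tsv")
    logger.info("augmented: %d -> %d samples", matrix.shape[1], aug.sample_count)
    aug_design = _design_from_groups(aug.provenance, design)

    # ---- stage: rescale ----------------------------------------------------
    scaling, dropped = fit_scaling(aug.matrix, aug_design, drop_zero_scale=True)
    if dropped:
        keep = [g for g in aug.matrix.values.index if g not in set(dropped)]
        aug.matrix = ExpressionMatrix(aug.matrix.values.loc[keep], scale=aug.matrix.scale)
        matrix = ExpressionMatrix(matrix.values.loc[keep], scale=matrix.scale)
        if truth is not None:
            truth = truth.loc[keep]
    scaling.to_json(outdir / "inputs" / "scaling_model.json")
    rescaled = rescale(aug.matrix, scaling)
    in_unit = float(((rescaled.values >= 0) & (rescaled.values <= 1)).to_numpy().mean())
    logger.info("rescaled: %.1f%% of values in [0, 1]", 100 * in_unit)

    split_cfg = config["split"]
    test_count = split_cfg.get("test_count")
    if test_count is None:
        test_count = max(int(round(split_cfg["test_fraction"] * aug.sample_count)), 1)
    train_df, test_df = split_train_test(aug, test_count=test_count, seed=seed)
    train_resc = rescaled.values[train_df.columns]
    test_resc = rescaled.values[test_df.columns]
    logger.info("split: %d train / %d test", train_resc.shape[1], test_resc.shape[1])

    # ---- stage: train ------------------------------------------------------
    gan_cfg = GanConfig(
        gene_count=aug.matrix.shape[0], seed=seed,
        **{k: tuple(v) if isinstance(v, list) else v for k, v in config["gan"].items()},
    )
    generator, critic, trace = train(train_resc.to_numpy().T, gan_cfg)
    if trace.aborted_at is not None:
        raise RuntimeError(f"GAN training diverged at epoch {trace.aborted_at}")
    save_checkpoints(trace, gan_cfg, outdir / "checkpoints")
    logger.info("trained %d epochs; %d checkpoints", gan_cfg.epochs, len(trace.checkpoints))

    # ---- stage: resemble / similarity --------------------------------------
    res_cfg = config["resemble"]
    sampler = LatentSampler(train_resc.to_numpy(), mode=gan_cfg.latent_mode, seed=seed + 11)
    res_targets = rescaled.values[matrix.samples] if res_cfg.get("originals_only") else rescaled.values
    result = resemble(
        res_targets, generator, sampler,
        pool_size=res_cfg["pool_size"], k=res_cfg["k"],
        epoch=max(trace.checkpoints) if trace.checkpoints else None,
    )
    result.match_table().to_csv(outdir / "resembled_matches.tsv", sep="\t", index=False)
    result.latents().to_csv(outdir / "resembled_latents.tsv", sep="\t")
    result.profiles(aug.matrix.genes).to_csv(outdir / "resembled_profiles.tsv", sep="\t")

    _, fake = generate(generator, train_resc.shape[1], sampler)
    report = similarity_report(train_resc, pd.DataFrame(fake.T, index=aug.matrix.genes),
                               groups=aug.groups())
    tv = total_variation_distance(train_resc.to_numpy(), fake)
    corr_gap = float(
        abs(report["within_real_correlations"].mean() - report["real_to_fake_correlations"].mean())
    )
    logger.info("similarity: TV=%.3f corr-gap=%.3f", tv, corr_gap)

    # ---- stage: transition curves ------------------------------------------
    prog = config["progression"]
    phenos, ages = design.phenotypes(), design.ages()
    from_cond = prog.get("from") or f"{phenos[0]}{ages[-1]}"
    to_cond = prog.get("to") or f"{phenos[-1]}{ages[-1]}"
    window = epoch_window(trace.checkpoint_epochs, prog.get("epoch_window", 0.5))
    t_grid = np.linspace(0.0, 1.0, int(prog.get("t_points", 101)))
    curves = transition_curves(
        gan_cfg, trace.checkpoints, window, rescaled.values, aug_design,
        from_cond, to_cond, t_grid=t_grid,
        pool_size=res_cfg["pool_size"], k=res_cfg["k"], seed=seed + 23,
        group_of=aug.group_of(),
    )
    curves.to_long_frame().to_csv(outdir / "curves" / "transition_curves.tsv",
                                  sep="\t", index=False)
    logger.info("curves: %d genes x %d t-points over %d epochs (%s -> %s)",
                curves.mean.shape[0], curves.mean.shape[1], len(window), from_cond, to_cond)

    # ---- stage: classify ---------------------------------------------------
    pat_cfg = config["patterns"]
    if pat_cfg.get("template_tsv"):
        grid, templates = templates_from_tsv(pat_cfg["template_tsv"])
        if len(grid) != len(t_grid):
            raise ConfigurationError("template TSV grid length != progression t_points")
    else:
        templates = default_templates(t_grid)
    templates_to_tsv(templates, t_grid, outdir / "patterns" / "templates.tsv")
    assignments = classify(
        curves.mean, templates, strict_r=pat_cfg["strict_r"], max_r=pat_cfg["max_r"]
    )
    assignments_frame(assignments).to_csv(outdir / "patterns" / "assignments.tsv",
                                          sep="\t", index=False)
    venn = venn_counts(assignments)
    (outdir / "patterns" / "venn.json").write_text(json.dumps(venn, indent=2))
    logger.info("classified: %d assigned / %d unassigned (up %d, down %d)",
                venn["assigned_genes"], venn["unassigned"], venn["up_total"], venn["down_total"])

    # ---- stage: enrichment -------------------------------------------------
    enrichment_table = None
    gmt = config["enrichment"].get("gmt")
    if gmt:
        gmt_path = Path(gmt)
        if not gmt_path.exists():
            raise ConfigurationError(f"enrichment requested but GMT not found: {gmt_path}")
        input_hashes["gmt"] = _sha256(gmt_path)
        collection = read_gmt(gmt_path)
        universe = list(aug.matrix.genes)
        enrichment_table = pattern_enrichment(assignments, collection, universe)
        enrichment_table.to_csv(outdir / "enrichment" / "ora.tsv", sep="\t", index=False)
        logger.info("enrichment: %d rows across lists", len(enrichment_table))

    # ---- manifest ----------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": _jsonable(config),
        "seed": seed,
        "input_hashes": input_hashes,
        "counts": {
            "genes": aug.matrix.shape[0],
            "original_samples": matrix.shape[1],
            "augmented_samples": aug.sample_count,
            "train": train_resc.shape[1],
            "test": test_resc.shape[1],
            "dropped_zero_scale_genes": len(dropped),
        },
        "metrics": {
            "in_unit_fraction": in_unit,
            "tv_distance": tv,
            "corr_gap": corr_gap,
        },
        "decisions": {
            "sd_convention": "sample SD (ddof=1) for sigma[k,j] and sigma_SS",
            "sigma_ss_scope": "pooled over the entire standard-scaled matrix",
            "gp_lambda": gan_cfg.gp_lambda,
            "critic_steps": gan_cfg.critic_steps,
            "augment_order": "augment on normalized scale, then fit scaling on augmented set",
            "epoch_window": window,
            "templates": "logistic archetypes at t=1/3 and 2/3 (early/late), linear gradual",
            "split": "group-stratified",
        },
        "runtime_seconds": round(time.time() - t_start, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "outdir": outdir,
        "manifest": manifest,
        "matrix": matrix,
        "design": design,
        "truth": truth,
        "augmented": aug,
        "scaling": scaling,
        "rescaled": rescaled,
        "trace": trace,
        "gan_config": gan_cfg,
        "generator": generator,
        "resembled": result,
        "similarity": report,
        "curves": curves,
        "assignments": assignments,
        "venn": venn,
        "enrichment": enrichment_table,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
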