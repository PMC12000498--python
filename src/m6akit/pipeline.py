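"""Stage orchestration behind the CLI.

A run is driven by a config mapping (usually loaded from YAML) naming the
stages to execute and their parameters. Outputs are deterministic given the
config and seed: every table is TSV with a '#' parameter header and the log
carries no timestamps.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .clustering import (build_feature_matrix, cluster_correlation_sign,
                         hypergeometric_enrichment, kmeans_cluster)
from .errors import ConfigError, M6AKitError
from .inheritance import classify_inheritance, stage_fractions
from .io import (CountMatrix, SampleSheet, read_counts, read_gmt,
                 read_result_table, read_sample_sheet, read_tree,
                 write_counts, write_result_table, write_sample_sheet,
                 write_tree)
from .kinetics import fit_decay_table
from .landscape import (DEFAULT_LFC_THRESH, DEFAULT_P_THRESH, M6ALandscape,
                        assemble_landscape, union_target_count)
from .nbtest import (DEFAULT_MIN_TOTAL_COUNT, condition_contrast,
                     ip_input_contrast, size_factors)
from .overlay import (DEFAULT_DEG_LFC_THRESH, DEFAULT_DEG_P_THRESH, call_degs,
                      overlay_m6a)
from .simulate import (SimulationParams, default_tree, simulate_de_counts,
                       simulate_landscape_counts)

log = logging.getLogger("m6akit")

ALL_STAGES = ("simulate", "quantify", "landscape", "inherit", "cluster", "de", "decay")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def expression_profiles(counts: CountMatrix, sheet: SampleSheet,
                        condition: str | None = "WT") -> pd.DataFrame:
    """Gene x population normalized mean expression from INPUT libraries."""
    input_samples = sheet.samples_for(assay="INPUT", condition=condition)
    if not input_samples:
        input_samples = sheet.samples_for(assay="INPUT")
    sub = counts.subset_samples(input_samples)
    sf = size_factors(sub)
    norm = sub.counts / sf[None, :]
    cols = {}
    for pop in sheet.populations:
        pop_samples = [s for s in input_samples
                       if s in set(sheet.samples_for(population=pop))]
        if not pop_samples:
            continue
        idx = [input_samples.index(s) for s in pop_samples]
        cols[pop] = norm[:, idx].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(counts.gene_ids, name="gene_id"))


def run_pipeline(config: Mapping, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the requested stages; returns in-memory stage products.

    Raises ConfigError on invalid configuration and other M6AKitError
    subclasses on bad inputs; the CLI maps these to a non-zero exit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    _require(not unknown, f"unknown stage(s): {unknown}")
    seed = int(config.get("seed", 0) if seed is None else seed)

    log_lines = [f"m6akit {__version__}", f"seed={seed}", f"stages={','.join(stages)}"]
    products: dict = {}

    # ------------------------------------------------------------------ simulate
    if "simulate" in stages:
        sim_cfg = dict(config.get("simulate", {}))
        tree_path = sim_cfg.pop("tree", None)
        tree = read_tree(tree_path) if tree_path else default_tree()
        params = SimulationParams(
            n_genes=int(sim_cfg.get("n_genes", 1000)),
            tree=tree,
            frac_methylated_root=float(sim_cfg.get("frac_methylated_root", 0.3)),
            p_inherit=float(sim_cfg.get("p_inherit", 0.8)),
            p_denovo=float(sim_cfg.get("p_denovo", 0.1)),
            enrichment_lfc=float(sim_cfg.get("enrichment_lfc", 2.0)),
            dispersion=float(sim_cfg.get("dispersion", 0.1)),
            mean_depth=float(sim_cfg.get("mean_depth", 50.0)),
            n_reps=int(sim_cfg.get("n_reps", 2)),
            seed=seed,
        )
        cm, sheet, truth = simulate_landscape_counts(params)
        write_counts(cm, out / "sim_counts.tsv")
        write_sample_sheet(sheet, out / "sim_samples.csv")
        write_tree(tree, out / "sim_tree.tsv")
        truth_long = truth.origin.stack().rename("origin").reset_index()
        truth_long.columns = ["gene_id", "population", "origin"]
        truth_long["true_lfc"] = truth.true_lfc.stack().to_numpy()
        write_result_table(truth_long, out / "sim_truth.tsv",
                           params={"seed": seed, "n_genes": params.n_genes,
                                   "p_inherit": params.p_inherit,
                                   "p_denovo": params.p_denovo})
        products.update(counts=cm, samples=sheet, truth=truth, tree=tree)
        log_lines.append(f"simulate: n_genes={params.n_genes} "
                         f"populations={len(tree.nodes)} n_reps={params.n_reps}")

    # ------------------------------------------------------------------ quantify
    if "quantify" in stages:
        qcfg = dict(config.get("quantify", {}))
        cm, sheet = _load_counts(products, qcfg, config)
        min_total = int(qcfg.get("min_total_count", DEFAULT_MIN_TOTAL_COUNT))
        _require(min_total >= 0, "min_total_count must be >= 0")
        pops = qcfg.get("populations") or sheet.populations
        results = {}
        for pop in pops:
            res = ip_input_contrast(cm, sheet, pop, min_total_count=min_total)
            results[pop] = res
            write_result_table(res.table, out / f"enrichment_{pop}.tsv",
                               params={"population": pop, "contrast": "ip-vs-input",
                                       "min_total_count": min_total})
        products["enrichment"] = results
        log_lines.append(f"quantify: {len(results)} population contrast(s)")

    # ------------------------------------------------------------------ landscape
    if "landscape" in stages:
        lcfg = dict(config.get("landscape", {}))
        lfc_thresh = float(lcfg.get("lfc_thresh", DEFAULT_LFC_THRESH))
        p_thresh = float(lcfg.get("p_thresh", DEFAULT_P_THRESH))
        _require(lfc_thresh > 0, "lfc_thresh must be positive")
        _require(0 < p_thresh <= 1, "p_thresh must lie in (0, 1]")
        _require("enrichment" in products, "landscape stage needs quantify results")
        ls = assemble_landscape(products["enrichment"], lfc_thresh, p_thresh)
        write_result_table(ls.to_long(), out / "landscape_long.tsv",
                           params=ls.provenance)
        write_result_table(ls.z.reset_index(), out / "landscape_z.tsv",
                           params=ls.provenance)
        products["landscape"] = ls
        log_lines.append(f"landscape: union target count={union_target_count(ls)}")

    # ------------------------------------------------------------------ inherit
    if "inherit" in stages:
        icfg = dict(config.get("inherit", {}))
        _require("landscape" in products, "inherit stage needs the landscape")
        tree = products.get("tree")
        if tree is None:
            tree_path = icfg.get("tree")
            _require(tree_path is not None, "inherit stage needs a tree")
            tree = read_tree(tree_path)
        mode = str(icfg.get("mode", "any_ancestor")).replace("-", "_")
        table = classify_inheritance(products["landscape"], tree, mode=mode)
        write_result_table(table.table, out / "origin.tsv", params={"mode": mode})
        write_result_table(stage_fractions(table), out / "stage_summary.tsv",
                           params={"mode": mode})
        products["inheritance"] = table
        log_lines.append(f"inherit: mode={mode} n={len(table)}")

    # ------------------------------------------------------------------ cluster
    if "cluster" in stages:
        ccfg = dict(config.get("cluster", {}))
        k = int(ccfg.get("k", 2))
        _require(k >= 1, "K must be >= 1")
        n_init = int(ccfg.get("n_init", 10))
        _require("landscape" in products, "cluster stage needs the landscape")
        ls: M6ALandscape = products["landscape"]
        cm, sheet = products.get("counts"), products.get("samples")
        _require(cm is not None, "cluster stage needs counts for expression profiles")
        expr = expression_profiles(cm, sheet)
        gene_mode = str(ccfg.get("genes", "targets"))
        genes = None
        if gene_mode == "targets":
            genes = sorted(set().union(*(ls.targets_in(p) for p in ls.populations)))
        feats = build_feature_matrix(ls, expr, genes=genes)
        assignment = kmeans_cluster(feats, k=k, seed=seed, n_init=n_init)
        write_result_table(assignment.labels.reset_index().rename(
            columns={"index": "gene_id"}), out / "clusters.tsv",
            params={"k": k, "seed": seed, "n_init": n_init,
                    "inertia": f"{assignment.inertia:.6g}"})
        corr = cluster_correlation_sign(assignment, ls, expr)
        write_result_table(corr, out / "cluster_correlation.tsv", params={"k": k})
        products["clusters"] = assignment
        if ccfg.get("gmt"):
            collection = read_gmt(ccfg["gmt"])
            universe = set(feats.index)
            enr_rows = []
            for cluster in sorted(assignment.labels.unique()):
                sel = set(assignment.labels.index[assignment.labels == cluster])
                enr = hypergeometric_enrichment(sel, collection, universe)
                enr.insert(0, "cluster", cluster)
                enr_rows.append(enr)
            write_result_table(pd.concat(enr_rows, ignore_index=True),
                               out / "cluster_enrichment.tsv", params={"k": k})
        log_lines.append(f"cluster: k={k} n_genes={len(feats)}")

    # ------------------------------------------------------------------ de
    if "de" in stages:
        dcfg = dict(config.get("de", {}))
        lfc_thresh = float(dcfg.get("lfc_thresh", DEFAULT_DEG_LFC_THRESH))
        p_thresh = float(dcfg.get("p_thresh", DEFAULT_P_THRESH))
        _require(lfc_thresh > 0, "lfc_thresh must be positive")
        _require(0 < p_thresh <= 1, "p_thresh must lie in (0, 1]")
        if "sim" in dcfg or ("counts" not in dcfg and "simulate" in stages):
            sim = dict(dcfg.get("sim", {}))
            de_cm, de_sheet, de_flags = simulate_de_counts(
                n_genes=int(sim.get("n_genes", 1000)),
                n_reps=int(sim.get("n_reps", 2)),
                frac_de=float(sim.get("frac_de", 0.1)),
                lfc_de=float(sim.get("lfc_de", 1.0)),
                dispersion=float(sim.get("dispersion", 0.1)),
                mean_depth=float(sim.get("mean_depth", 50.0)),
                seed=seed + 1,
            )
            write_counts(de_cm, out / "de_counts.tsv")
            write_sample_sheet(de_sheet, out / "de_samples.csv")
            write_result_table(de_flags.reset_index().rename(
                columns={"index": "gene_id"}), out / "de_truth.tsv",
                params={"seed": seed + 1})
        else:
            _require("counts" in dcfg and "samples" in dcfg,
                     "de stage needs counts and samples (or a sim section)")
            de_cm = read_counts(dcfg["counts"])
            de_sheet = read_sample_sheet(dcfg["samples"])
            de_flags = None
        res = condition_contrast(de_cm, de_sheet, numerator="KO", denominator="WT")
        degs = call_degs(res, lfc_thresh, p_thresh)
        if "landscape" in products:
            pop = str(dcfg.get("population", products["landscape"].populations[0]))
            ov = overlay_m6a(degs, products["landscape"], pop)
            write_result_table(ov["table"].table, out / "degs.tsv",
                               params={"lfc_thresh": lfc_thresh, "p_thresh": p_thresh,
                                       "population": pop})
            summary = pd.DataFrame([{"population": pop,
                                     "n_up_tagged": ov["n_up_tagged"],
                                     "n_down_tagged": ov["n_down_tagged"],
                                     "n_tagged_degs": ov["n_tagged_degs"]}])
            write_result_table(summary, out / "de_summary.tsv",
                               params={"lfc_thresh": lfc_thresh, "p_thresh": p_thresh})
            products["overlay"] = ov
        else:
            write_result_table(degs.table, out / "degs.tsv",
                               params={"lfc_thresh": lfc_thresh, "p_thresh": p_thresh})
        products["degs"] = degs
        log_lines.append(f"de: lfc_thresh={lfc_thresh} p_thresh={p_thresh}")

    # ------------------------------------------------------------------ decay
    if "decay" in stages:
        kcfg = dict(config.get("decay", {}))
        intercept = str(kcfg.get("intercept", "fixed_zero"))
        if "input" in kcfg:
            df = pd.read_csv(kcfg["input"])
            _require({"gene", "time_h", "rel_abundance"} <= set(df.columns),
                     "decay CSV needs columns gene, time_h, rel_abundance")
            rows = list(df[["gene", "time_h", "rel_abundance"]].itertuples(index=False))
        else:
            from .simulate import simulate_decay
            sim = dict(kcfg.get("sim", {}))
            curves, _ = simulate_decay(
                true_half_life_h=float(sim.get("t_half", 3.0)),
                times_h=sim.get("times", [0, 2, 4, 8]),
                noise_sd=float(sim.get("noise_sd", 0.05)),
                n_curves=int(sim.get("n_curves", 20)),
                seed=seed + 2,
            )
            rows = [(f"gene{i + 1}", t, r) for i, c in enumerate(curves)
                    for t, r in zip(c.times, c.rel_abundance)]
        fits = fit_decay_table(rows, intercept=intercept)
        fit_df = pd.DataFrame([
            {"gene_id": g, "k_decay": f.k_decay, "t_half": f.t_half,
             "r_squared": f.r_squared, "n_points": f.n_points, "flag": f.flag}
            for g, f in sorted(fits.items())
        ])
        write_result_table(fit_df, out / "decay_fits.tsv",
                           params={"intercept": intercept})
        products["decay"] = fits
        log_lines.append(f"decay: {len(fits)} gene(s), intercept={intercept}")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return products


def _load_counts(products: dict, stage_cfg: dict, config: Mapping):
    """Counts + sheet from an upstream simulate stage or from disk."""
    if "counts" in products and "counts" not in stage_cfg:
        return products["counts"], products["samples"]
    _require("counts" in stage_cfg and "samples" in stage_cfg,
             "stage needs 'counts' and 'samples' paths when simulate is not run")
    cm = read_counts(stage_cfg["counts"])
    sheet = read_sample_sheet(stage_cfg["samples"])
    sheet.validate_against(cm)
    return cm, sheet
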