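"""End-to-end pipeline driver.

Chains the stages of the proteome-allocation analysis on synthetic (or user
supplied) inputs: network generation -> chemostat RBA solutions -> synthetic
proteomes -> flux sampling and k_app calibration -> growth simulation and
randomized-k_app ensemble -> utilization -> essentiality -> fitness.  Each
stage writes one TSV/JSON under the output directory and the run ends with a
manifest carrying the configuration hash, seeds and timings, so a rerun with
the same configuration is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import calibration, essentiality, fitness, rba, synth, utilization
from .io import config_hash, write_tsv
from .network import ReactionNetwork

log = logging.getLogger("necalloc")

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "synth": {
        "n_substrates": 3,
        "include_cbb": True,
        "include_phb": True,
        "proteome": {"noise_cv": 0.0, "n_replicates": 4, "excess": {}},
        "insertion_library": {
            "n_genes": 500, "frac_essential": 0.1, "essential_rate_ratio": 0.02,
        },
        "barcode": {
            "depth": 1_000_000, "mutants_per_gene": 6, "n_neutral": 160,
            "targets": {"target_ppc": -4.0, "target_cbbR": -6.0},
        },
    },
    "calibration": {"n_samples": 200, "flux_slack": 0.001},
    "ensemble": {"n_draws": 20},
    "simulate": {"tol_mu": 1e-4},
    "utilization": {"t_low": 33.0, "t_high": 66.0},
    "essentiality": {"window": 100, "fold": 5.0, "central_fraction": 0.8},
    "fitness": {"pseudocount": 0.5, "threshold": 3.0, "min_generations": 8.0},
    "stages": ["synth", "calibrate", "simulate", "ensemble", "utilization",
               "essentiality", "fitness"],
    "inputs": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def validate_config(config: dict) -> dict:
    """Merge with defaults and fail fast on inconsistencies (missing input
    files for enabled stages, non-positive tolerances) before any compute."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    for key, tol in (("simulate", "tol_mu"),):
        if cfg[key][tol] <= 0:
            raise ValueError(f"{key}.{tol} must be positive")
    for stage, path in (cfg.get("inputs") or {}).items():
        if path and not Path(path).exists():
            raise FileNotFoundError(f"input for stage {stage!r} not found: {path}")
    for stage in cfg["stages"]:
        if stage not in DEFAULT_CONFIG["stages"]:
            raise ValueError(f"unknown stage {stage!r}")
    return cfg


def run_pipeline(config: dict | None = None, outdir: str | Path = "results/pipeline") -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    cfg = validate_config(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config_hash": config_hash(cfg), "seed": seed,
                      "stages": {}, "outputs": {}}
    t_start = time.time()

    def stage_done(name: str, t0: float, **outputs) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        manifest["outputs"].update({k: str(v) for k, v in outputs.items()})
        log.info("stage %s done in %.2fs", name, time.time() - t0)

    # --- network -----------------------------------------------------------
    t0 = time.time()
    scfg = cfg["synth"]
    network = synth.gen_toy_network(synth.ToyNetworkConfig(
        n_substrates=scfg["n_substrates"], include_cbb=scfg["include_cbb"],
        include_phb=scfg["include_phb"], seed=seed))
    kapp_true = synth.toy_kapp_true(network)
    machineries = synth.toy_machineries()
    budgets = synth.toy_budgets()
    conditions = synth.toy_conditions()
    net_path = outdir / "network.json"
    network.to_json(net_path)
    stage_done("synth", t0, network=net_path)

    # --- chemostat solutions, proteomes, flux samples ----------------------
    solutions: dict[str, rba.RBASolution] = {}
    proteomes: dict[str, pd.Series] = {}
    samples: dict[str, calibration.FluxSamples] = {}
    kapp_est = kapp_true
    if "calibrate" in cfg["stages"]:
        t0 = time.time()
        pcfg = scfg["proteome"]
        for i, (name, cond) in enumerate(sorted(conditions.items())):
            sol = rba.solve_feasible(rba.build_rba_problem(
                network, kapp_true, cond.dilution_rate, cond, machineries, budgets))
            if not sol.feasible:
                raise RuntimeError(f"chemostat RBA infeasible for {name}")
            solutions[name] = sol
            prot, _ = synth.gen_proteome(
                sol, network, noise_cv=pcfg["noise_cv"],
                n_replicates=pcfg["n_replicates"], seed=seed + 100 + i,
                excess=pcfg.get("excess") or {}, machineries=machineries,
                condition=name)
            proteomes[name] = prot.mean
            fixed = {cond.substrate_exchange: sol.fluxes[cond.substrate_exchange]}
            samples[name] = calibration.sample_flux_space(
                network, cond, n_samples=cfg["calibration"]["n_samples"],
                seed=seed + 200 + i, fixed_fluxes=fixed,
                flux_slack=cfg["calibration"]["flux_slack"])
        kapp_est = calibration.estimate_kapp(samples, proteomes, network)
        kapp_est.to_tsv(outdir / "kapp.tsv")
        stage_done("calibrate", t0, kapp=outdir / "kapp.tsv")

    # --- growth simulation per condition ------------------------------------
    if "simulate" in cfg["stages"]:
        t0 = time.time()
        rows = []
        for name, cond in sorted(conditions.items()):
            opt = rba.maximize_growth(network, kapp_est, cond, machineries,
                                      budgets, tol_mu=cfg["simulate"]["tol_mu"])
            rows.append({"condition": name, **rba.growth_summary(opt, network, cond)})
        growth = pd.DataFrame(rows)
        write_tsv(growth, outdir / "growth.tsv")
        stage_done("simulate", t0, growth=outdir / "growth.tsv")

    # --- randomized-k_app ensemble ------------------------------------------
    if "ensemble" in cfg["stages"]:
        t0 = time.time()
        draws = calibration.sample_kapp_ensemble(
            kapp_est, n=cfg["ensemble"]["n_draws"], seed=seed + 300)
        by_condition = {
            name: [rba.maximize_growth(network, k, cond, machineries, budgets)
                   for k in draws]
            for name, cond in sorted(conditions.items())
        }
        summary = calibration.count_utilized_reactions(by_condition)
        with open(outdir / "ensemble.json", "w") as fh:
            json.dump({"counts": summary.counts,
                       "core": sorted(summary.core),
                       "union": sorted(summary.union)}, fh, indent=2)
        stage_done("ensemble", t0, ensemble=outdir / "ensemble.json")

    # --- utilization ---------------------------------------------------------
    if "utilization" in cfg["stages"] and solutions:
        t0 = time.time()
        predicted = {n: s.enzymes for n, s in solutions.items()}
        measured = {n: calibration.enzyme_concentrations(network, proteomes[n])
                    for n in solutions}
        records = utilization.utilization_table(predicted, measured)
        cats = utilization.categorize_utilization(
            records, cfg["utilization"]["t_low"], cfg["utilization"]["t_high"])
        write_tsv(records, outdir / "utilization.tsv")
        write_tsv(cats, outdir / "utilization_categories.tsv")
        stage_done("utilization", t0, utilization=outdir / "utilization.tsv")

    # --- essentiality --------------------------------------------------------
    calls = None
    if "essentiality" in cfg["stages"]:
        t0 = time.time()
        ecfg = scfg["insertion_library"]
        lib, truth = synth.gen_insertion_library(
            n_genes=ecfg["n_genes"], frac_essential=ecfg["frac_essential"],
            essential_rate_ratio=ecfg["essential_rate_ratio"], seed=seed + 400)
        calls = essentiality.classify_library(
            lib, window_genes=cfg["essentiality"]["window"],
            central_fraction=cfg["essentiality"]["central_fraction"],
            fold=cfg["essentiality"]["fold"])
        calls["truth_essential"] = calls["gene"].isin(truth.essential_genes)
        write_tsv(calls, outdir / "essentiality.tsv")
        stage_done("essentiality", t0, essentiality=outdir / "essentiality.tsv")

    # --- fitness -------------------------------------------------------------
    if "fitness" in cfg["stages"]:
        t0 = time.time()
        bcfg = scfg["barcode"]
        fitness_true = {f"neutral_{i:03d}": 0.0 for i in range(bcfg["n_neutral"])}
        fitness_true.update(bcfg.get("targets") or {})
        counts, truth = synth.gen_barcode_counts(
            fitness_true, mutants_per_gene=bcfg["mutants_per_gene"],
            depth=bcfg["depth"], seed=seed + 500)
        fcfg = cfg["fitness"]
        scores = fitness.fitness_scores(
            counts, pseudocount=fcfg["pseudocount"], threshold=fcfg["threshold"],
            min_generations=fcfg["min_generations"])
        scores["F_true"] = scores["gene"].map(truth.fitness_true)
        write_tsv(scores, outdir / "fitness.tsv")
        stage_done("fitness", t0, fitness=outdir / "fitness.tsv")

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
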