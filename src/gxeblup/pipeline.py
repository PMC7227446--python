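"""End-to-end pipeline: QC -> kinship -> model fits -> CV -> heritability.

Driven by a JSON (or YAML) run configuration with either real input paths or
a simulation block.  Every artifact written is listed in a manifest, and a
provenance sidecar records the configuration, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crossval import across_company_cv, cv0_partition, cv00_partition, cv1_partition, percent_change, run_cv
from .markers import MarkerMatrix, compute_grm, filter_markers, impute_missing
from .model import MODEL_TERMS, ModelSpec, estimate_heritability, fit_model, partition_additive, variance_partition
from .pedigree import PedigreeTable, compute_a_matrix, subfamily_summary
from .phenotypes import load_phenotypes, summarize_traits, env_anova
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)

#: interaction counterpart of each main-effect model
INTERACTION_OF = {"ELG": "ELG-GxE", "ELA": "ELA-AxE", "ELGA": "ELGA-GxE-AxE"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        return yaml.safe_load(text)
    return json.loads(text)


def validate_config(config: dict) -> dict:
    has_inputs = "inputs" in config
    has_sim = "simulation" in config
    if has_inputs == has_sim:
        raise ValueError("config must name exactly one of 'inputs' or 'simulation'")
    for m in config.get("models", []):
        if m not in MODEL_TERMS:
            raise ValueError(f"models: unknown model {m!r}")
    cv = config.get("cv")
    if cv and cv.get("scheme") not in (None, "cv1", "cv0", "cv00", "across"):
        raise ValueError(f"cv.scheme: unknown scheme {cv.get('scheme')!r}")
    return config


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute the configured stages in dependency order.

    Returns a manifest dict mapping artifact names to file paths.  All
    tables are CSV with six significant digits; a ``provenance.json``
    captures config hash, seed and version.
    """
    config = validate_config(config)
    t0 = time.time()
    out = Path(output_dir or config.get("output_dir", "gxeblup_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    trait = config.get("trait", "protein")
    manifest: dict[str, str] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.6g")
        manifest[name] = str(path)

    # -- data --------------------------------------------------------------
    if "simulation" in config:
        sim_cfg = SimulationConfig(**{**config["simulation"],
                                      "seed": stage_seed(seed, "simulate")})
        ds = simulate_dataset(sim_cfg)
        table, G, A = ds.phenotypes, ds.G, ds.A
        write("simulated_phenotypes", table.df)
        log.info("simulated %d records, %d lines, %d markers",
                 table.n_records, len(table.lines), ds.markers.n_markers)
    else:
        paths = config["inputs"]
        table = load_phenotypes(paths["phenotypes"], config.get("column_map"))
        markers = MarkerMatrix.from_csv(paths["genotypes"])
        markers, report = filter_markers(markers, config.get("qc", {}).get("max_missing", 0.10))
        freq = markers.allele_freq()
        markers = impute_missing(markers, stage_seed(seed, "impute"))
        G = compute_grm(markers, allele_freq=freq)
        ped = PedigreeTable.from_csv(paths["pedigree"])
        A = compute_a_matrix(ped, assume_fully_inbred=True,
                             member_ids=[l for l in table.lines])
        (out / "qc_report.json").write_text(json.dumps(report, indent=2))
        manifest["qc_report"] = str(out / "qc_report.json")

    trait = trait if trait in table.traits else table.traits[0]
    write("trait_summary", summarize_traits(table))
    anova_rows = []
    for t in table.traits:
        try:
            f, d1, d2 = env_anova(table, t)
            anova_rows.append({"trait": t, "F": f, "df_between": d1, "df_within": d2})
        except ValueError:
            pass
    if anova_rows:
        write("environment_anova", pd.DataFrame(anova_rows))

    G.to_csv(out / "grm.csv")
    manifest["grm"] = str(out / "grm.csv")
    A.to_csv(out / "amat.csv")
    manifest["amat"] = str(out / "amat.csv")

    # -- model fits --------------------------------------------------------
    mcmc = config.get("mcmc", {})
    model_names = config.get("models", ["ELGA-GxE-AxE"])
    var_rows, part_rows, h2_rows, add_rows = [], [], [], []
    fits = {}
    for name in model_names:
        spec = ModelSpec(name, seed=stage_seed(seed, f"fit:{name}"),
                         n_iter=mcmc.get("n_iter", 12_000),
                         burn_in=mcmc.get("burn_in", 2_000),
                         thin=mcmc.get("thin", 5))
        fit = fit_model(table, trait, spec, G=G, A=A)
        fits[name] = fit
        pct = variance_partition(fit)
        for sym, val in fit.varcomp.items():
            var_rows.append({"trait": trait, "model": name, "component": sym,
                             "estimate": val, "posterior_sd": fit.varcomp_sd[sym],
                             "pct_within_env": pct.get(sym, np.nan)})
        if "g" in spec.terms and "a" in spec.terms:
            vr_g, vr_a = partition_additive(fit)
            add_rows.append({"trait": trait, "model": name,
                             "sigma2_G": fit.varcomp["sigma2_g"],
                             "sigma2_A": fit.varcomp["sigma2_a"],
                             "VR_G": vr_g, "VR_A": vr_a})
        h = estimate_heritability(fit, table)
        h2_rows.append({"trait": trait, "model": name, "H2": h.H2, "h2": h.h2,
                        "sigma2_y": h.sigma2_y, "mh": h.mh, "ph": h.ph})
    write("variance_components", pd.DataFrame(var_rows))
    if add_rows:
        write("additive_partition", pd.DataFrame(add_rows))
    write("heritability", pd.DataFrame(h2_rows))

    # -- cross-validation --------------------------------------------------
    cv_cfg = config.get("cv")
    if cv_cfg:
        scheme = cv_cfg.get("scheme", "cv1")
        cv_rows = []
        for name in model_names:
            spec = ModelSpec(name, seed=stage_seed(seed, f"cv:{name}"),
                             n_iter=mcmc.get("n_iter", 12_000),
                             burn_in=mcmc.get("burn_in", 2_000),
                             thin=mcmc.get("thin", 5))
            if scheme == "across":
                res = across_company_cv(table, cv_cfg["validation_company"], trait,
                                        spec, k=cv_cfg.get("k", 10),
                                        seed=stage_seed(seed, "cvfolds"), G=G, A=A)
            else:
                if scheme == "cv1":
                    plan = cv1_partition(table, k=cv_cfg.get("k", 10),
                                         seed=stage_seed(seed, "cvfolds"))
                elif scheme == "cv0":
                    plan = cv0_partition(table, cv_cfg["target_year"])
                else:
                    plan = cv00_partition(table, cv_cfg["target_year"])
                res = run_cv(table, trait, spec, plan, G=G, A=A)
            cv_rows.append({"scheme": res.scheme, "model": name, "trait": trait,
                            "ability": res.ability, "se": res.se,
                            "n_folds": len(res.fold_correlations)})
        cv_df = pd.DataFrame(cv_rows)
        # percent change of main-effect models upon adding interactions
        pc_rows = []
        ability = dict(zip(cv_df["model"], cv_df["ability"]))
        for main, inter in INTERACTION_OF.items():
            if main in ability and inter in ability and ability[main] != 0:
                pc_rows.append({"trait": trait, "scheme": scheme, "main": main,
                                "interaction": inter,
                                "pct_change": percent_change(ability[main], ability[inter])})
        write("cv_summary", cv_df)
        if pc_rows:
            write("cv_percent_change", pd.DataFrame(pc_rows))

    prov = {
        "version": __version__, "seed": seed, "trait": trait,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "elapsed_s": round(time.time() - t0, 2),
        "manifest": manifest,
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    manifest["provenance"] = str(out / "provenance.json")
    return manifest
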