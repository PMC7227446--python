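"""Simulation experiments that validate the pipeline end to end.

These routines generate data from the known model, run the estimators, and
report calibration/performance statistics: variance-component recovery
coverage, null and signal cross-validation abilities, and the gain (or not)
from interaction terms under different CV schemes.  They are used both by
the test suite and by the reproduction script.

Problem sizes default to a reduced scale (a few hundred lines, the
two-company 14-environment layout) so a full experiment runs in minutes on
one CPU; the generating variance components default to the protein-content
magnitudes of a combined two-program analysis.
"""

from __future__ import annotations

import numpy as np

from .crossval import cv00_partition, cv1_partition, percent_change, run_cv
from .model import ModelSpec, fit_model
from .simulate import DEFAULT_TRUTH, SimulationConfig, simulate_dataset

#: reduced-scale two-company layout used by the recovery experiment
RECOVERY_CONFIG = dict(
    n_founders=60, n_families=90, n_singleton_crosses=20, n_markers=1200,
    missing_design_fraction=0.55,
)

#: strong-interaction scenario for the scheme-dependent gain experiment
GXE_TRUTH = {
    "sigma2_E": 0.30, "sigma2_L": 0.02, "sigma2_g": 0.10, "sigma2_a": 0.0,
    "sigma2_gE": 0.08, "sigma2_aE": 0.0, "sigma2_R": 0.10,
}


def parameter_recovery(n_reps: int = 20, seed: int = 0,
                       truth: dict | None = None,
                       config_kwargs: dict | None = None,
                       n_iter: int = 4000, burn_in: int = 1000,
                       level: float = 0.90) -> dict:
    """Frequentist coverage of posterior credible intervals.

    Simulates ``n_reps`` datasets from the full interaction model, fits the
    generating model by Gibbs sampling, and counts how often each true
    variance falls inside its central ``level`` credible interval.
    """
    truth = dict(truth or DEFAULT_TRUTH)
    kw = {**RECOVERY_CONFIG, **(config_kwargs or {}), "truth": truth}
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    cover = {k: 0 for k in truth}
    for rep in range(n_reps):
        ds = simulate_dataset(SimulationConfig(**kw, seed=seed + rep))
        spec = ModelSpec("ELGA-GxE-AxE", n_iter=n_iter, burn_in=burn_in,
                         thin=3, seed=seed + 10_000 + rep)
        fit = fit_model(ds.phenotypes, "protein", spec, G=ds.G, A=ds.A)
        for k, v in truth.items():
            lo, hi = np.quantile(fit.variance_samples[k], [lo_q, hi_q])
            cover[k] += int(lo <= v <= hi)
    return {
        "n_reps": n_reps,
        "coverage": {k: c / n_reps for k, c in cover.items()},
        "truth": truth,
    }


def cv1_null_experiment(n_reps: int = 10, seed: int = 0) -> dict:
    """CV1 prediction ability on data with zero genetic variance.

    An unbiased pipeline gives abilities scattered around zero; the summary
    reports the replicate mean and its standard error.
    """
    truth = dict(sigma2_E=0.5, sigma2_L=0.0, sigma2_g=0.0, sigma2_a=0.0,
                 sigma2_gE=0.0, sigma2_aE=0.0, sigma2_R=0.3)
    abilities = []
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_founders=20, n_families=16, n_singleton_crosses=4, n_markers=300,
            n_chromosomes=3, companies={"NS": {2015: 2, 2016: 2}},
            missing_design_fraction=0.2, truth=truth, seed=seed + rep)
        ds = simulate_dataset(cfg)
        spec = ModelSpec("ELG", n_iter=600, burn_in=150, thin=2,
                         seed=seed + 5000 + rep)
        plan = cv1_partition(ds.phenotypes, k=4, seed=seed + 7000 + rep)
        abilities.append(run_cv(ds.phenotypes, "protein", spec, plan, G=ds.G).ability)
    abilities = np.asarray(abilities)
    return {
        "n_reps": n_reps,
        "mean_ability": float(abilities.mean()),
        "se": float(abilities.std(ddof=1) / np.sqrt(n_reps)),
    }


def interaction_gain_experiment(n_reps: int = 3, seed: int = 0,
                                truth: dict | None = None,
                                n_iter: int = 1200, burn_in: int = 300) -> dict:
    """Scheme-dependent value of the marker-by-environment term.

    On data with substantial true GxE variance, compares ELG with ELG-GxE
    under CV1 (new lines, observed environments — interactions predictable)
    and CV00 (new lines, unobserved year — interactions unpredictable),
    averaging abilities over replicates.
    """
    truth = dict(truth or GXE_TRUTH)
    res = {("CV1", m): [] for m in ("ELG", "ELG-GxE")}
    res.update({("CV00", m): [] for m in ("ELG", "ELG-GxE")})
    for rep in range(n_reps):
        cfg = SimulationConfig(
            n_founders=24, n_families=30, n_singleton_crosses=6, n_markers=400,
            n_chromosomes=4,
            companies={"NS": {2015: 2, 2016: 2, 2017: 2}},
            missing_design_fraction=0.3, truth=truth, seed=seed + rep)
        ds = simulate_dataset(cfg)
        # breeding cohorts: a quarter of the lines enter the program in the
        # final year (their earlier records are removed), giving CV00 a
        # realistic new-line validation set
        table = ds.phenotypes
        rng = np.random.default_rng(seed + 100 + rep)
        with_final = [l for l in table.lines
                      if (table.df.loc[table.df.line_id == l, "year"] == 2017).any()]
        newcomers = set(rng.choice(with_final, size=len(with_final) // 4, replace=False))
        drop = table.df["line_id"].isin(newcomers) & (table.df["year"] < 2017)
        table = table.subset(~drop)
        plan1 = cv1_partition(table, k=5, seed=seed + 300 + rep)
        plan00 = cv00_partition(table, 2017)
        for model in ("ELG", "ELG-GxE"):
            spec = ModelSpec(model, n_iter=n_iter, burn_in=burn_in, thin=2,
                             seed=seed + 600 + rep)
            res[("CV1", model)].append(
                run_cv(table, "protein", spec, plan1, G=ds.G).ability)
            res[("CV00", model)].append(
                run_cv(table, "protein", spec, plan00, G=ds.G).ability)
    out = {f"{scheme}_{model}": float(np.mean(v)) for (scheme, model), v in res.items()}
    out["cv1_gain"] = out["CV1_ELG-GxE"] - out["CV1_ELG"]
    out["cv00_gain"] = out["CV00_ELG-GxE"] - out["CV00_ELG"]
    out["cv1_pct_change"] = percent_change(out["CV1_ELG"], out["CV1_ELG-GxE"])
    out["n_reps"] = n_reps
    return out
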