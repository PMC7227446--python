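"""Cross-validation schemes for multi-environment genomic prediction.

Three schemes mirror the prediction problems breeders face:

* **CV1** — random 10-fold cross-validation over *lines*: predict newly
  developed lines in environments that are themselves observed.  All records
  of a line travel together, so a validation line is never seen in training.
* **CV0** — forward (leave-one-year-out) prediction: train on all years
  before the target year, predict every line's records in the target year.
* **CV00** — forward prediction of *new* lines: validation lines are those
  observed only in the target year; no target-year record enters training.

Prediction ability is the Pearson correlation between observed phenotypes
and estimated breeding values (one pair per validation genotype by default),
averaged over folds with its standard error.  CV1 predictions add the
genotype-by-environment interaction contributions for the observed
validation environments to the breeding value, but not the environment main
effect itself (crediting the environment mean would manufacture ability out
of the trial layout rather than genetics); forward schemes use pure breeding
values, since nothing is known about an unobserved year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FitResult, ModelSpec, fit_model, predict_values
from .phenotypes import PhenotypeTable
from .relmatrix import RelationshipMatrix

log = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """Fold assignments: per fold, train and validation record positions."""

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int | None = None
    target_year: int | None = None
    validation_company: str | None = None
    info: dict = field(default_factory=dict)

    def check_leakage(self, df: pd.DataFrame) -> None:
        """Assert no validation line's own records are in its training fold."""
        for tr, va in self.folds:
            if np.intersect1d(tr, va).size:
                raise AssertionError("overlapping train/validation records")
            if self.scheme in ("CV1", "CV00", "across_company"):
                shared = set(df["line_id"].iloc[tr]) & set(df["line_id"].iloc[va])
                if shared:
                    raise AssertionError(f"validation lines leak into training: {sorted(shared)[:5]}")


@dataclass
class CVResult:
    scheme: str
    model: str
    trait: str
    fold_correlations: list[float]
    fold_sizes: list[int]

    @property
    def ability(self) -> float:
        return float(np.mean(self.fold_correlations))

    @property
    def se(self) -> float | None:
        k = len(self.fold_correlations)
        if k < 2:
            return None
        return float(np.std(self.fold_correlations, ddof=1) / np.sqrt(k))


def cv1_partition(table: PhenotypeTable, k: int = 10, seed: int = 0) -> CVPlan:
    """Random k-fold partition of lines; all records of a line share a fold."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    lines = table.lines
    if len(lines) < k:
        raise ValueError(f"{len(lines)} lines cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(lines, dtype=object)[rng.permutation(len(lines))])
    # deal remainder one per fold from the first fold onward
    sizes = np.full(k, len(lines) // k)
    sizes[: len(lines) % k] += 1
    fold_of = {}
    pos = 0
    for f, s in enumerate(sizes):
        for l in shuffled[pos: pos + s]:
            fold_of[l] = f
        pos += s
    rec_fold = table.df["line_id"].map(fold_of).to_numpy()
    idx = np.arange(table.n_records)
    folds = [(idx[rec_fold != f], idx[rec_fold == f]) for f in range(k)]
    return CVPlan("CV1", folds, seed=seed)


def cv0_partition(table: PhenotypeTable, target_year: int) -> CVPlan:
    """Forward prediction: train on years < target_year, validate on it."""
    years = table.df["year"].to_numpy()
    tr = np.where(years < target_year)[0]
    va = np.where(years == target_year)[0]
    if tr.size == 0 or va.size == 0:
        raise ValueError(f"empty training or validation side for year {target_year}")
    info = {
        "n_train_lines": table.df["line_id"].iloc[tr].nunique(),
        "n_validation_lines": table.df["line_id"].iloc[va].nunique(),
    }
    return CVPlan("CV0", [(tr, va)], target_year=target_year, info=info)


def cv00_partition(table: PhenotypeTable, target_year: int) -> CVPlan:
    """Forward prediction of new lines: validate lines seen only in the
    target year; training uses no target-year records at all."""
    df = table.df
    years = df["year"].to_numpy()
    seen_before = set(df.loc[years < target_year, "line_id"])
    if not seen_before:
        raise ValueError(f"no records before year {target_year}")
    is_target = years == target_year
    new_line = ~df["line_id"].isin(seen_before).to_numpy()
    va = np.where(is_target & new_line)[0]
    if va.size == 0:
        raise ValueError(f"no new lines in year {target_year}")
    tr = np.where(~is_target)[0]
    info = {
        "n_train_lines": df["line_id"].iloc[tr].nunique(),
        "n_validation_lines": df["line_id"].iloc[va].nunique(),
    }
    return CVPlan("CV00", [(tr, va)], target_year=target_year, info=info)


def _fold_correlation(fit: FitResult, val_df: pd.DataFrame, trait: str,
                      mode: str, aggregate: str) -> float | None:
    """Correlate observed values with predictions over one validation fold."""
    targets = list(zip(val_df["line_id"], val_df["env_id"]))
    pred = predict_values(fit, targets, mode=mode)
    obs = val_df[trait].to_numpy(float)
    if aggregate == "genotype":
        f = pd.DataFrame({"line": val_df["line_id"].to_numpy(), "obs": obs, "pred": pred})
        g = f.groupby("line").mean()
        obs, pred = g["obs"].to_numpy(), g["pred"].to_numpy()
    if len(obs) < 3:
        return None
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1])


_SCHEME_MODE = {"CV1": "breeding_value_interaction",
                "across_company": "breeding_value_interaction",
                "CV0": "breeding_value", "CV00": "breeding_value"}


def run_cv(table: PhenotypeTable, trait: str, spec: ModelSpec, plan: CVPlan,
           G: RelationshipMatrix | None = None,
           A: RelationshipMatrix | None = None,
           mode: str | None = None, aggregate: str = "genotype") -> CVResult:
    """Fit the model on each training fold and score its validation fold.

    ``mode`` overrides the per-scheme default prediction composition
    (CV1/across-company: "breeding_value_interaction"; CV0/CV00:
    "breeding_value").
    ``aggregate="genotype"`` correlates one (mean observed, predicted) pair
    per validation genotype; ``aggregate="record"`` uses record-level pairs.
    """
    df = table.df
    plan.check_leakage(df)
    mode = mode or _SCHEME_MODE[plan.scheme]
    has_y = df[trait].notna().to_numpy()
    cors, sizes = [], []
    for fi, (tr, va) in enumerate(plan.folds):
        tr = tr[has_y[tr]]
        va = va[has_y[va]]
        fit = fit_model(df.iloc[tr].reset_index(drop=True), trait, spec, G=G, A=A)
        r = _fold_correlation(fit, df.iloc[va], trait, mode, aggregate)
        if r is None:
            log.warning("fold %d skipped: fewer than 3 validation observations", fi)
            continue
        cors.append(r)
        sizes.append(len(va))
    if not cors:
        raise ValueError("all folds skipped")
    return CVResult(plan.scheme, spec.name, trait, cors, sizes)


def across_company_cv(table: PhenotypeTable, validation_company: str, trait: str,
                      spec: ModelSpec, k: int = 10, seed: int = 0,
                      G: RelationshipMatrix | None = None,
                      A: RelationshipMatrix | None = None,
                      aggregate: str = "genotype") -> CVResult:
    """CV1-style prediction with combined companies as the training pool.

    Lines of the validation company are dealt into k folds; each fold's
    validation set contains only that company's lines while its training set
    mixes both companies (all other companies' lines train in every fold).
    The model gains a fixed company (breeding-program) covariate.
    """
    df = table.df
    companies = set(df["company"])
    if validation_company not in companies:
        raise ValueError(f"company {validation_company!r} not present")
    if len(companies) < 2:
        raise ValueError("need at least two companies")
    spec = spec.with_fixed("company")

    by_line = df.groupby("line_id")["company"].agg(lambda s: sorted(set(s)))
    val_lines = [l for l, cs in by_line.items() if cs == [validation_company]]
    if len(val_lines) < k:
        raise ValueError("not enough validation-company lines for the fold count")
    rng = np.random.default_rng(seed)
    order = list(np.array(val_lines, dtype=object)[rng.permutation(len(val_lines))])
    sizes = np.full(k, len(order) // k)
    sizes[: len(order) % k] += 1
    idx = np.arange(len(df))
    folds = []
    pos = 0
    for s in sizes:
        fold_lines = set(order[pos: pos + s])
        pos += s
        in_val = df["line_id"].isin(fold_lines).to_numpy()
        folds.append((idx[~in_val], idx[in_val]))
    plan = CVPlan("across_company", folds, seed=seed,
                  validation_company=validation_company)
    return run_cv(table, trait, spec, plan, G=G, A=A, aggregate=aggregate)


def percent_change(main_ability: float, interaction_ability: float) -> float:
    """Percent change in prediction ability when interactions are added."""
    if main_ability == 0:
        raise ZeroDivisionError("main-effect ability is zero; percent change undefined")
    return 100.0 * (interaction_ability - main_ability) / main_ability
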