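"""Multi-environment trial phenotype records.

A trial record is one line (genotype) evaluated in one environment, where an
environment is a company-year-location combination such as ``NS15_1``.
Records carry up to four seed-quality traits; each trait may be missing
independently, so a record can contribute to the protein analysis but not to
test weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: canonical trait column names (protein in % dry matter, test weight in
#: kg/hL, seed-fraction weights above 2.5 / 2.2 mm sieve in %)
TRAITS = ("protein", "test_weight", "sf_abv2_5", "sf_abv2_2")

REQUIRED_COLUMNS = ("line_id", "company", "year", "location")


def make_env_id(company: str, year: int, location: int) -> str:
    """Build the canonical environment identifier.

    The identifier is the company code followed by the two-digit year and the
    location number, e.g. ``make_env_id("NS", 2015, 1) == "NS15_1"``.  The
    year is zero-padded so identifiers sort lexically within a decade.
    """
    year = int(year)
    location = int(location)
    if year < 1900:
        raise ValueError(f"year {year} out of range (expected >= 1900)")
    if location < 1:
        raise ValueError(f"location {location} must be >= 1")
    return f"{company}{year % 100:02d}_{location}"


def parse_env_id(env_id: str) -> tuple[str, int, int]:
    """Invert :func:`make_env_id`, returning (company, year mod 100, location)."""
    head, loc = env_id.rsplit("_", 1)
    return head[:-2], int(head[-2:]), int(loc)


@dataclass
class PhenotypeTable:
    """Long-format table of line-by-environment trait records.

    Wraps a :class:`pandas.DataFrame` with columns ``line_id``, ``company``,
    ``year``, ``location``, ``env_id`` and one column per trait (NaN =
    missing).  ``env_id`` is always a pure function of (company, year,
    location).
    """

    df: pd.DataFrame
    traits: tuple[str, ...] = TRAITS

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        self.traits = tuple(t for t in self.traits if t in df.columns)
        if not self.traits:
            raise ValueError("no trait columns present")
        if "env_id" not in df.columns:
            df = df.assign(
                env_id=[
                    make_env_id(c, y, l)
                    for c, y, l in zip(df["company"], df["year"], df["location"])
                ]
            )
        self.df = df
        self.validate()

    # -- basic views -------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def lines(self) -> list[str]:
        """Distinct line ids in order of first appearance."""
        return list(dict.fromkeys(self.df["line_id"]))

    @property
    def environments(self) -> list[str]:
        return list(dict.fromkeys(self.df["env_id"]))

    def validate(self) -> None:
        df = self.df
        if (df["line_id"].astype(str) == "").any() or df["line_id"].isna().any():
            raise ValueError("empty line_id in phenotype table")
        expected = [
            make_env_id(c, y, l)
            for c, y, l in zip(df["company"], df["year"], df["location"])
        ]
        if list(df["env_id"]) != expected:
            raise ValueError("env_id column inconsistent with (company, year, location)")
        if len(df) and df[list(self.traits)].isna().all(axis=1).any():
            raise ValueError("record with all traits missing (drop at load time)")

    def subset(self, mask) -> "PhenotypeTable":
        return PhenotypeTable(self.df.loc[mask].reset_index(drop=True), traits=self.traits)

    def records_for_trait(self, trait: str) -> pd.DataFrame:
        """Rows with a non-missing value for `trait`."""
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}")
        return self.df.loc[self.df[trait].notna()].reset_index(drop=True)

    def env_counts(self, trait: str) -> pd.Series:
        """Observation count per environment for one trait (Table-1 layout)."""
        sub = self.records_for_trait(trait)
        return sub.groupby("env_id")[trait].size()


def load_phenotypes(path, column_map: dict | None = None) -> PhenotypeTable:
    """Read a phenotype CSV into a validated :class:`PhenotypeTable`.

    Parameters
    ----------
    path
        CSV with header; missing trait values as empty cells or ``NA``.
    column_map
        Optional mapping from canonical names (``line_id``, ``company``,
        ``year``, ``location``, trait names) to the column names actually in
        the file.

    Records where every trait is missing are dropped (count logged).
    """
    raw = pd.read_csv(path, na_values=["NA", ""], dtype={})
    colmap = dict(column_map or {})
    rename = {v: k for k, v in colmap.items() if v in raw.columns}
    df = raw.rename(columns=rename)

    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise KeyError(f"missing required column(s): {missing_cols}")
    traits = tuple(t for t in TRAITS if t in df.columns)
    if not traits:
        raise KeyError(f"no trait columns found among {TRAITS}")

    for col in ("year", "location"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()].tolist()
        if bad:
            raise ValueError(f"unparseable {col} in rows {bad}")
        df[col] = converted.astype(int)
    for t in traits:
        df[t] = pd.to_numeric(df[t], errors="coerce")

    all_missing = df[list(traits)].isna().all(axis=1)
    if all_missing.any():
        log.info("dropping %d record(s) with all traits missing", int(all_missing.sum()))
        df = df.loc[~all_missing]

    df = df[[*REQUIRED_COLUMNS, *traits]].copy()
    df["line_id"] = df["line_id"].astype(str)
    df["company"] = df["company"].astype(str)
    return PhenotypeTable(df.reset_index(drop=True), traits=traits)


def summarize_traits(table: PhenotypeTable) -> pd.DataFrame:
    """Descriptive statistics per trait, combined and per company.

    Returns a tidy frame with columns ``scope`` ("combined" or a company
    code), ``trait``, ``n``, ``mean``, ``sd``, ``min``, ``max``.  The SD uses
    the n-1 denominator; traits with a single observation get NaN SD and a
    trait with no observations in a scope is reported with n = 0 and NaN
    statistics.
    """
    if table.n_records == 0:
        raise ValueError("empty phenotype table")
    scopes = [("combined", table.df)]
    scopes += [(c, g) for c, g in table.df.groupby("company", sort=True)]
    rows = []
    for scope, g in scopes:
        for trait in table.traits:
            vals = g[trait].dropna().to_numpy(float)
            n = vals.size
            rows.append({
                "scope": scope,
                "trait": trait,
                "n": n,
                "mean": vals.mean() if n else np.nan,
                "sd": vals.std(ddof=1) if n > 1 else np.nan,
                "min": vals.min() if n else np.nan,
                "max": vals.max() if n else np.nan,
            })
    return pd.DataFrame(rows)


def env_anova(table: PhenotypeTable, trait: str) -> tuple[float, int, int]:
    """One-way fixed-effects ANOVA of a trait across environments.

    Returns ``(F, df_between, df_within)`` where F is the ratio of the
    between-environment to the within-environment mean square.  Environments
    with no non-missing record are excluded (with a warning).
    """
    sub = table.records_for_trait(trait)
    groups = [g.to_numpy(float) for _, g in sub.groupby("env_id")[trait] if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two environments with data")
    k = len(groups)
    n = sum(len(g) for g in groups)
    f, _ = stats.f_oneway(*groups)
    # identical groups give 0/0 in scipy; the between-group MS is then zero
    if np.isnan(f):
        grand = np.concatenate(groups)
        ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
        f = 0.0 if ss_between < 1e-12 else np.inf
    return float(f), k - 1, n - k
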