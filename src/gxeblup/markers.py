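"""SNP marker QC, imputation and the VanRaden genomic relationship matrix.

Genotypes are reference-allele dosages in {0, 1, 2} with NaN for missing.
The QC pipeline mirrors standard practice for array genotypes on inbred
lines: drop monomorphic markers and markers with a missing fraction above a
threshold, then impute remaining holes by drawing from each marker's
empirical genotype distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmatrix import RelationshipMatrix

log = logging.getLogger(__name__)

VALID_CODES = (0.0, 1.0, 2.0)


@dataclass
class MarkerMatrix:
    """Lines x markers dosage matrix with per-marker allele frequencies."""

    line_ids: list[str]
    marker_ids: list[str]
    genotypes: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.genotypes = np.asarray(self.genotypes, float)
        if self.genotypes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("genotype matrix shape inconsistent with id lists")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if obs.size and not np.isin(obs, VALID_CODES).all():
            bad = np.argwhere(~np.isin(np.nan_to_num(self.genotypes, nan=0.0), VALID_CODES)
                              & ~np.isnan(self.genotypes))
            i, j = bad[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[i, j]} at line "
                f"{self.line_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_freq(self) -> np.ndarray:
        """Reference-allele frequency per marker from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.genotypes, index=self.line_ids,
                     columns=self.marker_ids).to_csv(path, na_rep="NA")


def filter_markers(markers: MarkerMatrix, max_missing: float = 0.10
                   ) -> tuple[MarkerMatrix, dict]:
    """Drop monomorphic markers and markers with too much missingness.

    A marker is monomorphic when all its *non-missing* dosages are identical;
    it is too sparse when its missing fraction is strictly greater than
    ``max_missing`` (a marker at exactly the threshold is retained).  Returns
    the filtered matrix and a report dict with counts per removal reason.
    """
    X = markers.genotypes
    miss = np.isnan(X).mean(axis=0)
    n_obs = (~np.isnan(X)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mono = (np.nanmax(X, axis=0) == np.nanmin(X, axis=0)) | (n_obs == 0)
    too_missing = miss > max_missing
    keep = ~(mono | too_missing)
    if not keep.any():
        raise ValueError("all markers removed by filtering")
    report = {
        "n_input": markers.n_markers,
        "n_monomorphic": int(mono.sum()),
        "n_high_missing": int((too_missing & ~mono).sum()),
        "n_retained": int(keep.sum()),
    }
    log.info("marker filter: %s", report)
    out = MarkerMatrix(markers.line_ids,
                       [m for m, k in zip(markers.marker_ids, keep) if k],
                       X[:, keep])
    return out, report


def impute_missing(markers: MarkerMatrix, seed: int) -> MarkerMatrix:
    """Fill missing dosages by sampling each marker's observed distribution.

    Every missing cell of marker *m* is replaced by a draw from the empirical
    distribution of the observed genotype codes of *m* (the "random"
    marginal-distribution algorithm).  The RNG stream is keyed by
    (seed, marker index) so the result is independent of marker processing
    order.  Non-missing cells are never changed.
    """
    X = markers.genotypes.copy()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(markers.n_markers)
    for j in range(markers.n_markers):
        col = X[:, j]
        hole = np.isnan(col)
        if not hole.any():
            continue
        obs = col[~hole]
        if obs.size == 0:
            raise ValueError(f"marker {markers.marker_ids[j]!r} has no observed values")
        rng = np.random.default_rng(children[j])
        X[hole, j] = rng.choice(obs, size=int(hole.sum()), replace=True)
    return MarkerMatrix(markers.line_ids, markers.marker_ids, X)


def compute_grm(markers: MarkerMatrix, mode: str = "vanraden-centered",
                allele_freq: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = XX' / (2 * sum p(1-p)).

    ``mode="vanraden-centered"`` (default): columns are centered at twice the
    allele frequency and the cross-product is divided by 2*sum(p_m*(1-p_m)).
    ``mode="centered-standardized"``: columns are additionally scaled to unit
    variance and the cross-product divided by the marker count.

    ``allele_freq`` lets the caller center at frequencies computed before
    imputation (the recommended workflow); by default frequencies come from
    the matrix itself.
    """
    X = markers.genotypes
    if np.isnan(X).any():
        raise ValueError("missing genotypes present; impute first")
    p = markers.allele_freq() if allele_freq is None else np.asarray(allele_freq, float)
    if ((p <= 0) | (p >= 1)).any():
        fixed = [markers.marker_ids[j] for j in np.where((p <= 0) | (p >= 1))[0][:5]]
        raise ValueError(f"fixed allele frequency (p=0 or 1) at markers {fixed}")
    Xc = X - 2.0 * p
    if mode == "vanraden-centered":
        denom = 2.0 * np.sum(p * (1.0 - p))
        G = (Xc @ Xc.T) / denom
    elif mode == "centered-standardized":
        sd = Xc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = Xc / sd
        G = (Z @ Z.T) / markers.n_markers
    else:
        raise ValueError(f"unknown GRM mode {mode!r}")
    G = (G + G.T) / 2.0
    return RelationshipMatrix(markers.line_ids, G, kind="genomic")
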