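"""Line-by-line relationship (covariance) matrices.

Both the marker-based genomic relationship matrix G and the pedigree-based
numerator relationship matrix A are symmetric positive semi-definite matrices
indexed by line id; this module provides the shared container with alignment,
validation and square-CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RelationshipMatrix:
    line_ids: list[str]
    values: np.ndarray
    kind: str = "genomic"  # "genomic" | "pedigree"

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.values = np.asarray(self.values, float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")
        self._index = {l: i for i, l in enumerate(self.line_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate line ids")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def indices(self, lines) -> np.ndarray:
        try:
            return np.array([self._index[str(l)] for l in lines], dtype=int)
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} absent from {self.kind} matrix") from None

    def __contains__(self, line: str) -> bool:
        return str(line) in self._index

    def submatrix(self, rows, cols=None) -> np.ndarray:
        ri = self.indices(rows)
        ci = ri if cols is None else self.indices(cols)
        return self.values[np.ix_(ri, ci)]

    def subset(self, lines) -> "RelationshipMatrix":
        return RelationshipMatrix(list(lines), self.submatrix(lines), kind=self.kind)

    def min_eigenvalue_ratio(self) -> float:
        """min(eig)/max(eig); >= -1e-8 for a numerically PSD matrix."""
        w = np.linalg.eigvalsh(self.values)
        top = max(w[-1], 1e-300)
        return float(w[0] / top)

    def is_psd(self, rtol: float = 1e-8) -> bool:
        return self.min_eigenvalue_ratio() >= -rtol

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "genomic") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError("row and column line ids differ")
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind=kind)
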