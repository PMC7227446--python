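"""Pedigree handling and the additive (numerator) relationship matrix.

The A-matrix is built by the tabular (recursive) method: processing the
pedigree in topological order, a founder gets diagonal 1 and zero
relationship to earlier entries; for an individual i with parents p1, p2,
a(i, j) = 0.5 * (a(j, p1) + a(j, p2)) for every earlier j, and the diagonal
is a(i, i) = 1 + 0.5 * a(p1, p2).  Unknown parents contribute zero.

For fully inbred line programs the matrix can be rescaled to the
identity-by-descent probability scale (diagonal forced to 1, off-diagonals
a(i,j)/sqrt(a(i,i)*a(j,j))), which yields values in [0, 1].
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmatrix import RelationshipMatrix

log = logging.getLogger(__name__)

UNKNOWN = ("", "0", "NA", "na", "None")


def _is_unknown(p) -> bool:
    return p is None or (isinstance(p, float) and np.isnan(p)) or str(p) in UNKNOWN


@dataclass
class PedigreeTable:
    """Rows of (id, parent1, parent2); unknown parents stored as None."""

    ids: list[str]
    parent1: list[str | None]
    parent2: list[str | None]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.parent1 = [None if _is_unknown(p) else str(p) for p in self.parent1]
        self.parent2 = [None if _is_unknown(p) else str(p) for p in self.parent2]
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i in self.ids if self.ids.count(i) > 1]
            raise ValueError(f"duplicate pedigree id(s): {sorted(set(dup))[:5]}")
        if not (len(self.ids) == len(self.parent1) == len(self.parent2)):
            raise ValueError("column length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    def parents_of(self) -> dict[str, tuple[str | None, str | None]]:
        return {i: (p1, p2) for i, p1, p2 in zip(self.ids, self.parent1, self.parent2)}

    @classmethod
    def from_csv(cls, path) -> "PedigreeTable":
        df = pd.read_csv(path, dtype=str, na_values=["NA", ""], keep_default_na=False)
        cols = {c.lower(): c for c in df.columns}
        idc = cols.get("id", df.columns[0])
        p1c = cols.get("parent1", df.columns[1])
        p2c = cols.get("parent2", df.columns[2])
        return cls(list(df[idc]), list(df[p1c]), list(df[p2c]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"id": self.ids,
                      "parent1": ["0" if p is None else p for p in self.parent1],
                      "parent2": ["0" if p is None else p for p in self.parent2]}
                     ).to_csv(path, index=False)


def sort_pedigree(ped: PedigreeTable) -> PedigreeTable:
    """Topologically order a pedigree so every parent precedes its offspring.

    Parents referenced but absent from the id column are auto-inserted as
    founders (with a warning).  The sort is stable: it keeps the input order
    wherever that order is already consistent.  A parentage cycle raises a
    ValueError naming the ids involved.
    """
    known = set(ped.ids)
    parents = ped.parents_of()
    extra: list[str] = []
    for p1, p2 in parents.values():
        for p in (p1, p2):
            if p is not None and p not in known:
                known.add(p)
                extra.append(p)
    if extra:
        log.warning("auto-inserting %d referenced parent(s) as founders", len(extra))

    order: list[str] = []
    placed: set[str] = set()
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 2:
            return
        if state.get(node) == 1:
            cyc = stack[stack.index(node):] + [node]
            raise ValueError(f"pedigree cycle detected: {' -> '.join(cyc)}")
        state[node] = 1
        stack.append(node)
        for p in parents.get(node, (None, None)):
            if p is not None:
                visit(p, stack)
        stack.pop()
        state[node] = 2
        order.append(node)
        placed.add(node)

    for i in extra + ped.ids:
        visit(i, [])

    return PedigreeTable(order,
                         [parents.get(i, (None, None))[0] for i in order],
                         [parents.get(i, (None, None))[1] for i in order])


def compute_a_matrix(ped: PedigreeTable, assume_fully_inbred: bool = False,
                     member_ids=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    With ``assume_fully_inbred`` the standard A is rescaled to the IBD
    probability scale of homozygous lines: diagonal forced to 1 and
    off-diagonals divided by sqrt(a_ii * a_jj), giving entries in [0, 1].
    ``member_ids`` optionally restricts the returned matrix to a subset of
    ids (the full recursion still runs over all ancestors).
    """
    ped = sort_pedigree(ped)
    n = len(ped)
    idx = {i: k for k, i in enumerate(ped.ids)}
    A = np.zeros((n, n))
    for k, (p1, p2) in enumerate(zip(ped.parent1, ped.parent2)):
        i1 = idx[p1] if p1 is not None else -1
        i2 = idx[p2] if p2 is not None else -1
        if k > 0:
            row = np.zeros(k)
            if i1 >= 0:
                row += A[i1, :k]
            if i2 >= 0:
                row += A[i2, :k]
            A[k, :k] = 0.5 * row
            A[:k, k] = A[k, :k]
        A[k, k] = 1.0 + (0.5 * A[i1, i2] if (i1 >= 0 and i2 >= 0) else 0.0)
    if assume_fully_inbred:
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        np.fill_diagonal(A, 1.0)
    out = RelationshipMatrix(ped.ids, A, kind="pedigree")
    if member_ids is not None:
        out = out.subset([str(m) for m in member_ids])
    return out


def subfamily_summary(ped: PedigreeTable, member_ids=None) -> dict:
    """Full-sib subfamily structure of a set of lines.

    Members are grouped by unordered parent pair.  A *subfamily* is a group
    with >= 2 members; a member whose parent pair is unique is a *singleton
    cross*; members with both parents unknown go in a founder/unknown bucket.
    """
    parents = ped.parents_of()
    members = list(ped.ids) if member_ids is None else [str(m) for m in member_ids]
    missing = [m for m in members if m not in parents]
    if missing:
        raise KeyError(f"member id(s) not in pedigree: {missing[:5]}")
    fams: dict[frozenset, list[str]] = defaultdict(list)
    founders = []
    for m in members:
        p1, p2 = parents[m]
        if p1 is None and p2 is None:
            founders.append(m)
        else:
            fams[frozenset((p1 or "?", p2 or "?"))].append(m)
    sizes = sorted(len(v) for v in fams.values() if len(v) >= 2)
    return {
        "n_subfamilies": sum(1 for v in fams.values() if len(v) >= 2),
        "n_singleton_crosses": sum(1 for v in fams.values() if len(v) == 1),
        "n_founder_or_unknown": len(founders),
        "min_family_size": sizes[0] if sizes else 0,
        "max_family_size": sizes[-1] if sizes else 0,
        "family_sizes": sizes,
    }
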