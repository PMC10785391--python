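"""Pedigree handling and the numerator relationship matrix A.

The additive (numerator) relationship matrix holds the pedigree-expected
additive genetic relationships between animals; its diagonal is 1 + F_i
where F_i is the inbreeding coefficient.  It is built with the tabular
method on a topologically sorted pedigree:

    a_ij = (a_{j,sire(i)} + a_{j,dam(i)}) / 2      for j < i
    a_ii = 1 + a_{sire(i),dam(i)} / 2

with an unknown parent contributing zero.  At herd scale (a few hundred
to a few thousand animals) the dense matrix is built directly; no sparse
A-inverse machinery is needed.
"""

from __future__ import annotations

import heapq
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PedigreeError", "read_pedigree", "sort_pedigree", "a_matrix", "inbreeding"]

UNKNOWN = "0"


class PedigreeError(ValueError):
    pass


def _norm(ped: pd.DataFrame) -> pd.DataFrame:
    ped = ped[["animal", "sire", "dam"]].astype(str).copy()
    ped.replace({"nan": UNKNOWN, "None": UNKNOWN, "": UNKNOWN}, inplace=True)
    if ped["animal"].duplicated().any():
        dup = ped.loc[ped["animal"].duplicated(), "animal"].iloc[0]
        raise PedigreeError(f"duplicate animal id {dup!r}")
    if (ped["animal"] == UNKNOWN).any():
        raise PedigreeError("animal id '0' is reserved for unknown parents")
    return ped


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read an animal,sire,dam CSV (0 = unknown parent)."""
    ped = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in ("animal", "sire", "dam") if c not in ped.columns]
    if missing:
        raise PedigreeError(f"pedigree CSV missing columns {missing}")
    return _norm(ped)


def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Stable topological sort so every parent precedes its offspring.

    Parents that never appear as animals are added as founders at the top.
    Raises :class:`PedigreeError` naming a cycle if one exists.
    """
    ped = _norm(ped)
    animals = list(ped["animal"])
    known = set(animals)
    # implicit founders: parents with no own record
    implicit = []
    for col in ("sire", "dam"):
        for p in ped[col]:
            if p != UNKNOWN and p not in known:
                known.add(p)
                implicit.append(p)
    if implicit:
        ped = pd.concat(
            [pd.DataFrame({"animal": implicit, "sire": UNKNOWN, "dam": UNKNOWN}), ped],
            ignore_index=True,
        )

    parents = {r.animal: [p for p in (r.sire, r.dam) if p != UNKNOWN]
               for r in ped.itertuples(index=False)}
    indeg = {a: len(ps) for a, ps in parents.items()}
    children: dict[str, list[str]] = {a: [] for a in parents}
    for a, ps in parents.items():
        for p in ps:
            children[p].append(a)

    # stable: among all currently-available animals, emit the one that
    # appears first in the input, so an already-sorted pedigree is unchanged
    pos = {a: i for i, a in enumerate(ped["animal"])}
    order = []
    ready = [(pos[a], a) for a in ped["animal"] if indeg[a] == 0]
    heapq.heapify(ready)
    placed = set()
    while ready:
        _, a = heapq.heappop(ready)
        order.append(a)
        placed.add(a)
        for ch in children[a]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(ready, (pos[ch], ch))
    if len(order) < len(parents):
        # walk parent links among the stuck nodes to name one cycle
        stuck = next(a for a in ped["animal"] if a not in placed)
        seen: list[str] = []
        node = stuck
        while node not in seen:
            seen.append(node)
            node = next(p for p in parents[node] if p not in placed)
        cycle = seen[seen.index(node):] + [node]
        raise PedigreeError(f"pedigree cycle: {' -> '.join(cycle)}")
    return ped.set_index("animal").loc[order].reset_index()


def a_matrix(ped: pd.DataFrame, *, assume_sorted: bool = False) -> tuple[np.ndarray, list[str]]:
    """Numerator relationship matrix by the tabular method.

    Returns ``(A, ids)`` with ``A[i, i] = 1 + F_i``.  The pedigree is
    topologically sorted first unless ``assume_sorted``; with
    ``assume_sorted=True`` an out-of-order pedigree raises.
    """
    if assume_sorted:
        ped = _norm(ped)
        seen: set[str] = set()
        for r in ped.itertuples(index=False):
            for p in (r.sire, r.dam):
                if p != UNKNOWN and p not in seen:
                    raise PedigreeError(
                        f"pedigree not sorted: parent {p!r} of {r.animal!r} not seen yet"
                    )
            seen.add(r.animal)
    else:
        ped = sort_pedigree(ped)

    ids = list(ped["animal"])
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [idx.get(s, -1) if s != UNKNOWN else -1 for s in ped["sire"]]
    dams = [idx.get(d, -1) if d != UNKNOWN else -1 for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A, ids


def inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Inbreeding coefficients F (diagonal of A minus one)."""
    A, ids = a_matrix(ped)
    return pd.Series(np.diag(A) - 1.0, index=ids, name="F")
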