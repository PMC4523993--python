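"""Pedigree-based additive (numerator) relationship matrix.

The polygenic random effect of the mixed models uses the classical
A-matrix: ``A[j, k]`` is twice the kinship coefficient between individuals
``j`` and ``k``, built by the tabular method.  Founders are treated as
unrelated and non-inbred; inbreeding accumulating in later generations is
handled by the recursion itself.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "build_A"]

#: Tokens accepted as "parent unknown" in pedigree tables.
UNKNOWN = {"0", "", ".", "na", "nan", "none"}


def _normalise(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s.lower() in UNKNOWN else s


class Pedigree:
    """Validated pedigree: (id, sire, dam) records in founder-first order.

    Accepts records in any order; a topological sort is performed so that
    parents always precede offspring.  Duplicate ids, unknown-but-named
    parents appearing nowhere, and cycles (an individual being its own
    ancestor) raise ``ValueError``.
    """

    def __init__(self, records: pd.DataFrame | Sequence[tuple]):
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame(records, columns=["id", "sire", "dam"])
        missing = {"id", "sire", "dam"} - set(records.columns)
        if missing:
            raise ValueError(f"pedigree table lacks columns {sorted(missing)}")

        ids = [str(x).strip() for x in records["id"]]
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate pedigree ids: {dupes}")
        parents = {
            i: (_normalise(s), _normalise(d))
            for i, s, d in zip(ids, records["sire"], records["dam"])
        }
        known = set(ids)
        for i, (s, d) in parents.items():
            for par in (s, d):
                if par is not None and par not in known:
                    raise ValueError(f"parent {par!r} of {i!r} has no pedigree record")

        # Kahn topological sort; leftover nodes mean a cycle.
        order: list[str] = []
        n_parents = {
            i: sum(p is not None for p in ps) for i, ps in parents.items()
        }
        children: dict[str, list[str]] = {i: [] for i in ids}
        for i, (s, d) in parents.items():
            for par in {s, d} - {None}:
                children[par].append(i)
        queue = [i for i in ids if n_parents[i] == 0]
        seen_edges = {i: 0 for i in ids}
        while queue:
            node = queue.pop()
            order.append(node)
            for child in children[node]:
                s, d = parents[child]
                seen_edges[child] += (s == node) + (d == node)
                if seen_edges[child] == n_parents[child]:
                    queue.append(child)
        if len(order) != len(ids):
            stuck = sorted(set(ids) - set(order))
            raise ValueError(f"pedigree contains a cycle involving {stuck}")

        self.ids: list[str] = order
        self.parents = parents
        self._index = {i: k for k, i in enumerate(order)}

    def __len__(self) -> int:
        return len(self.ids)


def build_A(ped: Pedigree | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Build the additive relationship matrix by the tabular method.

    With individuals sorted founders-first, ``A[k, k] = 1 + 0.5 * A[s, d]``
    and ``A[j, k] = 0.5 * (A[j, s] + A[j, d])`` for ``j`` processed before
    ``k``; an unknown parent contributes 0.  The result is symmetric
    positive semidefinite with unit (or larger, if inbred) diagonal.

    Returns
    -------
    (A, ids)
        The matrix and the id order of its rows/columns (founder-first).
    """
    if not isinstance(ped, Pedigree):
        ped = Pedigree(ped)
    n = len(ped)
    A = np.zeros((n, n))
    idx = ped._index
    for k, ind in enumerate(ped.ids):
        s, d = ped.parents[ind]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        A[k, k] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        for j in range(k):
            v = 0.0
            if si is not None:
                v += 0.5 * A[j, si]
            if di is not None:
                v += 0.5 * A[j, di]
            A[j, k] = A[k, j] = v
    return A, list(ped.ids)
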