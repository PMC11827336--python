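"""Pedigree container and the tabular-method numerator relationship matrix."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["Pedigree"]

UNKNOWN = None


class Pedigree:
    """Directed acyclic parent map over individuals.

    Parents are identified by string id or ``None`` when unknown.  A parent
    referenced but never listed as an individual is added implicitly as a
    founder with unknown parents.
    """

    def __init__(
        self,
        ids: Sequence[str],
        sire: Sequence[Optional[str]],
        dam: Sequence[Optional[str]],
    ) -> None:
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual identifiers in pedigree")
        if not (len(ids) == len(sire) == len(dam)):
            raise ValueError("ids, sire and dam must have equal length")
        known = set(ids)
        extra: List[str] = []
        for p in list(sire) + list(dam):
            if p is not None and p not in known and p not in extra:
                extra.append(p)
        self.ids: List[str] = extra + ids
        parent_map: Dict[str, Tuple[Optional[str], Optional[str]]] = {
            i: (None, None) for i in extra
        }
        for i, s, d in zip(ids, sire, dam):
            if s == i or d == i:
                raise ValueError(f"individual {i!r} listed as its own parent")
            parent_map[i] = (s, d)
        self.parent_map = parent_map

    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a table with columns id, sire, dam ('0'/NaN = unknown)."""

        def clean(v):
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "0":
                return None
            return str(v)

        return cls(
            [str(v) for v in df["id"]],
            [clean(v) for v in df["sire"]],
            [clean(v) for v in df["dam"]],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.parent_map[i][0] or "0" for i in self.ids],
                "dam": [self.parent_map[i][1] or "0" for i in self.ids],
            }
        )

    def parents_of(self, ind: str) -> Tuple[Optional[str], Optional[str]]:
        return self.parent_map[ind]

    def with_parents(self, ind: str, sire: Optional[str], dam: Optional[str]) -> "Pedigree":
        """Return a copy with one individual's parents replaced."""
        new = Pedigree.__new__(Pedigree)
        new.ids = list(self.ids)
        new.parent_map = dict(self.parent_map)
        new.parent_map[ind] = (sire, dam)
        return new

    def __contains__(self, ind: str) -> bool:
        return ind in self.parent_map

    def __len__(self) -> int:
        return len(self.ids)

    # ------------------------------------------------------------------
    def topological_order(self) -> List[str]:
        """Parents-before-offspring ordering; raises on a pedigree cycle."""
        children: Dict[str, List[str]] = {i: [] for i in self.ids}
        indeg = {i: 0 for i in self.ids}
        for i in self.ids:
            for p in self.parent_map[i]:
                if p is not None:
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in self.ids if indeg[i] == 0]
        order: List[str] = []
        while queue:
            node = queue.pop()
            order.append(node)
            for c in children[node]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.ids):
            raise ValueError("pedigree contains a cycle (individual is its own ancestor)")
        return order

    def numerator_matrix(self) -> Tuple[np.ndarray, List[str]]:
        """Numerator relationship matrix A by the tabular method.

        ``A[i, i] = 1 + 0.5 * A[s, d]`` and ``A[i, j] = 0.5 * (A[j, s] +
        A[j, d])`` with unknown parents contributing zero; founders with
        unknown, unrelated parents get a diagonal of exactly one.
        """
        order = self.topological_order()
        idx = {ind: k for k, ind in enumerate(order)}
        n = len(order)
        A = np.zeros((n, n))
        for k, ind in enumerate(order):
            s, d = self.parent_map[ind]
            si = idx[s] if s is not None else -1
            di = idx[d] if d is not None else -1
            if k:
                row = np.zeros(k)
                if si >= 0:
                    row += A[si, :k]
                if di >= 0:
                    row += A[di, :k]
                row *= 0.5
                A[k, :k] = row
                A[:k, k] = row
            A[k, k] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        # return in the pedigree's own id order
        perm = np.array([idx[i] for i in self.ids])
        return A[np.ix_(perm, perm)], list(self.ids)
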