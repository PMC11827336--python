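"""Pedigree and genomic relationship matrices.

Builds the numerator relationship matrix A (tabular method), its
genotyped submatrix A22, the additive genomic matrix

    Ga = Z Z' / (2 sum_j p_j (1 - p_j)),   Z_ij in {-2p, 1-2p, 2-2p}

with the counted allele anchored to the second most frequent one, the
dominance genomic matrix

    Gd = S S' / (4 sum_j (p_j (1 - p_j))^2),
    S_ij in {-2p^2, 2p(1-p), -2(1-p)^2}  for dosages 0, 1, 2,

and the blended G* = alpha * Ga + (1 - alpha) * A22 used to restore
invertibility when clones or marker shortage make Ga singular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "RelationshipMatrix",
    "numerator_A",
    "subset_A22",
    "vanraden_Ga",
    "vitezica_Gd",
    "blend",
    "DEFAULT_BLEND_ALPHA",
]

DEFAULT_BLEND_ALPHA = 0.98


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix over an ordered individual list."""

    values: np.ndarray
    ids: List[str]
    kind: str  # A | A22 | Ga | Gd | Gstar
    allele_freqs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        index = {i: k for k, i in enumerate(self.ids)}
        try:
            sel = np.array([index[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in matrix") from None
        return RelationshipMatrix(
            self.values[np.ix_(sel, sel)], list(ids), self.kind, self.allele_freqs
        )


def numerator_A(ped: Pedigree) -> RelationshipMatrix:
    """Expected additive relatedness from the pedigree (tabular method)."""
    A, ids = ped.numerator_matrix()
    return RelationshipMatrix(A, ids, "A")


def subset_A22(A: RelationshipMatrix, genotyped_ids: Sequence[str]) -> RelationshipMatrix:
    """Row/column restriction of A to the genotyped individuals."""
    out = A.subset(genotyped_ids)
    out.kind = "A22"
    return out


def _anchored_dosages(
    g: GenotypeMatrix, freqs: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean-imputed dosages re-coded so the counted allele has p <= 0.5."""
    if freqs is None:
        freqs = g.allele_freq()
        freqs = np.where(np.isfinite(freqs), freqs, 0.0)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (g.n_markers,):
            raise ValueError("freqs must have one entry per marker")
    M = g.mean_imputed()
    swap = freqs > 0.5
    if swap.any():
        M = M.copy()
        M[:, swap] = 2.0 - M[:, swap]
        freqs = np.where(swap, 1.0 - freqs, freqs)
    return M, freqs


def vanraden_Ga(
    g: GenotypeMatrix, freqs: Optional[np.ndarray] = None
) -> RelationshipMatrix:
    """Additive genomic relationship matrix from centered dosages.

    Missing calls are mean-imputed per marker before centering.  Allele
    frequencies default to in-sample estimates; pass precomputed values to
    keep clones from re-weighting them (estimate once per ortet, not per
    ramet).
    """
    M, p = _anchored_dosages(g, freqs)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    Z = M - 2.0 * p
    return RelationshipMatrix((Z @ Z.T) / denom, list(g.samples), "Ga", allele_freqs=p)


def vitezica_Gd(
    g: GenotypeMatrix, freqs: Optional[np.ndarray] = None
) -> RelationshipMatrix:
    """Dominance genomic relationship matrix from dominance-deviation codes.

    Observed dosages map to {-2p^2, 2p(1-p), -2(1-p)^2}; a missing call
    contributes its Hardy-Weinberg expectation (zero) instead.
    """
    if freqs is None:
        p = g.allele_freq()
        p = np.where(np.isfinite(p), p, 0.0)
    else:
        p = np.asarray(freqs, dtype=float)
    swap = p > 0.5
    d = g.dosages
    if swap.any():
        d = d.copy()
        d[:, swap] = 2.0 - d[:, swap]
        p = np.where(swap, 1.0 - p, p)
    denom = 4.0 * float(np.sum((p * (1.0 - p)) ** 2))
    if denom == 0.0:
        raise ValueError("all markers monomorphic: zero dominance denominator")
    s0 = -2.0 * p**2
    s1 = 2.0 * p * (1.0 - p)
    s2 = -2.0 * (1.0 - p) ** 2
    S = np.where(d == 0, s0, np.where(d == 1, s1, np.where(d == 2, s2, 0.0)))
    S = np.where(np.isfinite(d), S, 0.0)
    return RelationshipMatrix((S @ S.T) / denom, list(g.samples), "Gd", allele_freqs=p)


def blend(
    Ga: RelationshipMatrix,
    A22: RelationshipMatrix,
    alpha: float = DEFAULT_BLEND_ALPHA,
) -> RelationshipMatrix:
    """Convex combination G* = alpha * Ga + (1 - alpha) * A22.

    With alpha < 1 and a positive definite A22 the blend is positive
    definite even when Ga is singular (e.g. duplicated clone rows).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if list(Ga.ids) != list(A22.ids):
        raise ValueError("Ga and A22 must be over the same individuals in the same order")
    return RelationshipMatrix(
        alpha * Ga.values + (1.0 - alpha) * A22.values,
        list(Ga.ids),
        "Gstar",
        allele_freqs=Ga.allele_freqs,
    )
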