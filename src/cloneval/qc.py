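"""Marker/sample quality control, panel merging and pedigree verification.

Filters follow the usual SNP-array practice for breeding populations:
markers are dropped for low call rate, low minor allele frequency or a
duplicated map position, then samples with too many missing calls are
removed.  Parent-offspring assignments are checked through opposing
homozygotes (dosage 0 against dosage 2 at the same marker), which cannot
occur in a true parent-offspring pair without a genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "QCThresholds",
    "QCReport",
    "intersect_panels",
    "filter_markers_and_samples",
    "mendelian_error_rate",
    "opposing_homozygote_matrix",
    "verify_and_correct_pedigree",
]


@dataclass
class QCThresholds:
    """Exclusion thresholds; defaults match the evaluation this package mirrors."""

    marker_call_rate_min: float = 0.95
    maf_min: float = 0.02
    sample_call_rate_min: float = 0.80
    mendel_error_max: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "marker_call_rate_min",
            "maf_min",
            "sample_call_rate_min",
            "mendel_error_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    markers_in: int
    markers_removed_by_rule: Dict[str, int]
    samples_removed: int
    markers_out: int
    samples_out: int

    def to_dict(self) -> Dict:
        return {
            "markers_in": self.markers_in,
            "markers_removed_by_rule": dict(self.markers_removed_by_rule),
            "samples_removed": self.samples_removed,
            "markers_out": self.markers_out,
            "samples_out": self.samples_out,
        }


# ----------------------------------------------------------------------
def intersect_panels(panel_a: GenotypeMatrix, panel_b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two platforms on their shared markers.

    The output stacks all samples over exactly the markers present in both
    panels, in panel A's marker order.  When allele labels show the two
    platforms counted opposite alleles at a marker, panel B's dosages are
    flipped (d -> 2 - d) so both agree on a single reference.
    """
    shared = [m for m in panel_a.markers if m in set(panel_b.markers)]
    if not shared:
        raise ValueError("panels share no markers")
    a = panel_a.subset(markers=shared)
    b = panel_b.subset(markers=shared)
    if a.alleles is not None and b.alleles is not None:
        flip = np.array(
            [
                tuple(ab) == (bb[1], bb[0])
                for ab, bb in zip(a.alleles, b.alleles)
            ]
        )
        mismatched = [
            m
            for m, ab, bb in zip(shared, a.alleles, b.alleles)
            if tuple(ab) != tuple(bb) and tuple(ab) != (bb[1], bb[0])
        ]
        if mismatched:
            raise ValueError(f"incompatible alleles for markers {mismatched[:5]}")
        if flip.any():
            b = b.copy()
            b.dosages[:, flip] = 2.0 - b.dosages[:, flip]
            b.alleles[flip] = b.alleles[flip][:, ::-1]
    overlap = set(a.samples) & set(b.samples)
    if overlap:
        raise ValueError(f"samples present in both panels: {sorted(overlap)[:5]}")
    return GenotypeMatrix(
        np.vstack([a.dosages, b.dosages]),
        list(a.samples) + list(b.samples),
        shared,
        a.alleles,
    )


def filter_markers_and_samples(
    g: GenotypeMatrix,
    thresholds: Optional[QCThresholds] = None,
    duplicate_positions: Optional[Sequence[str]] = None,
    exclude_markers: Optional[Sequence[str]] = None,
) -> Tuple[GenotypeMatrix, QCReport]:
    """Apply marker filters first, then the sample call-rate filter.

    Rule order is deterministic: pre-supplied exclusion list (e.g. platform
    clustering-quality rejects), duplicate positions, marker call rate,
    MAF (computed on non-missing calls, strict '<' so a MAF exactly at the
    threshold is retained), then sample call rate.
    """
    t = thresholds or QCThresholds()
    removed: Dict[str, int] = {}
    keep = np.ones(g.n_markers, dtype=bool)

    if exclude_markers:
        drop = np.isin(g.markers, list(exclude_markers))
        removed["exclusion_list"] = int(drop.sum())
        keep &= ~drop
    if duplicate_positions:
        drop = np.isin(g.markers, list(duplicate_positions)) & keep
        removed["duplicate_position"] = int(drop.sum())
        keep &= ~drop

    call = g.marker_call_rate()
    drop = (call < t.marker_call_rate_min) & keep
    removed["call_rate"] = int(drop.sum())
    keep &= ~drop

    maf = g.minor_allele_freq()
    drop = (np.nan_to_num(maf, nan=0.0) < t.maf_min) & keep
    removed["maf"] = int(drop.sum())
    keep &= ~drop

    if not keep.any():
        raise ValueError("all markers removed by quality control")
    filtered = g.subset(markers=list(g.markers[keep]))

    s_call = filtered.sample_call_rate()
    s_keep = s_call >= t.sample_call_rate_min
    n_sample_removed = int((~s_keep).sum())
    if n_sample_removed:
        filtered = filtered.subset(samples=list(filtered.samples[s_keep]))

    report = QCReport(
        markers_in=g.n_markers,
        markers_removed_by_rule=removed,
        samples_removed=n_sample_removed,
        markers_out=filtered.n_markers,
        samples_out=filtered.n_samples,
    )
    return filtered, report


# ----------------------------------------------------------------------
def mendelian_error_rate(offspring: np.ndarray, parent: np.ndarray) -> float:
    """Opposing-homozygote rate between a putative parent-offspring pair.

    rate = (# markers where one is dosage 0 and the other dosage 2)
           / (# markers where both calls are non-missing)
    """
    o = np.asarray(offspring, dtype=float)
    p = np.asarray(parent, dtype=float)
    if o.shape != p.shape:
        raise ValueError("vectors must cover the same markers")
    both = np.isfinite(o) & np.isfinite(p)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no jointly non-missing markers")
    opposing = ((o == 0) & (p == 2)) | ((o == 2) & (p == 0))
    return float((opposing & both).sum()) / n


def opposing_homozygote_matrix(
    g: GenotypeMatrix, offspring: Sequence[str], candidates: Sequence[str]
) -> pd.DataFrame:
    """Pairwise Mendelian-error rates, offspring x candidate parents."""
    oi = g.sample_indices(offspring)
    ci = g.sample_indices(candidates)
    O = g.dosages[oi]
    C = g.dosages[ci]
    o0, o2, ook = (O == 0), (O == 2), np.isfinite(O)
    c0, c2, cok = (C == 0), (C == 2), np.isfinite(C)
    opp = o0.astype(float) @ c2.T.astype(float) + o2.astype(float) @ c0.T.astype(float)
    joint = ook.astype(float) @ cok.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(joint > 0, opp / joint, np.nan)
    return pd.DataFrame(rate, index=list(offspring), columns=list(candidates))


def verify_and_correct_pedigree(
    declared: Pedigree,
    g: GenotypeMatrix,
    candidates: Sequence[str],
    thresholds: Optional[QCThresholds] = None,
) -> Tuple[Pedigree, pd.DataFrame]:
    """Flag, replace or recover parents using opposing-homozygote rates.

    Declared parent-offspring pairs whose Mendelian-error rate exceeds the
    threshold are flagged; the genotyped candidate parent with the lowest
    rate (ties broken by lowest identifier) replaces the slot if it passes
    the threshold, otherwise the slot is set unknown.  Unknown slots (e.g.
    the pollen parent of open-pollinated progeny) are recovered the same
    way.  Pairs with an ungenotyped declared parent are skipped with a
    warning row, never silently accepted.

    The threshold is applied per pair (fraction of jointly typed markers),
    not per marker.
    """
    t = thresholds or QCThresholds()
    genotyped = set(g.samples)
    cand = sorted(c for c in candidates if c in genotyped)
    offspring = [
        i
        for i in declared.ids
        if i in genotyped and i not in set(cand)
        and declared.parents_of(i) != (None, None)
    ]
    rates = (
        opposing_homozygote_matrix(g, offspring, cand)
        if offspring and cand
        else pd.DataFrame()
    )

    corrected = declared
    records: List[Tuple] = []
    for child in offspring:
        sire, dam = declared.parents_of(child)
        new_parents = {"sire": sire, "dam": dam}
        for slot, parent in (("sire", sire), ("dam", dam)):
            other = new_parents["dam" if slot == "sire" else "sire"]
            if parent is not None and parent not in genotyped:
                records.append((child, slot, parent, np.nan, "skipped_ungenotyped", parent))
                continue
            if parent is not None:
                rate = mendelian_error_rate(
                    g.dosages[g.sample_indices([child])[0]],
                    g.dosages[g.sample_indices([parent])[0]],
                )
                if rate <= t.mendel_error_max:
                    records.append((child, slot, parent, rate, "confirmed", parent))
                    continue
                action = "replaced"
            else:
                rate = np.nan
                action = "recovered"
            # exhaustive scan over genotyped candidates, excluding the child
            # and whoever already fills the other slot
            row = rates.loc[child].drop(labels=[c for c in (child, other) if c in rates.columns], errors="ignore")
            if row.empty:
                best, best_rate = None, np.inf
            else:
                best_rate = float(row.min())
                best = sorted(row.index[row == best_rate])[0]
            if best is not None and best_rate <= t.mendel_error_max:
                new_parents[slot] = best
                records.append((child, slot, parent, rate, action, best))
            elif parent is not None:
                new_parents[slot] = None
                records.append((child, slot, parent, rate, "removed", None))
            # unknown slot with no acceptable candidate stays unknown, no row
        if (new_parents["sire"], new_parents["dam"]) != (sire, dam):
            corrected = corrected.with_parents(child, new_parents["sire"], new_parents["dam"])

    conflicts = pd.DataFrame(
        records,
        columns=["offspring", "slot", "declared_parent", "me_rate", "action", "new_parent"],
    )
    return corrected, conflicts
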