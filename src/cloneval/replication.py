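"""Influence of the number of ramets per ortet on heritability, accuracy
and clone ranking.

For every subset size k of the available replicates, all C(total, k)
replicate combinations are enumerated, a single-stage genomic model is
refit on each combination (site, sub-trial-within-site and replication-
within-sub-trial fixed; incomplete block random; additive and dominance
kernel terms; residual variance heterogeneous by site), parameters are
averaged, per-combination rankings are aggregated by rank sum, and the
coincidence against the full-replication reference ranking is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .mixedmodel import (
    FitResult,
    ModelSpec,
    REMLOptions,
    Residual,
    fit_reml,
    pev_to_accuracy,
    term_from_labels,
)
from .relmat import RelationshipMatrix

__all__ = [
    "enumerate_subsets",
    "SingleStageFit",
    "fit_single_stage",
    "ranking_from_values",
    "rank_sum_aggregate",
    "ranking_coincidence",
    "min_selection_size",
    "replication_study",
    "ReplicationStudyResult",
    "EXAMPLE_RANKING_TABLE",
]


def enumerate_subsets(total: int, k: int) -> List[Tuple[int, ...]]:
    """All C(total, k) replicate-index subsets in lexicographic order."""
    if not 1 <= k <= total:
        raise ValueError(f"subset size must satisfy 1 <= k <= {total}, got {k}")
    return list(combinations(range(1, total + 1), k))


# ----------------------------------------------------------------------
@dataclass
class SingleStageFit:
    """Summary of one single-stage genomic fit on a replicate combination."""

    components: Dict[str, float]
    sigma_p2: float
    h2_a: float
    delta2: float
    H2: float
    accuracy_additive: Optional[float]
    accuracy_dominance: Optional[float]
    genotypic_values: pd.Series
    ranking: pd.Series  # genotype -> integer position, 1 = best
    fit: FitResult


def single_stage_sigma_p2(components: Dict[str, float], site_names: Sequence[str]) -> float:
    """Phenotypic variance: sa + sd + sb + mean of the site residuals.

    With identical residual variances at every site this reduces to the
    homogeneous-residual formula sa + sd + sb + se.
    """
    res = [components[f"residual_{s}"] for s in site_names]
    return (
        components["additive"]
        + components["dominance"]
        + components["block"]
        + float(np.mean(res))
    )


def ranking_from_values(values: pd.Series) -> pd.Series:
    """Positions 1..n by descending value; ties broken by identifier."""
    order = sorted(values.index, key=lambda g: (-float(values[g]), str(g)))
    return pd.Series(np.arange(1, len(order) + 1), index=order)


def fit_single_stage(
    pheno: pd.DataFrame,
    Gstar: RelationshipMatrix,
    Gd: RelationshipMatrix,
    response: str = "vol_dm3",
    options: Optional[REMLOptions] = None,
    exclude: Sequence[str] = (),
) -> SingleStageFit:
    """Single-stage two-site genomic model on tree-level records.

    Residuals get one variance per site (a direct-sum, block-diagonal
    heterogeneous structure).  Non-genotyped trees are dropped; clones in
    ``exclude`` (e.g. commercial controls) are kept in the model but left
    out of the ranking.
    """
    sites = sorted(pheno["site"].unique())
    if len(sites) < 2:
        raise ValueError("the single-stage model expects at least two sites")
    known = set(Gstar.ids)
    data = pheno[pheno["genotype_id"].isin(known)]
    if data.empty:
        raise ValueError("no genotyped trees in the data")
    y = data[response].to_numpy(dtype=float)
    ok = np.isfinite(y)
    data, y = data[ok], y[ok]
    for s in sites:
        if s not in set(data["site"]):
            raise ValueError(f"site {s!r} absent from the subset data")

    # fixed effects: replication within sub-trial within site, encoded as
    # the finest nested cells (spans site + sub-trial + replication)
    cells = [
        f"{s}|{t}|{r}"
        for s, t, r in zip(data["site"], data["sub_trial"], data["replicate"])
    ]
    codes, uniques = pd.factorize(np.asarray(cells, dtype=object), sort=True)
    X = np.zeros((len(codes), len(uniques)))
    X[np.arange(len(codes)), codes] = 1.0

    block_labels = [
        f"{c}|{b}" for c, b in zip(cells, data["incomplete_block"])
    ]
    terms = [
        term_from_labels("block", block_labels),
        term_from_labels("additive", data["genotype_id"], K=Gstar.values, kernel_ids=Gstar.ids),
        term_from_labels("dominance", data["genotype_id"], K=Gd.values, kernel_ids=Gd.ids),
    ]
    spec = ModelSpec(
        y=y,
        X=X,
        random_terms=terms,
        residual=Residual(kind="heterogeneous_by_group", groups=data["site"].to_numpy()),
        fixed_names=list(uniques),
    )
    fit = fit_reml(spec, options)
    comps = fit.variance_components
    sp2 = single_stage_sigma_p2(comps, sites)
    sa, sd = comps["additive"], comps["dominance"]

    acc_a = pev_to_accuracy(fit.pev["additive"], sa) if sa > 0 and "additive" in fit.pev else None
    acc_d = pev_to_accuracy(fit.pev["dominance"], sd) if sd > 0 and "dominance" in fit.pev else None

    ids = fit.random_effect_levels["additive"]
    gv = pd.Series(
        np.asarray(fit.random_effects["additive"]) + np.asarray(fit.random_effects["dominance"]),
        index=ids,
    )
    present = set(data["genotype_id"]) - set(exclude)
    gv = gv[[g in present for g in gv.index]]
    return SingleStageFit(
        components=dict(comps),
        sigma_p2=sp2,
        h2_a=sa / sp2,
        delta2=sd / sp2,
        H2=(sa + sd) / sp2,
        accuracy_additive=acc_a,
        accuracy_dominance=acc_d,
        genotypic_values=gv,
        ranking=ranking_from_values(gv),
        fit=fit,
    )


# ----------------------------------------------------------------------
def rank_sum_aggregate(rankings: List[pd.Series]) -> pd.Series:
    """Aggregate rankings by the rank-sum rule (lowest sum is best).

    All rankings must cover the same clone set.  Ties in the rank sum are
    broken by clone identifier, so the output is a full permutation 1..n.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    base = set(rankings[0].index)
    for r in rankings[1:]:
        if set(r.index) != base:
            raise ValueError("rankings cover different clone sets")
    total = sum(r.astype(float) for r in rankings)
    order = sorted(total.index, key=lambda g: (float(total[g]), str(g)))
    return pd.Series(np.arange(1, len(order) + 1), index=order)


def ranking_coincidence(reference_top: Iterable, candidate_top: Iterable) -> float:
    """R(%) = 100 * |reference ∩ candidate| / |reference|."""
    ref: Set = set(reference_top)
    if not ref:
        raise ValueError("reference selection is empty")
    return 100.0 * len(ref & set(candidate_top)) / len(ref)


def min_selection_size(reference_top: Sequence, candidate_ranking: pd.Series) -> int:
    """Selection size needed for the candidate ranking to contain the
    reference clones: the worst (largest) candidate position among them."""
    missing = [g for g in reference_top if g not in candidate_ranking.index]
    if missing:
        raise ValueError(f"reference clones missing from candidate ranking: {missing}")
    return int(max(candidate_ranking.loc[list(reference_top)]))


# ----------------------------------------------------------------------
@dataclass
class ReplicationStudyResult:
    summary: pd.DataFrame  # one row per k: n_combinations, mean parameters
    rankings: pd.DataFrame  # clones x k: aggregated ranking positions
    coincidence: pd.DataFrame  # k x top-n: R(%) against the reference
    min_selection: pd.Series  # k -> minimum selection size for the top-10
    reference_ranking: pd.Series
    per_combination: Dict[int, List[SingleStageFit]] = field(default_factory=dict)


def replication_study(
    pheno: pd.DataFrame,
    Gstar: RelationshipMatrix,
    Gd: RelationshipMatrix,
    response: str = "vol_dm3",
    ks: Sequence[int] = (5, 4, 3, 2, 1),
    top_ns: Sequence[int] = (10, 20, 30),
    options: Optional[REMLOptions] = None,
    exclude: Sequence[str] = (),
    keep_fits: bool = False,
) -> ReplicationStudyResult:
    """Enumerate replicate subsets, refit, aggregate and compare rankings.

    The reference scenario uses all available replicates.  For each k the
    per-combination rankings are merged by rank sum; R(%) is the share of
    the reference top-n recovered by the aggregated top-n, and the minimum
    selection size is the worst aggregated position of the reference
    top-10 clones.
    """
    total = int(pheno["replicate"].max())
    ks = sorted(set(ks), reverse=True)
    if max(ks) > total:
        raise ValueError(f"requested k={max(ks)} exceeds {total} available replicates")

    light = options or REMLOptions(compute_pev=True)
    reference = fit_single_stage(pheno, Gstar, Gd, response, light, exclude)
    ref_rank = reference.ranking
    ref_top = {n: list(ref_rank.index[ref_rank.argsort()][:n]) for n in top_ns}
    ref_top10 = [g for g, _ in sorted(ref_rank.items(), key=lambda kv: kv[1])[:10]]

    summary_rows = []
    agg_ranks: Dict[int, pd.Series] = {}
    coinc_rows = []
    min_sel = {}
    per_comb: Dict[int, List[SingleStageFit]] = {}
    for k in ks:
        subsets = enumerate_subsets(total, k)
        fits: List[SingleStageFit] = []
        for subset in subsets:
            sub = pheno[pheno["replicate"].isin(subset)]
            fits.append(fit_single_stage(sub, Gstar, Gd, response, light, exclude))
        common = set.intersection(*(set(f.ranking.index) for f in fits))
        rankings = [
            ranking_from_values(f.genotypic_values.loc[sorted(common)]) for f in fits
        ]
        agg = rank_sum_aggregate(rankings)
        agg_ranks[k] = agg
        summary_rows.append(
            {
                "k": k,
                "n_combinations": len(subsets),
                "mean_H2": float(np.mean([f.H2 for f in fits])),
                "mean_h2_a": float(np.mean([f.h2_a for f in fits])),
                "mean_delta2": float(np.mean([f.delta2 for f in fits])),
                "mean_accuracy_additive": float(
                    np.mean([f.accuracy_additive for f in fits if f.accuracy_additive is not None])
                ),
                "mean_accuracy_dominance": float(
                    np.mean([f.accuracy_dominance for f in fits if f.accuracy_dominance is not None])
                ),
            }
        )
        row = {"k": k}
        for n in top_ns:
            cand_top = list(agg.index[agg.argsort()][:n])
            ref_n = [g for g in ref_top[n] if g in set(agg.index)]
            row[f"R_top{n}"] = ranking_coincidence(ref_n, cand_top)
        coinc_rows.append(row)
        min_sel[k] = min_selection_size(
            [g for g in ref_top10 if g in set(agg.index)], agg
        )
        if keep_fits:
            per_comb[k] = fits

    rankings_df = pd.DataFrame({k: agg_ranks[k] for k in ks})
    return ReplicationStudyResult(
        summary=pd.DataFrame(summary_rows).set_index("k"),
        rankings=rankings_df,
        coincidence=pd.DataFrame(coinc_rows).set_index("k"),
        min_selection=pd.Series(min_sel).sort_index(ascending=False),
        reference_ranking=ref_rank,
        per_combination=per_comb,
    )


# ----------------------------------------------------------------------
# A worked 10-clone example: aggregated ranking positions of the ten
# best-ranked clones under five ramets/progeny, re-ranked as the number of
# ramets per progeny drops from five to one.  Rows are labelled by the
# clones' genotypic values; columns by the number of ramets used.
EXAMPLE_RANKING_TABLE = pd.DataFrame(
    {
        5: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        4: [1, 2, 3, 4, 7, 8, 5, 6, 9, 10],
        3: [1, 2, 7, 6, 9, 10, 3, 4, 5, 8],
        2: [1, 3, 24, 22, 18, 21, 3, 4, 7, 6],
        1: [1, 3, 120, 9, 49, 72, 2, 9, 12, 8],
    },
    index=["40.25", "42.14", "35.21", "32.34", "65.13", "15.07", "10.24", "21.54", "34.19", "40.03"],
)
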