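"""Stage-wise genomic evaluation of a cloned progeny trial.

Stage 1 fits, within every sub-trial x site combination, a model with
genotype as a fixed effect, random replication and incomplete-block
effects, and an AR1 x AR1 spatially correlated residual; its genotype
BLUEs are the adjusted means.  Stage 2 models the stacked adjusted means
across environments with random trial-within-environment, additive (G*),
dominance (Gd), additive-by-environment and dominance-by-environment
effects plus an iid residual.  Genetic parameters, PEV-based accuracies
and the response to selection are derived from the stage-2 fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mixedmodel import (
    FitResult,
    ModelSpec,
    RandomTerm,
    REMLOptions,
    Residual,
    fit_reml,
    pev_to_accuracy,
    pev_to_reliability,
    solve_mixed,
    term_from_labels,
)
from .relmat import RelationshipMatrix

__all__ = [
    "Stage1Result",
    "VarianceComponents",
    "GeneticParameters",
    "SelectionResponse",
    "fit_stage1",
    "stage1_adjusted_means",
    "fit_stage2",
    "summarize_parameters",
    "genotypic_values_from_fit",
    "select_and_respond",
    "stagewise_evaluation",
]


# ----------------------------------------------------------------------
@dataclass
class Stage1Result:
    site: str
    sub_trial: str
    adjusted_means: pd.Series  # genotype -> BLUE on the trial mean scale
    rho_col: float
    rho_row: float
    variance_components: Dict[str, float]
    fit: FitResult


def _one_hot(labels: Sequence) -> Tuple[np.ndarray, List]:
    codes, uniques = pd.factorize(np.asarray(labels, dtype=object), sort=True)
    X = np.zeros((len(codes), len(uniques)))
    X[np.arange(len(codes)), codes] = 1.0
    return X, list(uniques)


def _stage1_spec(df: pd.DataFrame, response: str, estimate_spatial: bool) -> Tuple[ModelSpec, List]:
    X, gids = _one_hot(df["genotype_id"])
    rep_term = term_from_labels("replication", df["replicate"])
    block_labels = [
        f"{r}:{b}" for r, b in zip(df["replicate"], df["incomplete_block"])
    ]
    block_term = term_from_labels("block", block_labels)
    residual = Residual(
        kind="ar1_by_ar1",
        rows=df["row"].to_numpy(),
        cols=df["col"].to_numpy(),
        estimate_rho=estimate_spatial,
    )
    spec = ModelSpec(
        y=df[response].to_numpy(),
        X=X,
        random_terms=[rep_term, block_term],
        residual=residual,
        fixed_names=[str(g) for g in gids],
    )
    return spec, gids


def fit_stage1(
    df: pd.DataFrame,
    response: str = "vol_dm3",
    estimate_spatial: bool = True,
    options: Optional[REMLOptions] = None,
    fixed_components: Optional[Dict[str, float]] = None,
) -> Stage1Result:
    """First-stage spatial analysis of one sub-trial.

    ``df`` must hold a single (site, sub_trial) combination with columns
    genotype_id, replicate, incomplete_block, row, col and the response.
    Rows with a missing response are dropped.  ``fixed_components`` skips
    REML and solves at the given variances (useful for oracles).
    """
    sites = df["site"].unique()
    sts = df["sub_trial"].unique()
    if len(sites) != 1 or len(sts) != 1:
        raise ValueError("fit_stage1 expects data from exactly one sub-trial")
    df = df[np.isfinite(df[response].to_numpy(dtype=float))]
    spec, gids = _stage1_spec(df, response, estimate_spatial)
    if fixed_components is not None:
        fit = solve_mixed(spec, fixed_components)
    else:
        fit = fit_reml(spec, options)
    rho_col, rho_row = fit.rho if fit.rho is not None else (0.0, 0.0)
    return Stage1Result(
        site=str(sites[0]),
        sub_trial=str(sts[0]),
        adjusted_means=pd.Series(fit.fixed_effects, index=gids),
        rho_col=rho_col,
        rho_row=rho_row,
        variance_components=dict(fit.variance_components),
        fit=fit,
    )


def stage1_adjusted_means(
    pheno: pd.DataFrame,
    response: str = "vol_dm3",
    estimate_spatial: bool = True,
    options: Optional[REMLOptions] = None,
) -> Tuple[pd.DataFrame, List[Stage1Result]]:
    """Run stage 1 for every (site, sub_trial) and stack the adjusted means."""
    results: List[Stage1Result] = []
    rows = []
    for (site, st), group in pheno.groupby(["site", "sub_trial"], sort=True):
        res = fit_stage1(group, response, estimate_spatial, options)
        results.append(res)
        for gid, mean in res.adjusted_means.items():
            rows.append((gid, site, st, mean))
    means = pd.DataFrame(rows, columns=["genotype_id", "site", "sub_trial", "adj_mean"])
    return means, results


# ----------------------------------------------------------------------
@dataclass
class VarianceComponents:
    """The six stage-2 components; the phenotypic total is their sum."""

    additive: float
    dominance: float
    trial: float
    axe: float
    dxe: float
    residual: float
    standard_errors: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("additive", "dominance", "trial", "axe", "dxe", "residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"component {name!r} must be >= 0")

    @property
    def total(self) -> float:
        return (
            self.additive + self.dominance + self.trial + self.axe + self.dxe + self.residual
        )

    def as_dict(self) -> Dict[str, float]:
        return {
            "additive": self.additive,
            "dominance": self.dominance,
            "trial": self.trial,
            "axe": self.axe,
            "dxe": self.dxe,
            "residual": self.residual,
            "total": self.total,
        }

    @classmethod
    def from_fit(cls, fit: FitResult) -> "VarianceComponents":
        vc = fit.variance_components
        return cls(
            additive=vc["additive"],
            dominance=vc["dominance"],
            trial=vc["trial"],
            axe=vc["additive_x_env"],
            dxe=vc["dominance_x_env"],
            residual=vc["residual"],
            standard_errors=dict(fit.standard_errors),
        )


def fit_stage2(
    means: pd.DataFrame,
    Gstar: RelationshipMatrix,
    Gd: RelationshipMatrix,
    options: Optional[REMLOptions] = None,
    response: str = "adj_mean",
) -> Tuple[VarianceComponents, FitResult]:
    """Across-environment genomic model on the stage-1 adjusted means.

    Entries whose genotype is absent from the genomic kernels (non-
    genotyped clones) are dropped with a logged count.  The additive and
    dominance kernels must be over the same individuals in the same order.
    """
    if list(Gstar.ids) != list(Gd.ids):
        raise ValueError("additive and dominance kernels must share the individual order")
    known = set(Gstar.ids)
    keep = means["genotype_id"].isin(known)
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"dropping {n_drop} adjusted means for non-genotyped clones")
    data = means[keep]
    if data.empty:
        raise ValueError("no adjusted means left after matching against the kernels")

    X, site_ids = _one_hot(data["site"])
    terms = [
        term_from_labels("trial", data["sub_trial"]),
        term_from_labels("additive", data["genotype_id"], K=Gstar.values, kernel_ids=Gstar.ids),
        term_from_labels("dominance", data["genotype_id"], K=Gd.values, kernel_ids=Gd.ids),
        term_from_labels(
            "additive_x_env",
            data["genotype_id"],
            K=Gstar.values,
            kernel_ids=Gstar.ids,
            env_labels=data["site"],
        ),
        term_from_labels(
            "dominance_x_env",
            data["genotype_id"],
            K=Gd.values,
            kernel_ids=Gd.ids,
            env_labels=data["site"],
        ),
    ]
    spec = ModelSpec(
        y=data[response].to_numpy(dtype=float),
        X=X,
        random_terms=terms,
        residual=Residual(kind="iid"),
        fixed_names=[str(s) for s in site_ids],
    )
    fit = fit_reml(spec, options)
    return VarianceComponents.from_fit(fit), fit


# ----------------------------------------------------------------------
@dataclass
class GeneticParameters:
    """Heritabilities and PEV-based accuracies from a variance decomposition."""

    sigma_p2: float
    h2_a: float
    delta2: float
    H2: float
    shares: Dict[str, float]
    accuracy_additive: Optional[float] = None
    accuracy_dominance: Optional[float] = None
    reliability_additive: Optional[np.ndarray] = None
    reliability_dominance: Optional[np.ndarray] = None

    def as_dict(self) -> Dict[str, float]:
        out = {
            "sigma_p2": self.sigma_p2,
            "h2_a": self.h2_a,
            "delta2": self.delta2,
            "H2": self.H2,
        }
        out.update({f"share_{k}": v for k, v in self.shares.items()})
        if self.accuracy_additive is not None:
            out["accuracy_additive"] = self.accuracy_additive
        if self.accuracy_dominance is not None:
            out["accuracy_dominance"] = self.accuracy_dominance
        return out


def summarize_parameters(
    vc: VarianceComponents, fit: Optional[FitResult] = None
) -> GeneticParameters:
    """Heritability ratios h2 = sA/sP, d2 = sD/sP, H2 = (sA + sD)/sP.

    When a fit with PEVs is supplied, the additive/dominance accuracies use
    the mean PEV diagonal (r = sqrt(1 - mean PEV / sigma^2)) and per-clone
    reliabilities use per-element PEVs.
    """
    sp2 = vc.total
    if sp2 <= 0:
        raise ValueError("phenotypic variance is zero; parameters undefined")
    params = GeneticParameters(
        sigma_p2=sp2,
        h2_a=vc.additive / sp2,
        delta2=vc.dominance / sp2,
        H2=(vc.additive + vc.dominance) / sp2,
        shares={k: v / sp2 for k, v in vc.as_dict().items() if k != "total"},
    )
    if fit is not None and "additive" in fit.pev:
        if vc.additive > 0:
            params.accuracy_additive = pev_to_accuracy(fit.pev["additive"], vc.additive)
            params.reliability_additive = pev_to_reliability(
                fit.pev["additive"], vc.additive
            )
        if vc.dominance > 0 and "dominance" in fit.pev:
            params.accuracy_dominance = pev_to_accuracy(fit.pev["dominance"], vc.dominance)
            params.reliability_dominance = pev_to_reliability(
                fit.pev["dominance"], vc.dominance
            )
    return params


def genotypic_values_from_fit(fit: FitResult) -> pd.Series:
    """Predicted genotypic values g = a + d from the main genetic BLUPs."""
    a = fit.random_effects["additive"]
    d = fit.random_effects["dominance"]
    ids = fit.random_effect_levels["additive"]
    return pd.Series(np.asarray(a) + np.asarray(d), index=ids)


# ----------------------------------------------------------------------
@dataclass
class SelectionResponse:
    selected: List[str]
    base_mean: float
    selected_mean: float
    sigma_p: float
    intensity: float
    differential: float
    response: float
    response_pct: float


def select_and_respond(
    genotypic_values: pd.Series,
    phenotype_means: pd.Series,
    H2: float,
    n_select: int,
) -> SelectionResponse:
    """Truncation selection on predicted genotypic value (a + d).

    The differential S = mean(selected phenotypes) - mean(all phenotypes),
    the intensity i = S / sigma_p, and the response DR = S * H2, reported
    also as a percentage of the base mean.  Ties in the genotypic value are
    broken by genotype identifier.
    """
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > len(genotypic_values):
        raise ValueError("cannot select more genotypes than available")
    order = sorted(
        genotypic_values.index, key=lambda g: (-float(genotypic_values[g]), str(g))
    )
    selected = order[:n_select]
    pheno = phenotype_means.dropna()
    x0 = float(pheno.mean())
    xs = float(pheno.loc[[g for g in selected if g in pheno.index]].mean())
    sigma_p = float(pheno.std(ddof=1))
    S = xs - x0
    i = S / sigma_p if sigma_p > 0 else float("nan")
    dr = S * H2
    pct = 100.0 * dr / x0 if x0 != 0 else float("nan")
    return SelectionResponse(
        selected=list(selected),
        base_mean=x0,
        selected_mean=xs,
        sigma_p=sigma_p,
        intensity=i,
        differential=S,
        response=dr,
        response_pct=pct,
    )


# ----------------------------------------------------------------------
def stagewise_evaluation(
    pheno: pd.DataFrame,
    Gstar: RelationshipMatrix,
    Gd: RelationshipMatrix,
    response: str = "vol_dm3",
    estimate_spatial: bool = True,
    n_select: int = 30,
    stage1_options: Optional[REMLOptions] = None,
    stage2_options: Optional[REMLOptions] = None,
) -> Dict:
    """Full stage-wise run: stage 1, stage 2, parameters and selection."""
    means, stage1 = stage1_adjusted_means(pheno, response, estimate_spatial, stage1_options)
    vc, fit = fit_stage2(means, Gstar, Gd, stage2_options)
    params = summarize_parameters(vc, fit)
    gv = genotypic_values_from_fit(fit)
    present = set(pheno["genotype_id"])
    gv = gv[[g in present for g in gv.index]]
    pheno_means = pheno.groupby("genotype_id")[response].mean()
    n_sel = min(n_select, len(gv))
    selection = select_and_respond(gv, pheno_means, params.H2, n_sel)
    return {
        "adjusted_means": means,
        "stage1": stage1,
        "variance_components": vc,
        "fit": fit,
        "parameters": params,
        "genotypic_values": gv,
        "selection": selection,
    }
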