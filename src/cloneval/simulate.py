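"""Synthetic cloned-progeny-trial (CPT) generator.

Builds a breeding population (founders, open-pollinated half-sib and
controlled-cross full-sib families), clones each progeny into ramets,
lays the ramets out in alpha-lattice sub-trials across sites, and draws
phenotypes from an additive + dominance + trial + GxE + spatially
autocorrelated residual model.  Every draw flows from a single seeded
generator so each dataset is reproducible from (config, seed).

The default configuration mirrors the study conditions this package
emulates: 48 founder genitors, 47 half-sib plus 11 full-sib families of
60 progeny, 5 ramets per ortet, 16x16 alpha-lattice sub-trials of 256
treatments (250 progeny + 6 shared control clones) at two sites with 11
and 12 sub-trials.  ``small_config`` scales the same structure down to
desk size for experimentation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "SiteSpec",
    "TrueVariances",
    "GenotypingArtifacts",
    "SimulationConfig",
    "TruthRecord",
    "FamilyResult",
    "GenotypingResult",
    "CPTDataset",
    "study_config",
    "small_config",
    "simulate_founders",
    "simulate_controls",
    "make_families",
    "assign_layout",
    "simulate_phenotypes",
    "inject_genotyping_artifacts",
    "simulate_cpt",
]

ROW_SPACING_M = 2.5
COL_SPACING_M = 3.6


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
@dataclass
class SiteSpec:
    name: str
    n_subtrials: int


@dataclass
class TrueVariances:
    """Trait-variance-unit components of the generative model.

    Defaults are the magnitudes estimated for stem volume (dm^3) in the
    stage-wise evaluation this generator emulates.
    """

    additive: float = 250.76
    dominance: float = 365.14
    trial: float = 796.16
    axe: float = 37.47
    dxe: float = 6.28
    residual_per_site: Union[float, Dict[str, float]] = 200.39
    nugget: float = 0.0

    def residual_for(self, site: str) -> float:
        if isinstance(self.residual_per_site, dict):
            return float(self.residual_per_site[site])
        return float(self.residual_per_site)

    def validate(self, site_names: Sequence[str]) -> None:
        for name in ("additive", "dominance", "trial", "axe", "dxe", "nugget"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name!r} must be >= 0")
        for s in site_names:
            if self.residual_for(s) < 0:
                raise ValueError("residual variances must be >= 0")


@dataclass
class GenotypingArtifacts:
    """Rates of instrument-like imperfections injected into clean genotypes."""

    missing_rate: float = 0.02
    error_rate: float = 0.001
    panel_overlap_fraction: float = 0.5
    platform_b_fraction: float = 0.2
    panel_flip_fraction: float = 0.5
    genotyped_fraction: float = 0.8

    def validate(self) -> None:
        for name in (
            "missing_rate",
            "error_rate",
            "panel_overlap_fraction",
            "platform_b_fraction",
            "panel_flip_fraction",
            "genotyped_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    n_founders: int = 48
    n_snps: int = 2000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_hs_families: int = 47
    n_fs_families: int = 11
    progeny_per_family: int = 60
    ramets_per_ortet: int = 5
    sites: List[SiteSpec] = field(
        default_factory=lambda: [SiteSpec("MAT", 11), SiteSpec("PAL", 12)]
    )
    treatments_per_subtrial: int = 256
    n_controls: int = 6
    block_size: int = 16
    n_survivors: Optional[int] = 3142
    true_variances: TrueVariances = field(default_factory=TrueVariances)
    spatial_rho_col: float = -0.01
    spatial_rho_row: float = -0.085
    trait_mean: float = 52.36
    height_mean_m: float = 20.0
    height_sd_m: float = 2.5
    genotyping: GenotypingArtifacts = field(default_factory=GenotypingArtifacts)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if self.n_snps < 1:
            raise ValueError("need at least one marker")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.treatments_per_subtrial != self.block_size**2:
            raise ValueError(
                "alpha-lattice requires treatments_per_subtrial == block_size^2 "
                f"({self.treatments_per_subtrial} != {self.block_size}^2)"
            )
        if not 1 <= self.ramets_per_ortet <= 5:
            raise ValueError("ramets_per_ortet must be between 1 and 5")
        if not 0 <= self.n_controls < self.treatments_per_subtrial:
            raise ValueError("n_controls must be smaller than treatments_per_subtrial")
        if abs(self.spatial_rho_col) >= 1 or abs(self.spatial_rho_row) >= 1:
            raise ValueError("spatial autocorrelations must lie in (-1, 1)")
        self.true_variances.validate([s.name for s in self.sites])
        self.genotyping.validate()

    @property
    def n_families(self) -> int:
        return self.n_hs_families + self.n_fs_families

    @property
    def n_progeny(self) -> int:
        return self.n_families * self.progeny_per_family

    def trees_per_site(self) -> Dict[str, int]:
        per_subtrial = self.treatments_per_subtrial * self.ramets_per_ortet
        return {s.name: s.n_subtrials * per_subtrial for s in self.sites}


def study_config(**overrides) -> SimulationConfig:
    """The full study-scale configuration (two sites, 23 sub-trials)."""
    cfg = SimulationConfig()
    return replace(cfg, **overrides) if overrides else cfg


def small_config(**overrides) -> SimulationConfig:
    """Reduced configuration: 20 families x 10 progeny, 3 ramets, 2 sites."""
    cfg = SimulationConfig(
        n_founders=24,
        n_snps=1000,
        n_hs_families=16,
        n_fs_families=4,
        progeny_per_family=10,
        ramets_per_ortet=3,
        sites=[SiteSpec("S1", 3), SiteSpec("S2", 3)],
        treatments_per_subtrial=64,
        n_controls=6,
        block_size=8,
        n_survivors=None,
        genotyping=GenotypingArtifacts(genotyped_fraction=1.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


# ----------------------------------------------------------------------
# founders, families, controls
# ----------------------------------------------------------------------
def _hw_genotypes(freqs: np.ndarray, n: int, prefix: str, rng: np.random.Generator) -> GenotypeMatrix:
    dosages = rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(float)
    samples = [f"{prefix}{i + 1:03d}" for i in range(n)]
    markers = [f"SNP{j + 1:05d}" for j in range(len(freqs))]
    alleles = np.array([("B", "A")] * len(freqs), dtype=object)
    return GenotypeMatrix(dosages, samples, markers, alleles)


def sample_marker_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def simulate_founders(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenotypeMatrix:
    """Founder genotypes drawn marker-wise from Hardy-Weinberg proportions."""
    rng = rng or np.random.default_rng(config.seed)
    freqs = sample_marker_freqs(config, rng)
    return _hw_genotypes(freqs, config.n_founders, "GEN", rng)


def simulate_controls(
    config: SimulationConfig,
    founders: GenotypeMatrix,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Unrelated control clones at the founder allele frequencies."""
    freqs = founders.allele_freq()
    g = _hw_genotypes(freqs, config.n_controls, "CTRL", rng)
    return GenotypeMatrix(g.dosages, g.samples, founders.markers, founders.alleles)


def _gamete(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One haploid allele count per marker via Mendelian gene dropping."""
    return rng.binomial(1, dosages / 2.0)


@dataclass
class FamilyResult:
    progeny: GenotypeMatrix
    families: pd.DataFrame  # genotype_id, family_id, family_type
    truth_pedigree: Pedigree
    declared_pedigree: Pedigree


def make_families(
    founders: GenotypeMatrix,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> FamilyResult:
    """Gene-drop progeny for half-sib and full-sib families.

    Full-sib families come from fixed, distinct parent pairs.  Half-sib
    families have a known mother; the pollen father is drawn per seed and
    recorded only in the truth pedigree — the declared pedigree masks him
    as unknown, which is what pedigree verification later has to recover.
    """
    rng = rng or np.random.default_rng(config.seed)
    nf = founders.n_samples
    founder_ids = list(founders.samples)
    if config.n_hs_families > nf:
        raise ValueError("more half-sib families requested than available mothers")
    max_pairs = nf * (nf - 1) // 2
    if config.n_fs_families > max_pairs:
        raise ValueError("more full-sib families requested than distinct parent pairs")

    mothers = rng.choice(nf, size=config.n_hs_families, replace=False)
    pairs: List[Tuple[int, int]] = []
    seen = set()
    while len(pairs) < config.n_fs_families:
        a, b = rng.choice(nf, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key not in seen:
            seen.add(key)
            pairs.append((int(a), int(b)))

    n_prog = config.n_progeny
    dosages = np.empty((n_prog, founders.n_markers))
    ids: List[str] = []
    fam_rows = []
    truth_sire: List[Optional[str]] = []
    truth_dam: List[Optional[str]] = []
    decl_sire: List[Optional[str]] = []
    decl_dam: List[Optional[str]] = []

    k = 0
    fam_no = 0
    for m in mothers:
        fam_no += 1
        fam_id = f"F{fam_no:02d}"
        for p in range(config.progeny_per_family):
            pid = f"{fam_id}_P{p + 1:02d}"
            father = int(rng.choice([i for i in range(nf) if i != m]))
            dosages[k] = _gamete(founders.dosages[m], rng) + _gamete(
                founders.dosages[father], rng
            )
            ids.append(pid)
            fam_rows.append((pid, fam_id, "half-sib"))
            truth_dam.append(founder_ids[m])
            truth_sire.append(founder_ids[father])
            decl_dam.append(founder_ids[m])
            decl_sire.append(None)
            k += 1
    for a, b in pairs:
        fam_no += 1
        fam_id = f"F{fam_no:02d}"
        for p in range(config.progeny_per_family):
            pid = f"{fam_id}_P{p + 1:02d}"
            dosages[k] = _gamete(founders.dosages[a], rng) + _gamete(
                founders.dosages[b], rng
            )
            ids.append(pid)
            fam_rows.append((pid, fam_id, "full-sib"))
            truth_sire.append(founder_ids[a])
            truth_dam.append(founder_ids[b])
            decl_sire.append(founder_ids[a])
            decl_dam.append(founder_ids[b])
            k += 1

    progeny = GenotypeMatrix(dosages, ids, founders.markers, founders.alleles)
    none_f = [None] * nf
    truth = Pedigree(founder_ids + ids, none_f + truth_sire, none_f + truth_dam)
    declared = Pedigree(founder_ids + ids, none_f + decl_sire, none_f + decl_dam)
    families = pd.DataFrame(fam_rows, columns=["genotype_id", "family_id", "family_type"])
    return FamilyResult(progeny, families, truth, declared)


# ----------------------------------------------------------------------
# field layout
# ----------------------------------------------------------------------
def assign_layout(
    progeny_ids: Sequence[str],
    control_ids: Sequence[str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Alpha-lattice layout over sites, sub-trials, replicates and blocks.

    Per site, a disjoint set of progeny fills each sub-trial alongside the
    shared controls.  Every replicate is one block_size x block_size grid;
    within a replicate treatments are assigned to cells at random and each
    grid column forms one incomplete block.  Replicates are tiled side by
    side, so a sub-trial occupies block_size rows and
    block_size * ramets columns.
    """
    rng = rng or np.random.default_rng(config.seed)
    B = config.block_size
    per_st = config.treatments_per_subtrial - config.n_controls
    progeny_ids = list(progeny_ids)
    control_ids = list(control_ids)
    if len(control_ids) != config.n_controls:
        raise ValueError("control id count does not match configuration")

    records = []
    for site in config.sites:
        need = site.n_subtrials * per_st
        if len(progeny_ids) < need:
            raise ValueError(
                f"site {site.name}: {need} progeny required but only "
                f"{len(progeny_ids)} available"
            )
        chosen = rng.choice(len(progeny_ids), size=need, replace=False)
        site_progeny = [progeny_ids[i] for i in chosen]
        for t in range(site.n_subtrials):
            st_id = f"{site.name}_T{t + 1:02d}"
            treatments = site_progeny[t * per_st : (t + 1) * per_st] + control_ids
            for rep in range(1, config.ramets_per_ortet + 1):
                order = rng.permutation(len(treatments))
                col_offset = (rep - 1) * B
                for cell, ti in enumerate(order):
                    r, c = divmod(cell, B)
                    gid = treatments[ti]
                    records.append(
                        (
                            f"{gid}:{st_id}:R{rep}",
                            gid,
                            site.name,
                            st_id,
                            rep,
                            c + 1,  # incomplete block = grid column within replicate
                            r + 1,
                            col_offset + c + 1,
                        )
                    )
    return pd.DataFrame(
        records,
        columns=[
            "tree_id",
            "genotype_id",
            "site",
            "sub_trial",
            "replicate",
            "incomplete_block",
            "row",
            "col",
        ],
    )


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
@dataclass
class TruthRecord:
    """Ground truth behind a simulated phenotype table."""

    breeding_values: pd.Series
    dominance_deviations: pd.Series
    genotypic_values: pd.Series
    additive_by_site: pd.DataFrame
    dominance_by_site: pd.DataFrame
    trial_effects: pd.Series
    spatial_residuals: pd.Series
    phenotypic_values: pd.Series
    realized_variances: Dict[str, float]


def _scaled_scores(
    coding: np.ndarray, target_var: float, rng: np.random.Generator
) -> np.ndarray:
    """Marker-effect scores rescaled so their empirical variance hits target."""
    if target_var == 0.0:
        return np.zeros(coding.shape[0])
    effects = rng.standard_normal(coding.shape[1])
    scores = coding @ effects
    sd = scores.std(ddof=1)
    if sd == 0:
        return np.zeros(coding.shape[0])
    return scores * (np.sqrt(target_var) / sd)


def _dominance_coding(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Dominance-deviation coding per dosage: {-2p^2, 2p(1-p), -2(1-p)^2}."""
    s0 = -2.0 * p**2
    s1 = 2.0 * p * (1.0 - p)
    s2 = -2.0 * (1.0 - p) ** 2
    out = np.where(dosages == 0, s0, np.where(dosages == 1, s1, s2))
    return out


def simulate_phenotypes(
    layout: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, TruthRecord]:
    """Draw tree-level phenotypes on the layout.

    Breeding values are centered-dosage marker scores, dominance deviations
    use the heterozygosity coding, and both are rescaled so the realized
    genotype-level variance equals the configured component.  Site-specific
    genetic scores give the GxE terms the same kernel structure the
    evaluation models assume.  The residual field per sub-trial is an
    AR1 (cols) x AR1 (rows) draw plus an optional independent nugget.
    """
    rng = rng or np.random.default_rng(config.seed)
    tv = config.true_variances
    ortets = pd.unique(layout["genotype_id"])
    g = genotypes.subset(samples=list(ortets))
    p = g.allele_freq()
    poly = (p > 0) & (p < 1)
    Zc = (g.dosages - 2.0 * p)[:, poly]
    Sc = _dominance_coding(g.dosages, p)[:, poly]

    u = _scaled_scores(Zc, tv.additive, rng)
    v = _scaled_scores(Sc, tv.dominance, rng)
    site_names = [s.name for s in config.sites]
    j_site = {s: _scaled_scores(Zc, tv.axe, rng) for s in site_names}
    k_site = {s: _scaled_scores(Sc, tv.dxe, rng) for s in site_names}

    gidx = {gid: i for i, gid in enumerate(ortets)}
    sub_trials = layout[["site", "sub_trial"]].drop_duplicates()
    trial_eff = {
        st: rng.normal(0.0, np.sqrt(tv.trial)) for st in sub_trials["sub_trial"]
    }

    B = config.block_size
    n_cols = B * config.ramets_per_ortet
    from .mixedmodel import ar1_correlation  # local import to avoid a cycle

    Lr = np.linalg.cholesky(
        ar1_correlation(B, config.spatial_rho_row) + 1e-10 * np.eye(B)
    )
    Lc = np.linalg.cholesky(
        ar1_correlation(n_cols, config.spatial_rho_col) + 1e-10 * np.eye(n_cols)
    )

    y = np.empty(len(layout))
    spatial = np.empty(len(layout))
    site_arr = layout["site"].to_numpy()
    st_arr = layout["sub_trial"].to_numpy()
    row_arr = layout["row"].to_numpy() - 1
    col_arr = layout["col"].to_numpy() - 1
    gi = np.array([gidx[gid] for gid in layout["genotype_id"]])

    for st in sub_trials["sub_trial"]:
        mask = st_arr == st
        site = site_arr[mask][0]
        sigma_xi = np.sqrt(tv.residual_for(site))
        field_grid = sigma_xi * (Lr @ rng.standard_normal((B, n_cols)) @ Lc.T)
        spatial[mask] = field_grid[row_arr[mask], col_arr[mask]]

    nugget = (
        rng.normal(0.0, np.sqrt(tv.nugget), size=len(layout))
        if tv.nugget > 0
        else np.zeros(len(layout))
    )
    trial_term = np.array([trial_eff[st] for st in st_arr])
    j_term = np.array([j_site[s][i] for s, i in zip(site_arr, gi)])
    k_term = np.array([k_site[s][i] for s, i in zip(site_arr, gi)])
    y = config.trait_mean + trial_term + u[gi] + v[gi] + j_term + k_term + spatial + nugget

    # realise volumes as field measurements: draw heights, back out CBH so
    # that the volume formula reproduces y (in dm^3) exactly
    vol_dm3 = np.maximum(y, 0.5)
    th = np.clip(rng.normal(config.height_mean_m, config.height_sd_m, len(y)), 2.0, None)
    from .traits import DEFAULT_STEM_TAPER

    cbh = np.sqrt(40000.0 * (vol_dm3 / 1000.0) / (np.pi * th * DEFAULT_STEM_TAPER))

    pheno = layout.copy()
    pheno["cbh_cm"] = cbh
    pheno["th_m"] = th

    truth = TruthRecord(
        breeding_values=pd.Series(u, index=ortets),
        dominance_deviations=pd.Series(v, index=ortets),
        genotypic_values=pd.Series(u + v, index=ortets),
        additive_by_site=pd.DataFrame(j_site, index=ortets),
        dominance_by_site=pd.DataFrame(k_site, index=ortets),
        trial_effects=pd.Series(trial_eff),
        spatial_residuals=pd.Series(spatial, index=layout["tree_id"].to_numpy()),
        phenotypic_values=pd.Series(y, index=layout["tree_id"].to_numpy()),
        realized_variances={
            "additive": float(np.var(u, ddof=1)),
            "dominance": float(np.var(v, ddof=1)),
            "trial": float(np.var(list(trial_eff.values()), ddof=1))
            if len(trial_eff) > 1
            else 0.0,
            "axe": float(np.mean([np.var(j_site[s], ddof=1) for s in site_names])),
            "dxe": float(np.mean([np.var(k_site[s], ddof=1) for s in site_names])),
            "spatial": float(np.var(spatial, ddof=1)),
            "nugget": float(np.var(nugget, ddof=1)) if tv.nugget > 0 else 0.0,
        },
    )
    return pheno, truth


# ----------------------------------------------------------------------
# genotyping artifacts and panels
# ----------------------------------------------------------------------
@dataclass
class GenotypingResult:
    observed: GenotypeMatrix
    panel_a: GenotypeMatrix
    panel_b: GenotypeMatrix
    marker_panel: pd.Series  # marker -> {"shared", "a_only", "b_only"}
    sample_platform: pd.Series  # sample -> {"A", "B"}


def inject_genotyping_artifacts(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GenotypingResult:
    """Degrade clean genotypes into realistic two-platform panel data.

    Calls go missing at ``missing_rate``; surviving calls flip to one of
    the other two dosages at ``error_rate``.  Markers are split into a
    shared fraction and platform-private remainders, samples are assigned
    to one platform each, and a fraction of panel-B markers is re-coded on
    the opposite reference allele to exercise downstream harmonization.
    """
    rng = rng or np.random.default_rng(config.seed)
    art = config.genotyping
    obs = genotypes.dosages.copy()
    n, m = obs.shape

    miss = rng.random(obs.shape) < art.missing_rate
    obs[miss] = np.nan
    if art.error_rate > 0:
        err = (rng.random(obs.shape) < art.error_rate) & np.isfinite(obs)
        if err.any():
            shift = rng.integers(1, 3, size=int(err.sum()))
            obs[err] = np.mod(obs[err] + shift, 3)

    observed = GenotypeMatrix(obs, genotypes.samples, genotypes.markers, genotypes.alleles)

    perm = rng.permutation(m)
    n_shared = int(round(art.panel_overlap_fraction * m))
    shared = perm[:n_shared]
    rest = perm[n_shared:]
    a_only = rest[: len(rest) // 2]
    b_only = rest[len(rest) // 2 :]
    panel_of = np.empty(m, dtype=object)
    panel_of[shared] = "shared"
    panel_of[a_only] = "a_only"
    panel_of[b_only] = "b_only"

    on_b = rng.random(n) < art.platform_b_fraction
    if on_b.all() or (~on_b).all():  # keep both platforms populated
        on_b[0] = True
        on_b[-1] = False
    platform = np.where(on_b, "B", "A")

    a_markers = np.sort(np.concatenate([shared, a_only]))
    b_markers = np.sort(np.concatenate([shared, b_only]))
    panel_a = observed.subset(
        samples=list(observed.samples[~on_b]),
        markers=list(observed.markers[a_markers]),
    )
    panel_b = observed.subset(
        samples=list(observed.samples[on_b]),
        markers=list(observed.markers[b_markers]),
    )
    if art.panel_flip_fraction > 0 and panel_b.alleles is not None:
        flip = rng.random(panel_b.n_markers) < art.panel_flip_fraction
        panel_b.dosages[:, flip] = 2.0 - panel_b.dosages[:, flip]
        panel_b.alleles[flip] = panel_b.alleles[flip][:, ::-1]

    return GenotypingResult(
        observed=observed,
        panel_a=panel_a,
        panel_b=panel_b,
        marker_panel=pd.Series(panel_of, index=genotypes.markers),
        sample_platform=pd.Series(platform, index=genotypes.samples),
    )


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------
def _append_founder(ped: Pedigree, ind: str) -> Pedigree:
    new = Pedigree.__new__(Pedigree)
    new.ids = list(ped.ids) + [ind]
    new.parent_map = dict(ped.parent_map)
    new.parent_map[ind] = (None, None)
    return new


@dataclass
class CPTDataset:
    config: SimulationConfig
    founders: GenotypeMatrix
    controls: GenotypeMatrix
    progeny: GenotypeMatrix
    genotypes: GenotypeMatrix  # founders + progeny + controls, error free
    families: pd.DataFrame
    truth_pedigree: Pedigree
    declared_pedigree: Pedigree
    survivors: List[str]
    layout: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: TruthRecord
    genotyped_ids: List[str]
    genotyping: GenotypingResult

    @property
    def control_ids(self) -> List[str]:
        return list(self.controls.samples)


def simulate_cpt(config: SimulationConfig) -> CPTDataset:
    """Run the full generator: population, survival, layout, phenotypes, panels."""
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    fam = make_families(founders, config, rng)
    controls = simulate_controls(config, founders, rng)

    all_dos = np.vstack([founders.dosages, fam.progeny.dosages, controls.dosages])
    all_ids = np.concatenate([founders.samples, fam.progeny.samples, controls.samples])
    genotypes = GenotypeMatrix(all_dos, all_ids, founders.markers, founders.alleles)

    progeny_ids = list(fam.progeny.samples)
    if config.n_survivors is not None:
        if config.n_survivors > len(progeny_ids):
            raise ValueError("n_survivors exceeds the number of progeny")
        keep = rng.choice(len(progeny_ids), size=config.n_survivors, replace=False)
        survivors = [progeny_ids[i] for i in np.sort(keep)]
    else:
        survivors = progeny_ids

    layout = assign_layout(survivors, list(controls.samples), config, rng)
    fam_map = dict(zip(fam.families["genotype_id"], fam.families["family_id"]))
    # controls are pedigree founders of their own (unrelated by default)
    truth_ped = fam.truth_pedigree
    decl_ped = fam.declared_pedigree
    for cid in controls.samples:
        truth_ped = _append_founder(truth_ped, cid)
        decl_ped = _append_founder(decl_ped, cid)
    layout.insert(2, "family_id", [fam_map.get(g, "CONTROL") for g in layout["genotype_id"]])

    pheno, truth = simulate_phenotypes(layout, genotypes, config, rng)

    planted = list(pd.unique(layout["genotype_id"]))
    frac = config.genotyping.genotyped_fraction
    planted_progeny = [g for g in planted if g in fam_map]
    n_geno = int(round(frac * len(planted_progeny)))
    chosen = rng.choice(len(planted_progeny), size=n_geno, replace=False)
    genotyped = (
        list(founders.samples)
        + sorted(planted_progeny[i] for i in chosen)
        + list(controls.samples)
    )
    genotyping = inject_genotyping_artifacts(
        genotypes.subset(samples=genotyped), config, rng
    )

    return CPTDataset(
        config=config,
        founders=founders,
        controls=controls,
        progeny=fam.progeny,
        genotypes=genotypes,
        families=fam.families,
        truth_pedigree=truth_ped,
        declared_pedigree=decl_ped,
        survivors=survivors,
        layout=layout,
        phenotypes=pheno,
        truth=truth,
        genotyped_ids=genotyped,
        genotyping=genotyping,
    )
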