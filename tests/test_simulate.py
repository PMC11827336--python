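"""Synthetic CPT generator: population, layout and phenotype structure."""

import numpy as np
import pandas as pd
import pytest

from cloneval import simulate as sim
from cloneval.genotypes import GenotypeMatrix
from cloneval.qc import mendelian_error_rate
from conftest import tiny_config


def test_founder_dosages_are_valid():
    cfg = tiny_config(n_founders=48, n_snps=2000)
    g = sim.simulate_founders(cfg, np.random.default_rng(1))
    assert g.dosages.shape == (48, 2000)
    assert np.isin(g.dosages, [0, 1, 2]).all()


def test_forced_half_frequency():
    cfg = tiny_config(maf_range=(0.5, 0.5), n_founders=48, n_snps=1500)
    g = sim.simulate_founders(cfg, np.random.default_rng(2))
    assert g.allele_freq().mean() == pytest.approx(0.5, abs=0.01)


def test_hardy_weinberg_heterozygosity():
    # observed heterozygote share tracks 2p(1-p) averaged over markers
    cfg = tiny_config(n_founders=48, n_snps=2000)
    g = sim.simulate_founders(cfg, np.random.default_rng(3))
    het = (g.dosages == 1).mean(axis=0)
    p = g.allele_freq()
    expected = 2 * p * (1 - p)
    assert het.mean() == pytest.approx(expected.mean(), rel=0.02)


def test_invalid_maf_range_rejected():
    with pytest.raises(ValueError):
        tiny_config(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        tiny_config(maf_range=(0.1, 0.6))


def test_non_square_lattice_rejected():
    with pytest.raises(ValueError):
        tiny_config(treatments_per_subtrial=15)


def test_negative_variance_rejected():
    with pytest.raises(ValueError):
        tiny_config(true_variances=sim.TrueVariances(additive=-1.0))


def test_study_scale_family_count():
    # 47 half-sib + 11 full-sib families x 60 progeny
    cfg = sim.study_config(n_snps=10)
    rng = np.random.default_rng(0)
    founders = sim.simulate_founders(cfg, rng)
    fam = sim.make_families(founders, cfg, rng)
    assert fam.progeny.n_samples == 3480
    assert fam.families["family_id"].nunique() == 58
    assert (fam.families.groupby("family_id").size() == 60).all()


def test_mendelian_segregation_certainty():
    # opposite homozygote parents always give a heterozygous offspring
    founders = GenotypeMatrix(
        np.array([[0.0] * 20, [2.0] * 20]), ["P1", "P2"], [f"m{i}" for i in range(20)]
    )
    cfg = tiny_config(n_founders=2, n_snps=20, n_hs_families=0, n_fs_families=1,
                      progeny_per_family=5)
    fam = sim.make_families(founders, cfg, np.random.default_rng(5))
    assert (fam.progeny.dosages == 1.0).all()


def test_pedigree_relationships_among_sibs():
    cfg = tiny_config(n_founders=20, n_snps=50, n_hs_families=6, n_fs_families=2,
                      progeny_per_family=8)
    fam = sim.make_families(
        sim.simulate_founders(cfg, np.random.default_rng(7)), cfg, np.random.default_rng(7)
    )
    A, ids = fam.truth_pedigree.numerator_matrix()
    idx = {i: k for k, i in enumerate(ids)}
    fs, hs = [], []
    for fid, grp in fam.families.groupby("family_id"):
        members = [idx[g] for g in grp["genotype_id"]]
        ftype = grp["family_type"].iloc[0]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                (fs if ftype == "full-sib" else hs).append(A[members[a], members[b]])
    assert np.mean(fs) == pytest.approx(0.5, abs=1e-12)  # exact for unrelated parents
    # half sibs share the mother; occasionally the drawn father too
    assert 0.24 <= np.mean(hs) <= 0.33


def test_more_families_than_parents_rejected():
    cfg = tiny_config(n_founders=4, n_hs_families=5, n_fs_families=0)
    with pytest.raises(ValueError):
        sim.make_families(sim.simulate_founders(cfg), cfg)


def test_layout_design_counts(tiny_ds):
    cfg = tiny_ds.config
    layout = tiny_ds.layout
    per_st = layout.groupby(["site", "sub_trial"])
    # trees per sub-trial = treatments x replicates
    assert (per_st.size() == cfg.treatments_per_subtrial * cfg.ramets_per_ortet).all()
    for (_, st), grp in per_st:
        # each genotype planted exactly once per replicate
        counts = grp.groupby(["replicate", "genotype_id"]).size()
        assert (counts == 1).all()
        for rep, rgrp in grp.groupby("replicate"):
            # blocks partition the treatments into block_size groups of block_size
            sizes = rgrp.groupby("incomplete_block").size()
            assert len(sizes) == cfg.block_size and (sizes == cfg.block_size).all()
            assert set(rgrp["genotype_id"]) == set(grp["genotype_id"])
        # controls present in every replicate
        for cid in tiny_ds.control_ids:
            assert (grp["genotype_id"] == cid).sum() == cfg.ramets_per_ortet


def test_layout_progeny_disjoint_within_site(tiny_ds):
    layout = tiny_ds.layout
    prog = layout[layout["family_id"] != "CONTROL"]
    for _, site_grp in prog.groupby("site"):
        per_geno = site_grp.groupby("genotype_id")["sub_trial"].nunique()
        assert (per_geno == 1).all()


def test_layout_requires_enough_progeny():
    cfg = tiny_config()
    with pytest.raises(ValueError):
        sim.assign_layout([f"G{i}" for i in range(5)], [f"C{i}" for i in range(4)], cfg)


def test_phenotype_residual_only_limit():
    tv = sim.TrueVariances(additive=0, dominance=0, trial=0, axe=0, dxe=0,
                           residual_per_site=100.0, nugget=0)
    cfg = tiny_config(true_variances=tv, spatial_rho_col=0.0, spatial_rho_row=0.0, seed=31)
    ds = sim.simulate_cpt(cfg)
    y = ds.truth.phenotypic_values.to_numpy()
    assert np.var(y, ddof=1) == pytest.approx(100.0, rel=0.2)
    assert np.all(ds.truth.genotypic_values == 0.0)


def test_phenotype_component_calibration(tiny_ds):
    cfg = tiny_ds.config
    rv = tiny_ds.truth.realized_variances
    # marker-score components are rescaled to hit their targets exactly
    assert rv["additive"] == pytest.approx(cfg.true_variances.additive, rel=1e-6)
    assert rv["dominance"] == pytest.approx(cfg.true_variances.dominance, rel=1e-6)
    assert rv["axe"] == pytest.approx(cfg.true_variances.axe, rel=1e-6)
    # the phenotype decomposes exactly into its simulated parts
    t = tiny_ds.truth
    lay = tiny_ds.layout
    recon = (
        cfg.trait_mean
        + t.trial_effects.loc[lay["sub_trial"]].to_numpy()
        + t.breeding_values.loc[lay["genotype_id"]].to_numpy()
        + t.dominance_deviations.loc[lay["genotype_id"]].to_numpy()
        + np.array([t.additive_by_site.loc[g, s] for g, s in zip(lay["genotype_id"], lay["site"])])
        + np.array([t.dominance_by_site.loc[g, s] for g, s in zip(lay["genotype_id"], lay["site"])])
        + t.spatial_residuals.loc[lay["tree_id"]].to_numpy()
    )
    np.testing.assert_allclose(t.phenotypic_values.to_numpy(), recon, atol=1e-9)


def test_clones_share_genetic_values(tiny_ds):
    # removing the tree-level spatial residual leaves a value constant over
    # all ramets of an ortet within a site (genotype + trial + GxE effects)
    layout = tiny_ds.layout
    resid = tiny_ds.truth.spatial_residuals
    y = tiny_ds.truth.phenotypic_values
    genetic = (y - resid).rename("g")
    df = layout.assign(g=genetic.loc[layout["tree_id"]].to_numpy())
    spread = df.groupby(["genotype_id", "site", "sub_trial"])["g"].agg(
        lambda v: v.max() - v.min()
    )
    assert spread.max() < 1e-9


def test_spatial_field_correlogram():
    tv = sim.TrueVariances(additive=0, dominance=0, trial=0, axe=0, dxe=0,
                           residual_per_site=100.0, nugget=0)
    cfg = tiny_config(
        n_founders=30, n_hs_families=25, n_fs_families=1, progeny_per_family=10,
        sites=[sim.SiteSpec("S1", 1)], treatments_per_subtrial=256, block_size=16,
        ramets_per_ortet=5, n_controls=6, true_variances=tv,
        spatial_rho_col=0.3, spatial_rho_row=0.5, seed=17,
    )
    ds = sim.simulate_cpt(cfg)
    lay = ds.layout
    field = np.zeros((16, 80))
    field[lay["row"] - 1, lay["col"] - 1] = ds.truth.spatial_residuals.to_numpy()

    def lag1(a, axis):
        if axis == 0:
            x, z = a[:-1, :].ravel(), a[1:, :].ravel()
        else:
            x, z = a[:, :-1].ravel(), a[:, 1:].ravel()
        return np.corrcoef(x, z)[0, 1]

    assert lag1(field, 0) == pytest.approx(0.5, abs=0.12)  # along rows axis
    assert lag1(field, 1) == pytest.approx(0.3, abs=0.12)  # along columns axis


def test_artifacts_identity_when_rates_zero(tiny_ds):
    cfg = tiny_config(genotyping=sim.GenotypingArtifacts(
        missing_rate=0.0, error_rate=0.0, panel_flip_fraction=0.0, genotyped_fraction=1.0))
    g = tiny_ds.founders
    res = sim.inject_genotyping_artifacts(g, cfg, np.random.default_rng(4))
    np.testing.assert_array_equal(res.observed.dosages, g.dosages)


def test_artifacts_missing_rate_binomial():
    cfg = tiny_config(n_founders=25, n_snps=400,
                      genotyping=sim.GenotypingArtifacts(missing_rate=0.5, error_rate=0.0))
    g = sim.simulate_founders(cfg, np.random.default_rng(9))
    res = sim.inject_genotyping_artifacts(g, cfg, np.random.default_rng(9))
    n_calls = g.dosages.size
    frac = res.observed.missing_mask.mean()
    se = np.sqrt(0.25 / n_calls)
    assert abs(frac - 0.5) < 3 * se


def test_artifacts_create_opposing_homozygotes():
    # genotyping errors put opposing homozygotes into a true parent-offspring pair
    parent = np.zeros(4000)
    child = np.zeros(4000)  # child identical: ME rate 0 without errors
    g = GenotypeMatrix(np.vstack([parent, child]), ["P", "O"], [f"m{i}" for i in range(4000)])
    cfg = tiny_config(genotyping=sim.GenotypingArtifacts(missing_rate=0.0, error_rate=0.02))
    res = sim.inject_genotyping_artifacts(g, cfg, np.random.default_rng(13))
    rate = mendelian_error_rate(res.observed.dosages[1], res.observed.dosages[0])
    assert rate > 0.0


def test_survival_subsampling():
    cfg = tiny_config(n_survivors=70)
    ds = sim.simulate_cpt(cfg)
    assert len(ds.survivors) == 70
    planted = set(ds.layout.loc[ds.layout.family_id != "CONTROL", "genotype_id"])
    assert planted <= set(ds.survivors)


def test_simulation_reproducible():
    a = sim.simulate_cpt(tiny_config(seed=99))
    b = sim.simulate_cpt(tiny_config(seed=99))
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
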