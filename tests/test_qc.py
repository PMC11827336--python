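"""Marker/sample filters, panel merging and pedigree verification."""

import numpy as np
import pytest

from cloneval import simulate as sim
from cloneval.genotypes import GenotypeMatrix
from cloneval.qc import (
    QCThresholds,
    filter_markers_and_samples,
    intersect_panels,
    mendelian_error_rate,
    verify_and_correct_pedigree,
)
from conftest import tiny_config


def _gm(dosages, samples, markers, alleles=None):
    return GenotypeMatrix(np.asarray(dosages, dtype=float), samples, markers, alleles)


# ----------------------------------------------------------------------
# panel intersection
# ----------------------------------------------------------------------
def test_intersection_is_shared_markers():
    a = _gm([[0, 1, 2]], ["s1"], ["m1", "m2", "m3"])
    b = _gm([[1, 2, 0]], ["s2"], ["m2", "m3", "m4"])
    merged = intersect_panels(a, b)
    assert list(merged.markers) == ["m2", "m3"]
    assert list(merged.samples) == ["s1", "s2"]
    np.testing.assert_array_equal(merged.dosages, [[1, 2], [1, 2]])


def test_intersection_harmonizes_flipped_alleles():
    alleles_a = np.array([("A", "C"), ("G", "T")], dtype=object)
    alleles_b = np.array([("A", "C"), ("T", "G")], dtype=object)  # second flipped
    a = _gm([[0, 0], [2, 2]], ["s1", "s2"], ["m1", "m2"], alleles_a)
    b = _gm([[0, 2], [1, 1]], ["s3", "s4"], ["m1", "m2"], alleles_b)
    merged = intersect_panels(a, b)
    # panel B's m2 dosages are flipped to d -> 2 - d
    np.testing.assert_array_equal(merged.dosages[2], [0, 0])
    np.testing.assert_array_equal(merged.dosages[3], [1, 1])


def test_intersection_identity_and_errors():
    a = _gm([[0, 1]], ["s1"], ["m1", "m2"])
    b = _gm([[2, 1]], ["s2"], ["m1", "m2"])
    assert list(intersect_panels(a, b).markers) == ["m1", "m2"]
    c = _gm([[1]], ["s3"], ["zz"])
    with pytest.raises(ValueError, match="no markers"):
        intersect_panels(a, c)


# ----------------------------------------------------------------------
# marker and sample filters
# ----------------------------------------------------------------------
def test_filter_rules():
    rng = np.random.default_rng(0)
    n = 50
    good = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
    low_call = good.copy()
    low_call[:3, 0] = np.nan  # call rate 47/50 = 0.94 < 0.95
    ok_call = good.copy()
    ok_call[:2, 0] = np.nan  # 0.96 retained
    low_maf = np.zeros((n, 1))
    low_maf[0, 0] = 1.0  # MAF = 0.01 < 0.02
    edge_maf = np.zeros((n, 1))
    edge_maf[0, 0] = 2.0  # MAF exactly 0.02: retained (strict <)
    mono = np.zeros((n, 1))  # MAF 0 removed
    dosages = np.hstack([good, low_call, ok_call, low_maf, edge_maf, mono])
    g = _gm(dosages, [f"s{i}" for i in range(n)], ["good", "lowcall", "okcall", "lowmaf", "edgemaf", "mono"])
    out, report = filter_markers_and_samples(g)
    assert list(out.markers) == ["good", "okcall", "edgemaf"]
    assert report.markers_removed_by_rule["call_rate"] == 1
    assert report.markers_removed_by_rule["maf"] == 2
    assert report.markers_out == report.markers_in - sum(report.markers_removed_by_rule.values())


def test_filter_sample_call_rate_and_exclusion_list():
    rng = np.random.default_rng(1)
    dosages = rng.binomial(2, 0.4, size=(10, 20)).astype(float)
    dosages[0, :15] = np.nan  # sample call rate 0.25 < 0.80
    g = _gm(dosages, [f"s{i}" for i in range(10)], [f"m{i}" for i in range(20)])
    out, report = filter_markers_and_samples(
        g, QCThresholds(marker_call_rate_min=0.5), exclude_markers=["m0", "m1"]
    )
    assert report.markers_removed_by_rule["exclusion_list"] == 2
    assert report.samples_removed == 1
    assert "s0" not in set(out.samples)


def test_filter_all_markers_removed_is_error():
    g = _gm(np.zeros((5, 3)), [f"s{i}" for i in range(5)], ["a", "b", "c"])
    with pytest.raises(ValueError, match="all markers removed"):
        filter_markers_and_samples(g)


# ----------------------------------------------------------------------
# Mendelian errors
# ----------------------------------------------------------------------
def test_mendelian_error_examples():
    same = np.array([0, 1, 2, 0, 1])
    assert mendelian_error_rate(same, same) == 0.0
    off = np.array([0.0] * 9 + [2.0])
    par = np.array([1.0] * 9 + [0.0])
    assert mendelian_error_rate(off, par) == pytest.approx(0.1)
    het = np.ones(10)
    hom = np.concatenate([np.zeros(5), 2 * np.ones(5)])
    assert mendelian_error_rate(het, hom) == 0.0


def test_mendelian_error_symmetric_and_order_invariant():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 3, 200).astype(float)
    b = rng.integers(0, 3, 200).astype(float)
    assert mendelian_error_rate(a, b) == mendelian_error_rate(b, a)
    perm = rng.permutation(200)
    assert mendelian_error_rate(a[perm], b[perm]) == mendelian_error_rate(a, b)


def test_mendelian_error_requires_joint_calls():
    a = np.full(5, np.nan)
    b = np.ones(5)
    with pytest.raises(ValueError):
        mendelian_error_rate(a, b)


# ----------------------------------------------------------------------
# pedigree verification / correction
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def clean_population():
    cfg = tiny_config(
        n_founders=16, n_snps=600, n_hs_families=6, n_fs_families=2,
        progeny_per_family=10, seed=41,
        genotyping=sim.GenotypingArtifacts(missing_rate=0.0, error_rate=0.0,
                                           genotyped_fraction=1.0),
    )
    rng = np.random.default_rng(cfg.seed)
    founders = sim.simulate_founders(cfg, rng)
    fam = sim.make_families(founders, cfg, rng)
    g = GenotypeMatrix(
        np.vstack([founders.dosages, fam.progeny.dosages]),
        list(founders.samples) + list(fam.progeny.samples),
        founders.markers,
    )
    return founders, fam, g


def test_consistent_pedigree_unflagged(clean_population):
    founders, fam, g = clean_population
    corrected, conflicts = verify_and_correct_pedigree(
        fam.truth_pedigree, g, list(founders.samples)
    )
    bad = conflicts[~conflicts["action"].isin(["confirmed"])]
    assert bad.empty
    assert corrected.to_frame().equals(fam.truth_pedigree.to_frame())


def test_hidden_fathers_recovered(clean_population):
    # declared pedigree hides the pollen father of every half-sib progeny;
    # on error-free data the opposing-homozygote scan recovers him
    founders, fam, g = clean_population
    corrected, conflicts = verify_and_correct_pedigree(
        fam.declared_pedigree, g, list(founders.samples)
    )
    hs = fam.families.loc[fam.families["family_type"] == "half-sib", "genotype_id"]
    hits = sum(
        corrected.parents_of(child)[0] == fam.truth_pedigree.parents_of(child)[0]
        for child in hs
    )
    assert hits / len(hs) >= 0.95


def test_wrong_declared_parent_flagged(clean_population):
    founders, fam, g = clean_population
    child = fam.families.loc[fam.families["family_type"] == "full-sib", "genotype_id"].iloc[0]
    true_sire, true_dam = fam.truth_pedigree.parents_of(child)
    # swap in an unrelated founder as the declared dam
    impostor = next(
        f for f in founders.samples if f not in (true_sire, true_dam)
    )
    broken = fam.truth_pedigree.with_parents(child, true_sire, impostor)
    corrected, conflicts = verify_and_correct_pedigree(broken, g, list(founders.samples))
    row = conflicts[(conflicts["offspring"] == child) & (conflicts["slot"] == "dam")]
    assert row["action"].iloc[0] == "replaced"
    assert corrected.parents_of(child)[1] == true_dam


def test_ungenotyped_parent_skipped_with_warning(clean_population):
    founders, fam, g = clean_population
    child = fam.families["genotype_id"].iloc[0]
    broken = fam.truth_pedigree.with_parents(child, "GHOST", fam.truth_pedigree.parents_of(child)[1])
    corrected, conflicts = verify_and_correct_pedigree(broken, g, list(founders.samples))
    row = conflicts[(conflicts["offspring"] == child) & (conflicts["slot"] == "sire")]
    assert row["action"].iloc[0] == "skipped_ungenotyped"
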