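"""Shared fixtures: one tiny simulated CPT dataset reused across tests."""

import numpy as np
import pytest

from cloneval import simulate as sim
from cloneval.relmat import blend, numerator_A, subset_A22, vanraden_Ga, vitezica_Gd
from cloneval.traits import add_volume_columns


def tiny_config(**overrides) -> sim.SimulationConfig:
    """A very small but structurally complete CPT configuration."""
    base = dict(
        n_founders=12,
        n_snps=400,
        n_hs_families=8,
        n_fs_families=2,
        progeny_per_family=8,
        ramets_per_ortet=3,
        sites=[sim.SiteSpec("S1", 2), sim.SiteSpec("S2", 2)],
        treatments_per_subtrial=16,
        block_size=4,
        n_controls=4,
        n_survivors=None,
        genotyping=sim.GenotypingArtifacts(genotyped_fraction=1.0),
        seed=202,
    )
    base.update(overrides)
    return sim.SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_ds() -> sim.CPTDataset:
    return sim.simulate_cpt(tiny_config())


@pytest.fixture(scope="session")
def tiny_pheno(tiny_ds):
    return add_volume_columns(tiny_ds.phenotypes)


@pytest.fixture(scope="session")
def tiny_kernels(tiny_ds):
    g = tiny_ds.genotypes.subset(samples=tiny_ds.genotyped_ids)
    Ga = vanraden_Ga(g)
    Gd = vitezica_Gd(g, freqs=Ga.allele_freqs)
    A = numerator_A(tiny_ds.truth_pedigree)
    A22 = subset_A22(A, list(g.samples))
    Gstar = blend(Ga, A22)
    return {"genotypes": g, "Ga": Ga, "Gd": Gd, "A22": A22, "Gstar": Gstar}
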