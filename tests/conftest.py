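import numpy as np
import pytest

from mobilome.forge import (ComplexConfig, ElementSpec, forge_complex,
                            plant_in_group, standard_complex)


@pytest.fixture(scope="session")
def small_complex():
    """2+2 strains, 25 kb, with a shared ICE and GI planted in group A."""
    cfg = ComplexConfig(n_strains_per_group=2, ancestral_length=25_000,
                        rng_seed=3)
    cx = forge_complex(cfg)
    ice = ElementSpec("iE01", "ICE", 9000, 9, cargo_gc_offset=-0.05,
                      integration_site="tRNA-Ala-GGC", dr_length=48,
                      module_genes=["integrase", "virB1", "virB4", "virB5",
                                    "virB6", "virB9", "virB11",
                                    "relaxase VirD2", "t4cp2 coupling protein"])
    gi = ElementSpec("iE02", "GI", 5000, 5, cargo_gc_offset=0.05,
                     integration_site="tRNA-Arg-TCT", dr_length=14,
                     module_genes=["integrase", "merR regulator"])
    plant_in_group(cx, ice, 11)
    plant_in_group(cx, gi, 23)
    return cx


@pytest.fixture(scope="session")
def study_complex():
    """The standard study condition (8 strains, 3 integrated elements +
    plasmid in group A, ICE split across draft contigs)."""
    return standard_complex(1)


@pytest.fixture(scope="session")
def family_table(small_complex):
    from mobilome import pangenome
    table = pangenome.cluster_from_genomes(small_complex.genomes)
    pangenome.compartmentalize(table, small_complex.groups)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
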