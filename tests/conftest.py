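import numpy as np
import pytest
from hypothesis import settings

from cosegmap import CrossConfig, Genotype, ROLES, Role, VariantRecord
from cosegmap.simulate import make_fixture_suite

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def make_variant(
    scaffold="s1",
    pos=100,
    ref="A",
    alt="G",
    hom_parent=Genotype.HOM_ALT,
    het_parent=Genotype.HET,
    hom_pool=Genotype.HOM_ALT,
    het_pool=Genotype.HET,
    pass_filter=True,
):
    return VariantRecord(
        scaffold=scaffold,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={
            Role.HOM_PARENT: hom_parent,
            Role.HET_PARENT: het_parent,
            Role.HOM_POOL: hom_pool,
            Role.HET_POOL: het_pool,
        },
        pass_filter=pass_filter,
    )


def random_variant(rng, scaffold, pos, classes=("SNP", "MNP", "INDEL")):
    """Random record with arbitrary genotypes/filters for oracle fuzzing."""
    kind = classes[rng.integers(0, len(classes))]
    if kind == "SNP":
        ref, alt = "A", "G"
    elif kind == "MNP":
        ref, alt = "AT", "GC"
    else:
        ref, alt = "A", "AT"
    gts = {role: Genotype(int(rng.integers(-1, 3))) for role in ROLES}
    return VariantRecord(
        scaffold=scaffold,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=gts,
        pass_filter=bool(rng.random() < 0.85),
    )


@pytest.fixture(scope="session")
def small_cross_cfg():
    """Desk-scale cross kept small enough for repeated end-to-end runs."""
    return CrossConfig(
        scaffold_lengths=(3_000_000, 3_000_000, 3_000_000),
        causal_pos=1_500_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def fixture_suite(small_cross_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(small_cross_cfg, outdir)
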