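import pytest

from l1screen import SimConfig, gen_bio_oligos, gen_l1_reference, gen_target_locus


@pytest.fixture(scope="session")
def l1_ref():
    return gen_l1_reference(SimConfig(seed=1))


@pytest.fixture(scope="session")
def oligos(l1_ref):
    return gen_bio_oligos(l1_ref)


@pytest.fixture(scope="session")
def target(l1_ref, oligos):
    seq, info = gen_target_locus(
        length=5000, planted_en_sites=5, seed=3, plant_a_tract=True,
        avoid_oligos=oligos,
    )
    return seq, info
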