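import pytest

from structbatch.fixtures import (build_coil, build_helix,
                                  build_synthetic_binding_interface,
                                  build_synthetic_c2_domain)


@pytest.fixture(scope="session")
def helix12():
    return build_helix(12)


@pytest.fixture(scope="session")
def coil_monomer():
    """16-residue seeded coil; large enough that circular-permutation scans
    over its rings have stable score statistics."""
    return build_coil(16, seed=7)


@pytest.fixture(scope="session")
def synthetic_complex():
    return build_synthetic_binding_interface()


@pytest.fixture(scope="session")
def c2_domain():
    return build_synthetic_c2_domain(seed=0)
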