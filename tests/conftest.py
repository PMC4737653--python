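import dataclasses

import numpy as np
import pytest

from sheetfuse import (
    FixtureSpec,
    FusionConfig,
    make_chimera_test_pair,
    make_fixture,
    scan_insertion_sites,
)


@pytest.fixture(scope="session")
def helix18():
    return make_fixture(FixtureSpec("helix", (18,)))


@pytest.fixture(scope="session")
def hairpin828():
    return make_fixture(FixtureSpec("hairpin", (8, 2, 8)))


@pytest.fixture(scope="session")
def toy_ferredoxin():
    return make_fixture(FixtureSpec("toy_ferredoxin"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def engineered():
    """Host, insert, the scanned engineered site, and a widened variant.

    The engineered match is geometrically exact, so its junctions bond
    directly (zero-length linkers).  The widened site removes two further
    host strand residues, leaving a gap that a 2-residue linker legitimately
    closes — the non-trivial linker-closure case.
    """
    host, insert, expected = make_chimera_test_pair(0)
    site = scan_insertion_sites(host, insert, FusionConfig())[0]
    wide = dataclasses.replace(
        site, host_j=site.host_j + 2,
        removed_segment=tuple(range(site.host_i + 1, site.host_j + 2)))
    return {"host": host, "insert": insert, "expected": expected,
            "site": site, "wide_site": wide}
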