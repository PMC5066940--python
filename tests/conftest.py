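"""Shared fixtures: synthetic duplexes with known ground truth.

Builders are moderately expensive (internal-coordinate calibration plus
phosphate bridging), so the canonical structures are session-scoped.
"""

import numpy as np
import pytest

from duplexlens import (
    GeneratorSpec,
    build_helix,
    build_torsion_exact,
    complement_sequence,
    make_ensemble,
    pair_duplex,
)

DDD = "CGCGAATTCGCG"
OXOG4 = "CGCXAATTCGCG"
OXOG10 = "CGCGAATTCXCG"


@pytest.fixture(scope="session")
def ddd_helix():
    """Ideal Drew-Dickerson duplex at uniform 36 deg / 3.38 Å."""
    s, truth = build_helix(GeneratorSpec(sequence=DDD))
    return s, truth


@pytest.fixture(scope="session")
def ddd_map(ddd_helix):
    s, _ = ddd_helix
    return pair_duplex(s, DDD, complement_sequence(DDD))


@pytest.fixture(scope="session")
def oxog4_helix():
    """Lesion-bearing duplex (8-oxoG at position 4), ideal helical placement."""
    s, truth = build_helix(GeneratorSpec(sequence=OXOG4))
    return s, truth


@pytest.fixture(scope="session")
def oxog4_bii():
    """Torsion-exact duplex with BII (eps 270, zeta 180) injected 3' of position 4."""
    return build_torsion_exact(
        GeneratorSpec(sequence=OXOG4, eps_zeta={4: (270.0, 180.0)}))


@pytest.fixture(scope="session")
def ddd_exact():
    """Torsion-exact all-default (all-BI) Drew-Dickerson duplex."""
    return build_torsion_exact(GeneratorSpec(sequence=DDD))


@pytest.fixture(scope="session")
def jittered_ensemble(ddd_helix):
    s, _ = ddd_helix
    return make_ensemble(s, sigma=0.1, n=10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
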