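import numpy as np
import pytest

from phasesep.config import RunConfig
from phasesep.fixtures import FixtureSegment, FixtureSpec, make_structure, make_sticker_toy


@pytest.fixture(scope="session")
def internal_config() -> RunConfig:
    return RunConfig(ss_backend="internal")


@pytest.fixture(scope="session")
def helix_model():
    """30-residue ideal alpha helix, confident pLDDT."""
    return make_structure(
        FixtureSpec(segments=[FixtureSegment(30, "helix", 90.0)], seed=1, name="helix30")
    )


@pytest.fixture(scope="session")
def helix_coil_model():
    """Helix (pLDDT 90) followed by a 25-residue low-confidence coil."""
    return make_structure(
        FixtureSpec(
            segments=[
                FixtureSegment(30, "helix", 90.0),
                FixtureSegment(25, "coil", 40.0),
            ],
            seed=3,
            name="helix_coil",
        )
    )


@pytest.fixture(scope="session")
def extended_model():
    return make_structure(
        FixtureSpec(segments=[FixtureSegment(20, "extended", 90.0)], seed=2, name="ext20")
    )


@pytest.fixture(scope="session")
def sticker_toy_21():
    return make_sticker_toy(2, 1, residues_per_cluster=4, cluster_spacing=50.0)


def make_random_coil(length: int, seed: int, plddt: float = 90.0):
    return make_structure(
        FixtureSpec(
            segments=[FixtureSegment(length, "coil", plddt)], seed=seed, name=f"coil{seed}"
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
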