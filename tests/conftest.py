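import numpy as np
import pytest

from retroprobe import fixtures
from retroprobe.models import Chemistry
from retroprobe.probe_mapper import map_platform
from retroprobe.re_annotator import GeneIndex, RepeatIndex, build_annotation


@pytest.fixture(scope="session")
def demo_fixture():
    """The bundled synthetic fixture (seed 1, antisense-cRNA chemistry)."""
    return fixtures.generate_fixture(fixtures.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def demo_hits(demo_fixture):
    hits, unmapped = map_platform(demo_fixture.platform.manifest, demo_fixture.genome.genome)
    return hits, unmapped


@pytest.fixture(scope="session")
def demo_rows(demo_fixture, demo_hits):
    hits, _ = demo_hits
    return build_annotation(
        demo_fixture.platform.manifest,
        hits,
        RepeatIndex(demo_fixture.genome.repeats),
        GeneIndex(demo_fixture.genome.genes),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sense_fixture():
    """Same layout generated for the sense-cDNA chemistry."""
    return fixtures.generate_fixture(
        fixtures.FixtureSpec(seed=1, chemistry=Chemistry.SENSE_CDNA)
    )
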