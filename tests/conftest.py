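import numpy as np
import pytest

from metaqtl.simulate import SimConfig, write_bundle
from metaqtl.types import CI95_FACTOR, GeneticMap, ProjectedQtl


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def bundle(default_cfg, tmp_path_factory):
    """A full synthetic bundle shared across tests (seeded, deterministic)."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(default_cfg, outdir)
    return paths


@pytest.fixture
def identity_map() -> GeneticMap:
    entries = [(f"m{i}", 1, float(10 * i)) for i in range(11)]
    return GeneticMap("identity", entries)


def projected_from_counts(x, s, chromosome=1):
    """Helper: build ProjectedQtl lists from raw position/sd arrays."""
    return [
        ProjectedQtl(
            qtl_id=f"q{i}",
            chromosome=chromosome,
            position=float(xi),
            sigma=float(si),
            ci95=float(si) * CI95_FACTOR,
        )
        for i, (xi, si) in enumerate(zip(np.atleast_1d(x), np.atleast_1d(s)))
    ]
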