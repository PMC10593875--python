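import numpy as np
import pytest

from pedcoseg.simulate import SimulationConfig, generate, write_dataset

CALLERS = ("cnvnator", "erds", "lumpy", "manta")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, background_variant_count=300)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_paths(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_ds")
    return write_dataset(small_dataset, outdir)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


NUCLEAR_PED = [
    "FAM1 DAD 0 0 1 1",
    "FAM1 MOM 0 0 2 1",
    "FAM1 KID1 DAD MOM 1 2",
    "FAM1 KID2 DAD MOM 2 1",
]
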