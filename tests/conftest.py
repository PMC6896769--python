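import numpy as np
import pytest

from fpsim.core import FingerprintMetadata, FingerprintRecord
from fpsim.synthetic import SyntheticSpec, generate_records


def make_records(num_bits, count, seed, density=None):
    return generate_records(
        SyntheticSpec(num_bits=num_bits, count=count, seed=seed, density=density)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def maccs_fps_text():
    """A small 166-bit MACCS-style FPS file with full header metadata."""
    return (
        "#FPS1\n"
        "#num_bits=166\n"
        "#type=OpenEye-MACCS166/3\n"
        "#software=OEGraphSim/2.0.6\n"
        "#source=drugs.sdf\n"
        "#date=2019-06-20T14:20:32\n"
        "000000103084601a59de42e9ea7f7bbbdf6ffe1f00\tacetsali\n"
        "000000000084241042584430030051444500051400\tacyclovir\n"
        "00000000300048b0a97be96ac6a6765e5e7d172f00\tamitriptyline\n"
    )


@pytest.fixture
def maccs_records(maccs_fps_text, tmp_path):
    import fpsim.fps_io as fps_io

    path = tmp_path / "maccs.fps"
    path.write_text(maccs_fps_text)
    with fps_io.read_fps(path) as reader:
        return reader.metadata, list(reader)
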