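import pytest

from dartk.simulate import SimulationSpec, write_fixture


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A complete synthetic input bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    spec = SimulationSpec(seed=11)
    paths = write_fixture(spec, outdir)
    return spec, paths
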