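import pytest

from dcdc.synthetic_data import generate_fixture_suite


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Session-scoped synthetic fixture suite."""
    outdir = tmp_path_factory.mktemp("fixtures")
    generate_fixture_suite(outdir, seed=7)
    return outdir
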