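import pytest

from dbaffinity import RunSpec, load_reference_library, simulate_run


@pytest.fixture(scope="session")
def ref_lib():
    return load_reference_library()


@pytest.fixture(scope="session")
def default_run(ref_lib):
    """The default synthetic run: 1 ppm m/z jitter, 0.05 min RT jitter,
    no fragment dropout, 20 decoy features, seed 42."""
    return simulate_run(ref_lib, RunSpec(seed=42))
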