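import pytest

from dinomir import simulate as sim

#: lag/log ratio spec used by most synthetic fixtures: a 4x up, a
#: lag-only, and a 4x down miRNA among the known-planted set
RATIO_SPEC = [
    ("aca-miR101-5p", 4.0),
    ("aca-miR102-5p", "only-A"),
    ("aca-miR103-5p", 0.25),
]


@pytest.fixture(scope="session")
def config():
    return sim.SimConfig(seed=1, fold_change_spec=list(RATIO_SPEC))


@pytest.fixture(scope="session")
def reference(config):
    return sim.generate_reference(config)


@pytest.fixture(scope="session")
def libraries(reference, config):
    return sim.generate_libraries(reference, config, mode="deterministic")


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, config):
    """Simulated input directory (deterministic mode) shared by tests."""
    out = tmp_path_factory.mktemp("sim") / "in"
    sim.simulate_to_dir(config, out, mode="deterministic")
    return out
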