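import pytest

from kinout import synthetic


@pytest.fixture(scope="session")
def toy_registry():
    """Deterministic 10-subfamily registry + domain library."""
    return synthetic.make_toy_registry(n_subfamilies=10, seed=42)


@pytest.fixture(scope="session")
def desk_kinome(toy_registry):
    """The desk-scale planted-event kinome: 200 sequences, 10 subfamilies,
    hybrid rate 0.10, rogue rate 0.025, fixed seed."""
    registry, library = toy_registry
    config = synthetic.KinomeConfig(
        n_sequences=200, n_subfamilies=10,
        hybrid_rate=0.10, rogue_rate=0.025, seed=42,
    )
    return synthetic.generate_kinome(registry, library, config)
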