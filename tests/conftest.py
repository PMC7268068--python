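import pytest

from fearpattern import DesignParams, assign_reinforcement, generate_design


@pytest.fixture(scope="session")
def default_design():
    """The reference design: 8 blocks x 24 trials, reinforcement assigned."""
    return assign_reinforcement(generate_design(DesignParams(seed=5)), seed=11)


@pytest.fixture(scope="session")
def small_design():
    """A 2-block miniature used where full scale is unnecessary."""
    return assign_reinforcement(
        generate_design(DesignParams(n_blocks=2, trials_per_block=16, seed=3)), seed=4
    )
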