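import pytest

from mirscreen.synthetic_data import gen_field_image, gen_screen_table, make_planted_scenario


@pytest.fixture(scope="session")
def small_field():
    """100-nucleus field, 20% apoptotic, clear channel separation."""
    return gen_field_image(100, 0.2, seed=7)


@pytest.fixture(scope="session")
def noiseless_screen():
    scenario = make_planted_scenario(seed=0, noise_sd=0.0)
    table, truth = gen_screen_table(scenario, seed=0)
    return scenario, table, truth
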