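import pytest

from datcascade.simulate import (
    SimConfig,
    generate_pair_experiment,
    make_truth,
    split_pair,
)


@pytest.fixture(scope="session")
def small_config():
    """A compact planted library: enough genes per stratum for the rank
    filter to have discriminating work, small enough for fast tests."""
    return SimConfig(
        seed=42,
        n_genes=400,
        class_counts={
            "concordant_up": 64,
            "concordant_down": 64,
            "discordant": 16,
            "pair1_only": 8,
            "pair2_only": 8,
        },
        n_patients=120,
        n_offtarget=10,
        n_specific=40,
    )


@pytest.fixture(scope="session")
def truth(small_config):
    return make_truth(small_config)


@pytest.fixture(scope="session")
def pair_experiment(small_config, truth):
    return generate_pair_experiment(small_config, truth)


@pytest.fixture(scope="session")
def de_tables(pair_experiment):
    from datcascade.de import nb_wald_test

    de1 = nb_wald_test(split_pair(pair_experiment, "pair1"))
    de2 = nb_wald_test(split_pair(pair_experiment, "pair2"))
    return de1, de2
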