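import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_links():
    """4-record toy links file: a-b listed in both directions, b-c once,
    plus one mouse record that must be filtered out."""
    return (
        "9606.A 9606.B 900\n"
        "9606.B 9606.A 900\n"
        "9606.B 9606.C 400\n"
        "10090.X 10090.Y 800\n"
    )


@pytest.fixture
def planted_60():
    """Default-scale planted-module fixture with its seeded/held-out split."""
    from netprio.synthetic import (
        SyntheticSpec,
        generate_annotations,
        generate_network,
        split_module_seeds,
    )

    spec = SyntheticSpec(rng_seed=11)
    net, truth = generate_network(spec)
    ann = generate_annotations(net, truth, spec)
    seeded, held = split_module_seeds(truth, 0.5, 11)
    return net, truth, ann, seeded, held
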