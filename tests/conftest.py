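import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def cnc_list():
    from asr_audiobench import make_cnc_list

    return make_cnc_list(seed=1)


@pytest.fixture
def sentence_list():
    from asr_audiobench import make_sentence_list

    return make_sentence_list(seed=1)


@pytest.fixture
def triplet_series():
    from asr_audiobench import make_triplet_series

    return make_triplet_series(seed=1, n=24)
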