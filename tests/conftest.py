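import random

import pytest
from hypothesis import HealthCheck, settings

import phicrypt as pc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def key():
    """The worked-example key, derived from the passcode 'passcode'."""
    return pc.derive_key("passcode")


@pytest.fixture
def rng():
    return random.Random(0xC6A1)


@pytest.fixture
def zero_nonce_factory():
    """Deterministic nonce injection for idempotence/regression checks."""
    counter = [0]

    def factory():
        counter[0] += 1
        return counter[0].to_bytes(12, "big")

    return factory
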