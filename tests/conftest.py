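import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def table3_design():
    """The worked GAS-pharyngitis design: MAC 0.85/0.85, expected accuracy
    0.92/0.95, one-sided alpha 0.05, power 0.90, prevalence 0.35."""
    from targetdx import DesignSpec, MACriteria

    return DesignSpec(
        alpha=0.05,
        power=0.90,
        expected_sensitivity=0.92,
        expected_specificity=0.95,
        mac=MACriteria(0.85, 0.85),
        prevalence=0.35,
    )
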