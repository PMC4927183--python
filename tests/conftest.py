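import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regencirc import MatureMiRNA, MiRNACatalog

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Watson-Crick pairing used by the independent oracles in several test files
WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@pytest.fixture
def rng():
    return np.random.default_rng(20160629)


@pytest.fixture
def small_catalog():
    return MiRNACatalog(
        "zebrafish",
        [
            MatureMiRNA("miR-21", "zebrafish", "TAGCTTATCAGACTGATGTTGA"),
            MatureMiRNA("miR-133a", "zebrafish", "TTTGGTCCCCTTCAACCAGCTG"),
            MatureMiRNA("miR-204", "zebrafish", "TTCCCTTTGTCATCCTATGCCT"),
        ],
    )
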