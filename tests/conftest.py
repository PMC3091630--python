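import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqdesign.synth import ExpressionLaw, draw_expression, sample_reads

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# study conditions of the synthetic transcriptome used across the tx tests:
# a Refseq-scale catalogue with a power-law expression law and a noise floor
LAW = ExpressionLaw(n_transcripts=20_000, alpha=2.0, delta_d=1e-4, seed=42)


@pytest.fixture(scope="session")
def expression_law() -> ExpressionLaw:
    return LAW


@pytest.fixture(scope="session")
def true_nu() -> np.ndarray:
    return draw_expression(LAW)


@pytest.fixture(scope="session")
def pilot_100k(true_nu):
    """A 100 K-read pilot of the synthetic transcriptome."""
    return sample_reads(true_nu, 10**5, seed=43)


@pytest.fixture(scope="session")
def pilot_1m(true_nu):
    """A 1 M-read pilot of the same sample."""
    return sample_reads(true_nu, 10**6, seed=44)
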