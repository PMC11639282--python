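import numpy as np
import pytest

from s2wex.corrections import MixingSpec, S3CorrectionSpec
from s2wex.kinetic_core import EnrichmentSpec, RateConstants


@pytest.fixture
def enrichment():
    """Standard experimental enrichment context (0.7% initial, 25% final)."""
    return EnrichmentSpec(alpha_in=0.007, alpha_f=0.25)


@pytest.fixture
def enrichment_clean():
    """Idealized context with zero initial enrichment."""
    return EnrichmentSpec(alpha_in=0.0, alpha_f=0.25)


@pytest.fixture
def sr_ph83_rates():
    """Sr-PSII pH 8.3 published rates (k_f1, k_f2, k_s1, k_s2, k_c1, k_c2)."""
    return RateConstants(120.0, 65.0, 1.0, 50.0, 3.6, 12.0)


@pytest.fixture
def corrections_off():
    """Mixing and S3 specs that disable both clock corrections."""
    return {
        "mixing": MixingSpec(mode="instant"),
        "s3": S3CorrectionSpec(enabled=False),
    }


def random_rates(rng: np.random.Generator, low: float = -2.0, high: float = 2.0):
    """Log-uniform random rate set spanning the experimentally relevant decades."""
    return RateConstants(*(10.0 ** rng.uniform(low, high, 6)))
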