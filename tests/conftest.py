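import numpy as np
import pytest

from crisisdetect import (
    CohortConfig,
    EmbeddingConfig,
    generate_synthetic_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but learnable cohort shared across tests (labels + embeddings)."""
    return generate_synthetic_cohort(
        CohortConfig(n_high_risk=60, n_control=60, seed=11),
        EmbeddingConfig(text_dim=32, audio_dim=16, segments_mean=6.0,
                        text_snr=6.0, audio_snr=0.2, seed=12),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
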