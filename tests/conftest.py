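import pytest
from hypothesis import settings

import m7gsub as m

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_benchmark():
    """A small motif-planted benchmark shared across tests (80+80 windows)."""
    spec = m.SyntheticSpec(
        n_transcripts=16,
        transcript_length=1500,
        n_positive_sites=80,
        motif="GxAG",
        noise_rate=0.1,
        seed=42,
    )
    return m.make_benchmark(spec, L=61)


@pytest.fixture
def toy_transcripts():
    """Two tiny transcripts with known G layouts."""
    return [
        m.RNASequence("tx1", "AAGAAGGAUGGCAG"),
        m.RNASequence("tx2", "GGGGAAAAGG"),
    ]
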