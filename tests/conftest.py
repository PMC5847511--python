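import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from sequonkit.proteome import ProteinRecord, ProteomeSet  # noqa: E402


@pytest.fixture
def tiny_proteome() -> ProteomeSet:
    """Three hand-built proteins covering viable/non-viable annotation."""
    proteome = ProteomeSet()
    proteome.add(
        ProteinRecord(
            accession="P00001",
            sequence="MNVSANPSNQTLLNNSS",
            signal_peptide=(1, 5),
            keywords=frozenset({"Membrane"}),
        )
    )
    proteome.add(
        ProteinRecord(
            accession="P00002",
            sequence="MKKLLNGTAAANGSA",
            keywords=frozenset({"Cytoplasm", "Nucleus"}),
        )
    )
    proteome.add(
        ProteinRecord(accession="P00003", sequence="MAAAAAAA")
    )
    return proteome


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
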