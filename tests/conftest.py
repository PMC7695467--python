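import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bindsel.weights import KmerWeightTable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def full_rescore_delta(anc: str, foc: str, table: KmerWeightTable) -> float:
    """Independent oracle: enumerate every window in both sequences."""
    k = table.k
    return math.fsum(
        table.weight(foc[i : i + k]) - table.weight(anc[i : i + k])
        for i in range(len(anc) - k + 1)
    )


@pytest.fixture(scope="session")
def k2_weights() -> dict[str, float]:
    rng = np.random.default_rng(12345)
    return {a + b: float(rng.normal()) for a in BASES for b in BASES}


@pytest.fixture(scope="session")
def k2_table(k2_weights) -> KmerWeightTable:
    return KmerWeightTable.from_mapping(k2_weights, k=2, source="test k=2")


@pytest.fixture(scope="session")
def k3_table() -> KmerWeightTable:
    rng = np.random.default_rng(99)
    w = {a + b + c: float(rng.normal()) for a in BASES for b in BASES for c in BASES}
    return KmerWeightTable.from_mapping(w, k=3, source="test k=3")
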