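import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# make the sibling oracle helpers importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

STOPS = {"TAA", "TAG", "TGA"}


def random_orf_bases(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA, a valid annotated CDS."""
    body = []
    while len(body) < n_codons:
        codon = "".join(rng.choice(list("ACGT"), 3))
        if codon not in STOPS:
            body.append(codon)
    return "ATG" + "".join(body) + "TAA"


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_920)


@pytest.fixture
def table1_params():
    from schwannoma.incidence import IncidenceModelParams

    return IncidenceModelParams()
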