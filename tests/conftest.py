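from __future__ import annotations

import numpy as np
import pytest

from divorph.io_formats import ProteinRecord, Provenance
from divorph.lg_data import AA_ORDER, LG_FREQS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng: np.random.Generator, length: int,
                   rec_id: str = "p", provenance=Provenance.REAL
                   ) -> ProteinRecord:
    aa = np.array(list(AA_ORDER))
    seq = "".join(aa[rng.choice(20, size=length, p=LG_FREQS)])
    return ProteinRecord(rec_id, seq, provenance)


@pytest.fixture
def make_protein():
    return random_protein
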