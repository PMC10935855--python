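import numpy as np
import pytest

from cladescan import PromoterRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def make_promoter():
    def _make(sequence, gene_id="g1", species_id="sp01", requested=None):
        return PromoterRecord(
            gene_id=gene_id,
            species_id=species_id,
            sequence=sequence.upper(),
            requested_length=len(sequence) if requested is None else requested,
            truncated=(requested is not None and len(sequence) < requested),
        )

    return _make
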