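import numpy as np
import pytest

from asmpatch.sequence_io import Origin, SeqRecord


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150)


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def contig(id_: str, seq: str) -> SeqRecord:
    return SeqRecord(id_, seq, Origin.contig)


def cpblr(id_: str, seq: str) -> SeqRecord:
    return SeqRecord(id_, seq, Origin.cpblr)
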