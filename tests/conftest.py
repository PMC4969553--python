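import numpy as np
import pytest

from nonbscan import SequenceRecord

BASES = np.array(list("ACGT"))


def random_record(seed: int, length: int | None = None, gc: float | None = None,
                  rec_id: str = "rand") -> SequenceRecord:
    """i.i.d. random sequence; length 100-500 and GC 0.2-0.8 unless given."""
    rng = np.random.default_rng(seed)
    if length is None:
        length = int(rng.integers(100, 501))
    if gc is None:
        gc = float(rng.uniform(0.2, 0.8))
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return SequenceRecord(rec_id, "".join(rng.choice(BASES, size=length, p=p)))


@pytest.fixture
def make_random_record():
    return random_record
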