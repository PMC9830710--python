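import numpy as np
import pytest

from refanchor import Assembly, SequenceRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def random_assembly(rng: np.random.Generator, n_records: int = 3,
                    length_range: tuple[int, int] = (50, 400),
                    with_n_runs: bool = False, name: str = "rand") -> Assembly:
    records = []
    for i in range(n_records):
        n = int(rng.integers(*length_range))
        seq = list(random_seq(rng, n))
        if with_n_runs and n > 20:
            for _ in range(int(rng.integers(0, 3))):
                start = int(rng.integers(0, n - 10))
                run = int(rng.integers(1, 10))
                seq[start : start + run] = "N" * run
        records.append(SequenceRecord(f"seq{i}", "".join(seq)))
    return Assembly(records, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
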