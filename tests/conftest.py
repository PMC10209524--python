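import pytest

from memfind.genome_io import SeqRecord
from memfind.synthetic import fixture_pair


@pytest.fixture(scope="session")
def chr_records():
    """Seven contiguously laid-out sequences with starts 0,4,7,13,17,27,32.

    The shortest (chr2) has length 3, so the generic predecessor builder
    can be exercised at step 3 and the power-of-two production step is 2.
    """
    starts = [0, 4, 7, 13, 17, 27, 32]
    lengths = [4, 3, 6, 4, 10, 5, 4]
    return (
        [SeqRecord(f"chr{i + 1}", s, ln) for i, (s, ln) in enumerate(zip(starts, lengths))],
        sum(lengths),  # 36
    )


@pytest.fixture(scope="session")
def mutated_pair():
    """10 kb three-sequence reference and a 1%-diverged near-copy."""
    return fixture_pair(seed=42, lengths=[6000, 2500, 1500], divergence=0.01)
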