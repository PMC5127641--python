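import numpy as np
import pytest

from specprofiler import ssm


def random_count_pair(seed: int, length: int = 6, depth: int = 5000):
    """A matched naive/sorted pool pair with arbitrary positive counts."""
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(ssm.AMINO_ACIDS, size=length))
    tables = []
    for label in ("naive", "sorted"):
        counts = ssm._empty_counts(length)
        counts.iloc[:, :] = rng.integers(0, 60, size=counts.shape)
        for pos, aa in enumerate(reference, start=1):
            counts.loc[pos, aa] = 0  # wild type lives in the shared tally
        tables.append(ssm.VariantCountTable(
            reference=reference, counts=counts, pool_label=label,
            wildtype_count=int(rng.integers(100, depth))))
    return tables[0], tables[1]


@pytest.fixture
def count_pair():
    return random_count_pair(seed=11)
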