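import numpy as np
import pytest

import hptkit as h


@pytest.fixture
def small_alignment():
    """Five-row gapped alignment with an H anchor at column 1."""
    rows = [
        h.AlignedSequence("s1", "AHGKLGS"),
        h.AlignedSequence("s2", "AH--GKL"),
        h.AlignedSequence("s3", "AHGKLGS"),
        h.AlignedSequence("s4", "CHGKLGT"),
        h.AlignedSequence("s5", "AQGKLGS"),
    ]
    return h.Alignment(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_rows(rng, n_rows, n_cols, gap_rate=0.15):
    """Random gapped rows over the 20-residue alphabet."""
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    probs = np.full(21, (1 - gap_rate) / 20)
    probs[-1] = gap_rate
    return [
        h.AlignedSequence(f"r{i}", "".join(rng.choice(aa, size=n_cols, p=probs)))
        for i in range(n_rows)
    ]
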