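import numpy as np
import pytest

from eurydelim import seqio, synthdata


def make_alignment(seqs, marker="COI", ids=None):
    ids = ids or [f"s{i+1}" for i in range(len(seqs))]
    recs = tuple(
        seqio.SequenceRecord(i, marker, s.upper()) for i, s in zip(ids, seqs)
    )
    return seqio.Alignment(recs, marker=marker)


def random_alignment(rng, n=6, length=50, marker="X"):
    bases = np.array(list("ACGT-N"))
    probs = [0.22, 0.22, 0.22, 0.22, 0.06, 0.06]
    seqs = [
        "".join(rng.choice(bases, size=length, p=probs)) for _ in range(n)
    ]
    return make_alignment(seqs, marker=marker)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def preset_dataset():
    """One paper-structure synthetic dataset shared across tests."""
    return synthdata.make_dataset(synthdata.paper_like_config(seed=1))
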