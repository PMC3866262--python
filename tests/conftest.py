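import numpy as np
import pytest

from motifcompare import Motif, MotifProfile, ColumnView


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_counts(rng, n_sites=10):
    """A random count 4-vector summing to n_sites, occasionally concentrated."""
    if rng.random() < 0.3:
        base = rng.integers(0, 4)
        counts = np.zeros(4, dtype=np.int64)
        counts[base] = n_sites
        # move a few counts off the dominant base
        for _ in range(rng.integers(0, 3)):
            other = rng.integers(0, 4)
            if counts[base] > 1:
                counts[base] -= 1
                counts[other] += 1
        return counts
    return rng.multinomial(n_sites, rng.dirichlet(np.ones(4)))


def random_motif(rng, length=None, n_sites=10, id="m"):
    length = int(length if length is not None else rng.integers(3, 9))
    counts = np.column_stack([random_counts(rng, n_sites) for _ in range(length)])
    return Motif(id=id, counts=counts)


def column_view(counts, pseudocount=1.0):
    """Build a ColumnView from a count 4-vector via a single-column motif."""
    m = Motif(id="col", counts=np.asarray(counts, dtype=np.int64)[:, None])
    return ColumnView.from_profile(MotifProfile.from_motif(m, pseudocount=pseudocount), 0)


@pytest.fixture
def random_motif_factory(rng):
    def make(**kw):
        return random_motif(rng, **kw)
    return make
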