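import numpy as np
import pytest

from mtgibbs.pedigree import from_records


@pytest.fixture
def trio():
    """Unrelated sire and dam with one offspring."""
    return from_records([("s", None, None), ("d", None, None), ("o", "s", "d")])


@pytest.fixture
def fullsib_mating():
    """Two founders, two full sibs, and an offspring of the sib mating."""
    return from_records(
        [
            ("A", None, None),
            ("B", None, None),
            ("C", "A", "B"),
            ("D", "A", "B"),
            ("E", "C", "D"),
        ]
    )


def random_pedigree(rng, n_founders=10, n_extra=50):
    """Random acyclic pedigree: each new animal mates two earlier ones."""
    recs = [(f"f{i}", None, None) for i in range(n_founders)]
    for i in range(n_extra):
        n = len(recs)
        s, d = rng.choice(n, size=2, replace=False)
        recs.append((f"x{i}", recs[s][0], recs[d][0]))
    return from_records(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
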