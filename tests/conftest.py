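import numpy as np
import pytest

from wssgblup.pedigree import UNKNOWN, Pedigree


@pytest.fixture
def trio():
    """Sire, dam (unrelated) and their offspring."""
    return Pedigree(np.array([1, 2, 3]), np.array([UNKNOWN, UNKNOWN, 0]),
                    np.array([UNKNOWN, UNKNOWN, 1]))


def random_pedigree(rng: np.random.Generator, n_founders: int = 10,
                    n_extra: int = 40) -> Pedigree:
    """Random valid pedigree: founders plus animals with parents drawn earlier."""
    sire = [UNKNOWN] * n_founders
    dam = [UNKNOWN] * n_founders
    for i in range(n_founders, n_founders + n_extra):
        s, d = rng.integers(0, i, size=2)
        if s == d:
            d = UNKNOWN
        sire.append(int(s))
        dam.append(int(d) if d != UNKNOWN else UNKNOWN)
    n = n_founders + n_extra
    return Pedigree(np.arange(1, n + 1), np.array(sire), np.array(dam))
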