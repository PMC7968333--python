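import numpy as np
import pandas as pd
import pytest

from reactnorm.kinship import Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(20210317)


@pytest.fixture
def trio_pedigree():
    """Sire, dam and one offspring."""
    return Pedigree(np.array([1, 2, 3]), np.array([-1, -1, 0]), np.array([-1, -1, 1]))


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and an offspring of the sib mating."""
    return Pedigree(
        np.array([1, 2, 3, 4, 5]),
        np.array([-1, -1, 0, 0, 2]),
        np.array([-1, -1, 1, 1, 3]),
    )


def _random_pedigree(rng, n, n_founders=8):
    sire, dam = [-1] * n_founders, [-1] * n_founders
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire.append(int(s))
        dam.append(int(d))
    return Pedigree(np.arange(1, n + 1), np.array(sire), np.array(dam))


@pytest.fixture
def make_pedigree(rng):
    """Factory for random multi-generation pedigrees."""

    def make(n, n_founders=8):
        return _random_pedigree(rng, n, n_founders)

    return make


@pytest.fixture
def hourly_day():
    """One complete day of hourly weather at constant temperatures."""

    def make(tdb, tdp, date="2013-07-01"):
        t = pd.date_range(date, periods=24, freq="h")
        return pd.DataFrame(
            {"time": t, "tdb_c": np.broadcast_to(tdb, 24).astype(float),
             "tdp_c": np.broadcast_to(tdp, 24).astype(float)}
        )

    return make
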