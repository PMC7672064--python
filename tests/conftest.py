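import numpy as np
import pytest

from orbitag import (
    LYSOZYME_CHICKEN,
    INSULIN_HUMAN,
    ProteinRecord,
    default_table,
    make_decoy_db,
)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def lysozyme():
    return ProteinRecord("LYSC_CHICK", "hen egg-white lysozyme", LYSOZYME_CHICKEN)


@pytest.fixture(scope="session")
def insulin():
    return ProteinRecord("INS_HUMAN", "human insulin B+A chains", INSULIN_HUMAN)


@pytest.fixture(scope="session")
def decoy_db(lysozyme, insulin):
    """100 random decoys plus the two real targets."""
    return make_decoy_db(100, seed=7) + [lysozyme, insulin]


def random_ladder_spectrum(rng, n_noise=10, ladder_len=5, mz0=400.0):
    """A planted residue ladder plus uniform noise peaks (test helper)."""
    from orbitag import Spectrum, Peak, default_table

    t = default_table()
    codes = sorted(t.items())
    mzs = [mz0]
    for _ in range(ladder_len):
        code, mass = codes[rng.integers(0, len(codes))]
        mzs.append(mzs[-1] + mass)
    mzs += list(rng.uniform(150, 2000, size=n_noise))
    return Spectrum(peaks=[Peak(m, 1.0) for m in mzs])
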