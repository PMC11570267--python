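import numpy as np
import pytest

import rhythmshift as rs

TPS6 = np.array([1.0, 5.0, 9.0, 13.0, 17.0, 21.0])
TPS48 = np.arange(0.0, 24.0, 0.5)


def lognormal_replicates(params, tps, cv, rng, n_rep=3):
    """Mean-preserving multiplicative lognormal replicates of a waveform.

    Written independently of the generator module so tests that feed the
    permutation machinery do not depend on it.
    """
    w = rs.make_waveform(params)(np.asarray(tps, dtype=float))
    out = []
    for mu in w:
        if cv == 0:
            out.append(np.full(n_rep, mu))
        else:
            sigma = np.sqrt(np.log1p(cv**2))
            out.append(mu * rng.lognormal(-sigma**2 / 2, sigma, n_rep))
    return out


@pytest.fixture
def tps6():
    return TPS6.copy()


@pytest.fixture
def tps48():
    return TPS48.copy()
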