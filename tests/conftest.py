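import numpy as np
import pytest


def sud_oracle(p, thresholds, lam):
    """Literal, loop-based transcription of the step-up-down definition.

    Kept deliberately naive (exhaustive search over candidate indices) so it
    can serve as an independent oracle for the vectorized engine.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(thresholds, dtype=float)
    m = p.size
    sp = np.sort(p)
    li = lam - 1
    istar = None
    if sp[li] <= a[li]:
        for j in range(li, m):
            if all(sp[i] <= a[i] for i in range(li, j + 1)):
                istar = j
    else:
        for j in range(li):
            if sp[j] <= a[j]:
                istar = j
    if istar is None:
        return np.zeros(m, dtype=bool)
    return p <= a[istar]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160225)
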