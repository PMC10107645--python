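import numpy as np
import pytest

from mplcox import (LikelihoodWorkspace, SubjectRecord, SurvDataset,
                    build_basis)


def mixed_dataset(n=48, seed=0, q=1):
    """Small deterministic dataset containing all four censoring types."""
    rng = np.random.default_rng(seed)
    subs = []
    for i in range(n):
        nseg = int(rng.integers(1, 4))
        ct = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 2.0, nseg - 1))])
        z = rng.normal(scale=0.8, size=(nseg, q)).round(2)
        x = np.array([rng.integers(0, 2), rng.uniform()], dtype=float)
        kind = i % 4
        if kind == 0:
            t = rng.uniform(0.2, 3.0)
            sub = SubjectRecord(yL=t, yR=t, censor_type="event", x=x,
                                change_times=ct, z_values=z)
        elif kind == 1:
            sub = SubjectRecord(yL=rng.uniform(0.2, 3.0), yR=np.inf,
                                censor_type="right", x=x,
                                change_times=ct, z_values=z)
        elif kind == 2:
            sub = SubjectRecord(yL=0.0, yR=rng.uniform(0.3, 3.0),
                                censor_type="left", x=x,
                                change_times=ct, z_values=z)
        else:
            lo = rng.uniform(0.2, 1.5)
            sub = SubjectRecord(yL=lo, yR=lo + rng.uniform(0.2, 1.5),
                                censor_type="interval", x=x,
                                change_times=ct, z_values=z)
        subs.append(sub)
    return SurvDataset(subjects=subs)


@pytest.fixture(scope="session")
def small_mixed():
    return mixed_dataset()


@pytest.fixture(scope="session")
def small_basis(small_mixed):
    return build_basis(small_mixed.observed_times(), small_mixed.n0,
                       m_override=6)


@pytest.fixture(scope="session")
def small_ws(small_mixed, small_basis):
    return LikelihoodWorkspace(small_mixed, small_basis)
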