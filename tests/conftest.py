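import numpy as np
import pytest

from camcr.mcr import ComponentRecord
from camcr.sweep import CList


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_clist(X: np.ndarray, n_bins: int = 4) -> CList:
    """Wrap a records × samples matrix as a CList with dummy spectra."""
    m, n = X.shape
    recs = [
        ComponentRecord(run_k=m, index_in_run=i + 1, concentration=X[i].copy(),
                        spectrum=np.ones(n_bins))
        for i in range(m)
    ]
    return CList(recs, n_samples=n, n_bins=n_bins)


@pytest.fixture()
def planted_clist(rng):
    """Three planted profile groups (8 members each) plus 4 noise records."""
    n = 20
    base = rng.uniform(0.2, 1.0, size=(3, n))
    rows, labels = [], []
    for g in range(3):
        for _ in range(8):
            rows.append(np.clip(base[g] + rng.normal(0, 0.03, n), 0, None))
            labels.append(g)
    for _ in range(4):
        rows.append(rng.uniform(0, 1, n))
        labels.append(-1)
    return make_clist(np.vstack(rows)), np.array(labels)
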