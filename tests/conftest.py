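import numpy as np
import pytest

from pcn import ROITimeSeries, pearson_bfn


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_scan(rng):
    """A 40 x 10 Gaussian scan."""
    return ROITimeSeries(values=rng.standard_normal((40, 10)), scan_id="small")


@pytest.fixture
def adni_shaped_scan(rng):
    """A scan with the 137 x 116 shape of the ADNI-style cohort."""
    return ROITimeSeries(values=rng.standard_normal((137, 116)), scan_id="adni-like")


def sign_matrix(s):
    """Rank-one sign matrix s s^T as a validated AdjacencyMatrix."""
    from pcn import AdjacencyMatrix

    s = np.asarray(s, dtype=float)
    return AdjacencyMatrix(values=np.outer(s, s), order=1)


def sign_template_scan(s, rng, m=30):
    """Signals that are sign-flipped copies of one template: R_1 = s s^T."""
    template = rng.standard_normal(m)
    X = np.outer(template, np.asarray(s, dtype=float))
    return ROITimeSeries(values=X, scan_id="template")


def pearson_oracle(x, y):
    """Scalar Pearson coefficient computed directly from its definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def rowwise_pearson_oracle(A):
    """Double-loop Pearson correlation of the rows of A."""
    n = A.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pearson_oracle(A[i], A[j])
    return out
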