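import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import gammaln

from microlda.io_preprocess import OtuCountTable, TaxonomyMap

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_table() -> OtuCountTable:
    values = np.array(
        [[2.0, 2.0, 4.0, 0.0], [1.0, 0.0, 3.0, 6.0], [5.0, 5.0, 0.0, 0.0]]
    )
    return OtuCountTable(["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"], values)


@pytest.fixture
def taxmap() -> TaxonomyMap:
    return TaxonomyMap({"o1": "g1", "o2": "g1", "o3": "g2", "o4": "NA"})


def enumerate_lda_posterior(counts: np.ndarray, K: int, alpha: float, beta: float):
    """Exact LDA posterior means by exhaustive enumeration of assignments.

    Brute-force oracle for tiny corpora: sums the collapsed joint
    p(z, w) over all K^N subgroup-assignment configurations and returns
    the posterior means of the smoothed theta and phi estimators.
    Independent of the Gibbs implementation.
    """
    counts = np.asarray(counts)
    n_docs, V = counts.shape
    doc = np.repeat(np.arange(n_docs), counts.sum(axis=1))
    word = np.concatenate(
        [np.repeat(np.arange(V), counts[d]) for d in range(n_docs)]
    )
    N = len(doc)
    Nd = counts.sum(axis=1)
    log_ws, theta_list, phi_list = [], [], []
    for z in itertools.product(range(K), repeat=N):
        z = np.array(z)
        ndk = np.zeros((n_docs, K))
        nkw = np.zeros((K, V))
        for t in range(N):
            ndk[doc[t], z[t]] += 1
            nkw[z[t], word[t]] += 1
        mk = nkw.sum(axis=1)
        log_ws.append(
            gammaln(ndk + alpha).sum()
            + gammaln(nkw + beta).sum()
            - gammaln(mk + V * beta).sum()
        )
        theta_list.append((ndk + alpha) / (Nd[:, None] + K * alpha))
        phi_list.append((nkw + beta) / (mk[:, None] + V * beta))
    log_ws = np.array(log_ws)
    w = np.exp(log_ws - log_ws.max())
    w /= w.sum()
    theta = np.tensordot(w, np.array(theta_list), axes=1)
    phi = np.tensordot(w, np.array(phi_list), axes=1)
    return theta, phi
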