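import numpy as np
import pytest
from scipy import stats

from telegraphkit import GeneModelSpec


@pytest.fixture(scope="session")
def tnf_spec():
    """One-step model at the fitted TNF-alpha rates (min^-1)."""
    return GeneModelSpec("one_step", k_on=0.02, k_off=0.12, k_t=16.8,
                         k_d=0.014, M=2000)


@pytest.fixture(scope="session")
def small_spec():
    """Small one-step model for fast transient tests."""
    return GeneModelSpec("one_step", k_on=0.05, k_off=0.15, k_t=4.0,
                         k_d=0.02, M=400)


@pytest.fixture(scope="session")
def two_step_spec():
    """Two-step permissive model with a slow, leaky first step."""
    return GeneModelSpec("two_step_permissive", k_on=0.09, k_off=0.12,
                         k_t=5.0, k_d=0.01, t_on=0.008, t_off=0.08,
                         k_0=1.0, M=600)


def discrete_ks_pvalue(sample, marginal):
    """Two-sided KS p-value of an integer sample against a pmf over 0..L-1.

    The supremum CDF gap is taken over the integer support (the correct
    statistic for distributions with atoms — `ks_1samp` assumes ties
    never happen); the asymptotic Kolmogorov p-value is conservative for
    discrete data, the safe direction for an agreement test.
    """
    sample = np.asarray(sample)
    marginal = np.asarray(marginal, dtype=float)
    L = max(marginal.size, int(sample.max()) + 1)
    F = np.ones(L)
    F[:marginal.size] = np.minimum(np.cumsum(marginal), 1.0)
    ecdf = np.cumsum(np.bincount(sample, minlength=L)) / sample.size
    D = np.abs(ecdf - F).max()
    return stats.kstwobign.sf(np.sqrt(sample.size) * D)
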