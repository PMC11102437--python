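import numpy as np
import pytest

import sdmd


@pytest.fixture(scope="session")
def demo_signal():
    """The two-component worked example (81 channels x 500 samples, 1 kHz)."""
    return sdmd.make_two_component_signal()


@pytest.fixture(scope="session")
def demo_dmd(demo_signal):
    """Rank-4 stacked exact DMD of the worked example."""
    return sdmd.exact_dmd(demo_signal, rank=4)


@pytest.fixture(scope="session")
def small_trialset():
    """Small 3-class separable trial set used by the decoding tests."""
    spec = sdmd.TrialSetSpec(n_classes=3, trials_per_class=12, n_channels=8,
                             n_samples=160, seed=3)
    return sdmd.make_trial_set(spec)


@pytest.fixture(scope="session")
def small_scheme():
    return sdmd.CVScheme(n_outer=3, outer_repeats=1, n_inner=2,
                         inner_repeats=1, seed=0)


def random_conjugate_modes(rng, n_channels, n_pairs, n_real=0):
    """Unit-norm conjugate-closed mode matrix (P, 2*n_pairs + n_real)."""
    cols = []
    for _ in range(n_pairs):
        v = rng.normal(size=n_channels) + 1j * rng.normal(size=n_channels)
        v /= np.linalg.norm(v)
        cols += [v, v.conj()]
    for _ in range(n_real):
        v = rng.normal(size=n_channels).astype(complex)
        v /= np.linalg.norm(v)
        cols.append(v)
    return np.column_stack(cols)
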