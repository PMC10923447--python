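import numpy as np
import pytest

from grstrat.simulate import ClusterSpec, CohortSpec, SimulationConfig, VariantSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_config(seed=0, mode="planted", n_healthy=200, n_case=200,
                variants=None, clusters=None, cohorts=None, missing_rate=0.0):
    """Small simulation config for tests."""
    if variants is None:
        variants = [
            VariantSpec(rsid=f"rs{i}", gene=f"G{i % 4}", freq=f, chrom="1",
                        pos=1000 + i)
            for i, f in enumerate([0.1, 0.2, 0.3, 0.4, 0.5, 0.25, 0.35, 0.45,
                                   0.15, 0.3, 0.2, 0.4])
        ]
    if clusters is None:
        clusters = [
            ClusterSpec("A", 0.25, onset_mean=55, onset_sd=8, fev1_mean=95,
                        fev1_sd=10, grs_delta=1.0),
            ClusterSpec("B", 0.25, onset_mean=50, onset_sd=8, fev1_mean=55,
                        fev1_sd=8, grs_delta=0.0),
            ClusterSpec("C", 0.25, onset_mean=8, onset_sd=5, fev1_mean=80,
                        fev1_sd=10, grs_delta=0.0),
            ClusterSpec("D", 0.25, onset_mean=60, onset_sd=8, fev1_mean=98,
                        fev1_sd=10, grs_delta=-1.0),
        ]
    if cohorts is None:
        cohorts = [CohortSpec("test", n_healthy, n_case)]
    return SimulationConfig(seed=seed, cohorts=cohorts, variants=variants,
                            clusters=clusters, mode=mode,
                            missing_rate=missing_rate)


@pytest.fixture
def small_config():
    return make_config()


def gaussian_blobs(rng, k, n_per, sep=6.0, p=3):
    """k well-separated spherical components; returns (X, truth labels)."""
    means = np.zeros((k, p))
    for i in range(k):
        means[i, i % p] = sep * (1 + i // p)
    X = np.vstack([rng.normal(m, 1.0, size=(n_per, p)) for m in means])
    truth = np.repeat(np.arange(k), n_per)
    return X, truth
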