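import numpy as np
import pytest

from tfcoherence import (
    ModelHyperparams,
    SimulationConfig,
    fit_tf_activities,
    simulate_dataset,
)

STANDARD_FIXTURE = dict(n_genes=500, seed=7)  # density 0.05, noise_sd 0.1 defaults


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard synthetic fixture: 500 genes, 16 TFs (8 coherent / 8
    divergent), 5 time points, density 0.05, noise SD 0.1, seed 7."""
    return simulate_dataset(SimulationConfig(**STANDARD_FIXTURE))


@pytest.fixture(scope="session")
def fitted_posteriors(standard_dataset):
    """Both conditions of the standard fixture fitted with default hyperparameters."""
    ds = standard_dataset
    post_a = fit_tf_activities(ds.expression_a, ds.connectivity, ModelHyperparams())
    post_b = fit_tf_activities(ds.expression_b, ds.connectivity, ModelHyperparams())
    return post_a, post_b


def pearson_by_sums(a, b):
    """Definitional-sums Pearson correlation, independent of numpy.corrcoef."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    n = len(a)
    sa, sb = sum(a), sum(b)
    saa = sum(v * v for v in a)
    sbb = sum(v * v for v in b)
    sab = sum(u * v for u, v in zip(a, b))
    num = n * sab - sa * sb
    den = ((n * saa - sa * sa) * (n * sbb - sb * sb)) ** 0.5
    return num / den
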