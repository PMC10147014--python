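import numpy as np
import pandas as pd
import pytest

from aminofrail import (
    generate_cohort,
    lloq_filter,
    replica_config,
    substitute_censored,
)


@pytest.fixture(scope="session")
def replica_cohort():
    return generate_cohort(replica_config(seed=1))


@pytest.fixture(scope="session")
def replica_matrix(replica_cohort):
    panel = lloq_filter(replica_cohort)
    X = substitute_censored(replica_cohort, panel)
    return X, replica_cohort.class_labels


def two_class_blobs(n_per_class=20, n_vars=4, effect=3.0, log_sd=0.35,
                    seed=0):
    """Two log-normal classes separated by ``effect`` log-units on the first
    two variables; returns (X DataFrame, labels Series)."""
    rng = np.random.default_rng(seed)
    shift = np.zeros(n_vars)
    shift[:2] = effect
    base = np.log(50.0)
    a = np.exp(base + log_sd * rng.standard_normal((n_per_class, n_vars)))
    b = np.exp(base + shift + log_sd * rng.standard_normal((n_per_class, n_vars)))
    X = pd.DataFrame(np.vstack([a, b]),
                     columns=[f"v{j}" for j in range(n_vars)])
    labels = pd.Series(["A"] * n_per_class + ["B"] * n_per_class)
    return X, labels


def noise_classes(n_per_class=12, n_vars=4, n_classes=2, seed=0):
    """Pure-noise classes: identical distributions, labels carry no signal."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    X = pd.DataFrame(rng.standard_normal((n, n_vars)),
                     columns=[f"v{j}" for j in range(n_vars)])
    labels = pd.Series(
        [chr(ord("A") + j) for j in range(n_classes) for _ in range(n_per_class)]
    )
    return X, labels
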