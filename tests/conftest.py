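import numpy as np
import pytest

from oximask import (
    LabeledFeatureSet,
    default_class_models,
    reference_models,
    validation_class_models,
)


@pytest.fixture(scope="session")
def cons_models():
    """Construction-cohort class models (the calibrated defaults)."""
    return default_class_models()


@pytest.fixture(scope="session")
def val_models():
    """Validation-stage class models (tighter spreads)."""
    return validation_class_models()


@pytest.fixture(scope="session")
def ref_lines():
    """(blood_line, coating_line) — the published boundaries."""
    return reference_models()


def gaussian_two_class(
    n_pos, n_neg, mu_pos, mu_neg, cov, seed, pos="blood", neg="reddish_tumor"
) -> LabeledFeatureSet:
    """Shared-covariance Gaussian two-class sample in feature space."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(np.asarray(cov, dtype=float))
    z_pos = np.asarray(mu_pos) + rng.standard_normal((n_pos, 2)) @ chol.T
    z_neg = np.asarray(mu_neg) + rng.standard_normal((n_neg, 2)) @ chol.T
    return LabeledFeatureSet(
        points=np.vstack([z_pos, z_neg]),
        labels=np.array([pos] * n_pos + [neg] * n_neg, dtype=object),
    )
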