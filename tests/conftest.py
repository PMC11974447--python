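import numpy as np
import pytest

from tractofov.experiments import desk_model_params, separable_two_bundle_tractogram
from tractofov.synthetic import BundleSpec, CohortConfig, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_subject():
    """2 bundles x 50 streamlines + 10 outliers, one bundle inferior."""
    bundles = [
        BundleSpec("upper", np.array([(-20.0, 0.0, 10.0), (20.0, 0.0, 40.0)]),
                   50, radial_sd=1.5, along_jitter=0.3),
        BundleSpec("deep", np.array([(0.0, -10.0, 30.0), (0.0, -14.0, -70.0)]),
                   50, radial_sd=1.5, along_jitter=0.3, inferior=True),
    ]
    cfg = CohortConfig(n_subjects=1, bundles=bundles, n_outliers=10, seed=7,
                       points_per_streamline=15)
    return generate_subject(cfg, 0)


@pytest.fixture(scope="session")
def separable_tractogram():
    return separable_two_bundle_tractogram(seed=0)


@pytest.fixture(scope="session")
def fitted_separable_model(separable_tractogram):
    """One small model fitted on the separable benchmark, reused across tests."""
    import warnings

    from tractofov.model import TractographyParcellator

    est = TractographyParcellator(
        random_state=0, **desk_model_params(epochs=8)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(separable_tractogram)
    return est


def random_polyline(rng, n_points=None, scale=30.0):
    n = n_points or rng.integers(3, 12)
    return np.cumsum(rng.normal(0, scale / n, size=(n, 3)), axis=0)
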