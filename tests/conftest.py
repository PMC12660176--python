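import numpy as np
import pytest

from quantalmap import simulate


@pytest.fixture(scope="session")
def small_gt() -> simulate.GroundTruth:
    """Two boutons, ten AZs: enough structure for every downstream stage."""
    return simulate.make_geometry(2, 5, seed=3)


@pytest.fixture()
def two_spot_gt() -> simulate.GroundTruth:
    """Hand-built geometry: two well-separated AZs on a 64x64 field."""
    az = np.array([[2.0, 2.0], [6.0, 6.0]])
    return simulate.GroundTruth(
        az_centroids=az, psd_centroids=az.copy(),
        true_pr=np.array([0.5, 0.5]),
        true_spont_rate=np.array([1.0, 1.0]),
        age_days=np.array([1.0, 4.0]),
        cac_positive=np.array([True, True]),
        bouton_index=np.array([0, 0]),
        pixel_size=0.133, field_shape=(64, 64), seed=0)
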