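import numpy as np
import pytest

import tractokit as tk
from tractokit.tensor import filter_negative_eigenvalues, scalar_map


@pytest.fixture(scope="session")
def straight_phantom():
    """Straight-bundle tensor phantom, filtered, with its FA map."""
    spec = tk.PhantomSpec(shape=(32, 24, 24))
    tv = filter_negative_eigenvalues(tk.make_tensor_phantom(spec))
    return spec, tv, scalar_map(tv, "fa")


@pytest.fixture(scope="session")
def arc_phantom():
    spec = tk.PhantomSpec(shape=(32, 32, 16), bundle_geometry="arc")
    tv = filter_negative_eigenvalues(tk.make_tensor_phantom(spec))
    return spec, tv


@pytest.fixture(scope="session")
def gradient_table():
    return tk.default_gradient_table(n_directions=12)


@pytest.fixture(scope="session")
def textured_dwi(gradient_table):
    """Noisy DWI of a small phantom with structured S0 (QC test subject)."""
    from tractokit.synthetic import textured_s0
    spec = tk.PhantomSpec(shape=(16, 16, 16))
    tv = tk.make_tensor_phantom(spec)
    s0 = textured_s0((16, 16, 16), seed=7)
    return tk.simulate_dwi(tv, gradient_table, s0=s0, noise_sd=10.0, seed=1)


@pytest.fixture(scope="session")
def tracked_bundle(straight_phantom):
    """Bundle tracked from a small central label on the straight phantom."""
    _, tv, fa = straight_phantom
    labels = np.zeros(tv.shape, dtype=np.int32)
    labels[16, 10:14, 10:14] = 1
    lab = tk.LabelVolume(labels, **tv.spatial_kwargs())
    params = tk.TrackingParams()
    seeds = tk.seeds_from_labelmap(lab, 1, fa, params)
    return tk.track(tv, seeds, params)


@pytest.fixture()
def two_fiber_bundle():
    return tk.FiberBundle(
        [np.array([[0.0, 0, 0], [10, 0, 0], [20, 0, 0]]),
         np.array([[0.0, 5, 0], [10, 5, 0], [20, 5, 0]])],
        {"FA": [np.array([0.3, 0.5, 0.4]), np.array([0.6, 0.7, 0.2])]})
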