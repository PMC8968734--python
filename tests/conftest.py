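import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from csvmtk import (PhantomSpec, RegParams, csvm_segment, make_brain_phantom,
                    make_motion_series, overall_accuracy,
                    register_time_series)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """The benchmark phantom: 2% noise, 30% bias field, seed 7."""
    return make_brain_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return make_brain_phantom(
        PhantomSpec(noise_fraction=0.0, bias_fraction=0.0, seed=7))


@pytest.fixture(scope="session")
def benchmark_segmentation(default_phantom):
    """Full C-SVM pipeline on the benchmark phantom (in-brain metrics)."""
    result = csvm_segment(default_phantom, n_train=1500, seed=7)
    metrics = overall_accuracy(result.labels, default_phantom.labels,
                               region_mask=default_phantom.labels > 0)
    return {"result": result, "metrics": metrics}


@pytest.fixture(scope="session")
def motion_base():
    """Noiseless (but bias-field) phantom used as the registration base."""
    return make_brain_phantom(PhantomSpec(noise_fraction=0.0, seed=7))


@pytest.fixture(scope="session")
def registered_noiseless(motion_base):
    series = make_motion_series(motion_base, 20, max_shift_px=3.0,
                                max_rot_deg=2.0, seed=11)
    result = register_time_series(series, RegParams(seed=11),
                                  compute_diagnostics=False)
    return {"series": series, "result": result}


@pytest.fixture(scope="session")
def registered_noisy(motion_base):
    series = make_motion_series(motion_base, 20, max_shift_px=3.0,
                                max_rot_deg=2.0, noise_fraction=0.02, seed=11)
    result = register_time_series(series, RegParams(seed=11),
                                  compute_diagnostics=False)
    return {"series": series, "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
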