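import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20120216)


@pytest.fixture
def small_truth():
    """A reduced planted-truth configuration shared by pipeline-level tests."""
    from regulonkit.synthetic import default_truth

    return default_truth(
        7,
        n_probesets=120,
        n_experiments=6,
        n_correlated=4,
        n_arrays=16,
        n_modules=2,
    )


@pytest.fixture
def merged_small(small_truth):
    from regulonkit.normalize import median_center, merge_and_scale
    from regulonkit.screen import GuideConfig, screen_experiment, select_experiments
    from regulonkit.synthetic import gen_experiment_collection

    _, matrices, _ = gen_experiment_collection(small_truth)
    records = [screen_experiment(m, GuideConfig()) for m in matrices]
    selected = set(select_experiments([r for r in records if r]))
    return merge_and_scale(
        [median_center(m) for m in matrices if m.experiment_id in selected]
    )
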