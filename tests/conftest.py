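import numpy as np
import pytest

import videopulse as vp
from videopulse.benchmark import (
    evaluate_model,
    make_benchmark,
    train_desk_model,
    desk_model_config,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_clip():
    """One default-condition synthetic clip with its reference pulse."""
    return vp.render_video(vp.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def clean_clip():
    """A corruption-free clip: pulse modulation only."""
    cfg = vp.SyntheticConfig(seed=7, noise_sd=0.0, jitter_px=0.0, drift_amplitude=0.0)
    return vp.render_video(cfg)


@pytest.fixture(scope="session")
def desk_benchmark():
    """The shared desk-scale corpus: 24 training and 12 held-out windows."""
    return make_benchmark(seed=0)


@pytest.fixture(scope="session")
def trained_variants(desk_benchmark):
    """All four network variants trained on the shared benchmark, 3 seeds each.

    Also evaluates an untrained (freshly initialized) model per seed as the
    no-learning control.  This is the package's end-to-end parameter-recovery
    and ablation experiment; it dominates the suite's runtime.
    """
    train, test = desk_benchmark
    seeds = (0, 1, 2)
    out = {}
    for variant in ("fm-fcn", "fcn-can", "fm-can", "can"):
        for seed in seeds:
            net, history = train_desk_model(variant, train, seed=seed)
            out[(variant, seed)] = {
                "results": evaluate_model(net, test),
                "history": history,
            }
    for seed in seeds:
        untrained = vp.build_model(desk_model_config("fm-fcn", seed=seed))
        out[("untrained", seed)] = {"results": evaluate_model(untrained, test),
                                    "history": []}
    return out
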