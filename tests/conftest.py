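import warnings

import numpy as np
import pytest

import sharedmap as sm


@pytest.fixture(scope="session")
def spain_graph():
    return sm.make_graph("spain")


@pytest.fixture(scope="session")
def small_graph():
    return sm.make_graph("grid", m=3)


@pytest.fixture(scope="session")
def small_data(small_graph):
    """Fast 9-area synthetic dataset with its generating truth."""
    return sm.simulate_dataset(seed=42, graph=small_graph, paper_scale=False)


@pytest.fixture(scope="session")
def small_fit(small_data, small_graph):
    data, _ = small_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.fit(data, sm.ModelSpec.selected(), sm.PriorConfig(), small_graph,
                      chains=2, iters=400, warmup=400, seed=99)


def make_samples(spec, draws, **meta):
    """Hand-built PosteriorSamples for derived-quantity tests."""
    base_meta = {"fix_delta": None, "chains": 1}
    base_meta.update(meta)
    return sm.PosteriorSamples(draws=draws, spec=spec, priors=sm.PriorConfig(),
                               meta=base_meta)
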