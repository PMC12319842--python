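import numpy as np
import pytest

import atlasforge as af
from atlasforge.pipeline import run_full_pipeline


@pytest.fixture(scope="session")
def bundle():
    """Standard phantom bundle shared by the whole suite."""
    return af.make_phantom(af.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_meta():
    return af.GridMeta((25.0, 25.0, 25.0))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    """One full alignment run on the standard phantom, reused by every test
    that inspects pipeline behaviour (the run itself is deterministic)."""
    return run_full_pipeline(bundle.nissl, bundle.ann_v2, bundle.template,
                             bundle.ann_v3, bundle.graph,
                             lobule_ids=bundle.lobule_ids,
                             fiducials=bundle.fiducials)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
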