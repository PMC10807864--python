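import numpy as np
import pandas as pd
import pytest

import distwm


@pytest.fixture(scope="session")
def reference_params():
    return distwm.ModelParams()


@pytest.fixture(scope="session")
def toy():
    """Deterministic two-area instance shared by exact tests."""
    atlas, d = distwm.toy_two_area_fixture()
    return atlas, d["W_raw"], d["connectome"]


@pytest.fixture(scope="session")
def small_connectome():
    """12-area synthetic connectome, fixed seed, used by network tests."""
    spec = distwm.FixtureSpec(n_areas=12, seed=7)
    return distwm.synthetic_connectome(spec)


@pytest.fixture(scope="session")
def default_connectome():
    """Full-size (43-area) synthetic connectome at the default spec."""
    spec = distwm.FixtureSpec(seed=1)
    return distwm.synthetic_connectome(spec)


def make_connectome(W, PV, h, atlas_names=None):
    """Hand-assembled Connectome bypassing the pipeline (for designed nets).

    W is used as the final simulation matrix; the CIB split uses the given
    hierarchy. Useful when a test needs full control of PV/h/W values.
    """
    from distwm.connectome import Connectome, cib_matrix, split_by_target

    W = np.asarray(W, float)
    n = W.shape[0]
    names = atlas_names or [f"N{i}" for i in range(n)]
    table = pd.DataFrame({
        "name": names,
        "volume_mm3": 1.0,
        "neuron_density": 1.0,
        "pv_density": np.asarray(PV, float),
        "hierarchy_raw": np.asarray(h, float),
        "module": "synthetic",
        "is_thalamic": False,
    })
    atlas = distwm.AreaAtlas(table)
    m = cib_matrix(np.asarray(h, float))
    W_E, W_I = split_by_target(W, m)
    return Connectome(atlas=atlas, W_raw=W, W_norm=W, W=W,
                      h=np.asarray(h, float), PV=np.asarray(PV, float),
                      m=m, W_E=W_E, W_I=W_I)
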