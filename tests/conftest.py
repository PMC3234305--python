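import numpy as np
import pytest

from qfish.clustering import cluster_spectra
from qfish.signal import GridConfig
from qfish.synth import SimConfig, emit_spectra, make_templates

# compact grid keeping simulations fast while leaving plenty of windows
SMALL_GRID = GridConfig(mz_min=600.0, mz_max=1200.0, bin_width=0.1,
                        window_k=30, kernel="gaussian")


@pytest.fixture(scope="session")
def small_grid() -> GridConfig:
    return SMALL_GRID


@pytest.fixture(scope="session")
def default_sim(small_grid):
    """One synthetic study at default noise, clustered once and shared."""
    cfg = SimConfig(n_templates=12, seed=42)
    templates = make_templates(cfg, small_grid)
    spectra, truth = emit_spectra(templates, cfg)
    clusters = cluster_spectra(spectra, grid=small_grid)
    return {
        "config": cfg,
        "templates": templates,
        "spectra": spectra,
        "truth": truth,
        "clusters": clusters,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
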