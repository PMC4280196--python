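import numpy as np
import pytest

from hypernitro import (
    SceneConfig,
    SpectraTable,
    extract_spectra_table,
    generate_scene,
    trim_bands,
)


@pytest.fixture(scope="session")
def small_scene():
    """A tiny but complete cohort: 6 leaf / 6 stem / 4 root samples."""
    cfg = SceneConfig(rng_seed=42, n_leaf=6, n_stem=6, n_root=4,
                      image_shape=(12, 10))
    return cfg, generate_scene(cfg)


@pytest.fixture(scope="session")
def small_table(small_scene):
    _, samples = small_scene
    return trim_bands(extract_spectra_table(samples), 420, 1000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_table(rng, n=8, p=5):
    """Small random spectra table for oracle comparisons."""
    X = rng.uniform(0.1, 0.9, size=(n, p))
    y = rng.uniform(0.5, 5.0, size=n)
    wl = np.linspace(500, 900, p)
    return SpectraTable(X=X, y=y, wavelengths=wl)
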