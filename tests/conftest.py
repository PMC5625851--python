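import numpy as np
import pytest

import grainspec as gs


def small_scene_config(seed: int = 0, **kwargs) -> gs.SceneConfig:
    """A fast, fully featured scene: fewer bands and kernels, same physics."""
    cfg = gs.SceneConfig(n_batches=1, kernels_per_batch=4, seed=seed, **kwargs)
    cfg.optics.n_bands = 64
    return cfg


def quiet(cfg: gs.SceneConfig) -> gs.SceneConfig:
    """Disable every stochastic artifact (noise, scatter, spikes)."""
    cfg.optics.noise_sd = 0.0
    cfg.optics.scatter_mult_range = 0.0
    cfg.optics.scatter_add_range = 0.0
    cfg.optics.spike_rate = 0.0
    return cfg


@pytest.fixture(scope="session")
def default_grid() -> gs.WavelengthGrid:
    return gs.SceneConfig().optics.wavelength_grid()


@pytest.fixture(scope="session")
def rendered_quiet_scene():
    """Noise-free rendered scene shared by round-trip style tests."""
    cfg = quiet(small_scene_config(seed=11))
    truth = gs.sample_kernel_population(cfg)
    cube, refs, truth = gs.render_scene(truth, cfg)
    return cfg, truth, cube, refs


@pytest.fixture(scope="session")
def rendered_noisy_scene():
    """Default-physics rendered scene (noise, scatter, spikes on)."""
    cfg = small_scene_config(seed=23)
    cfg.optics.spike_rate = 2e-5  # enough planted spikes in a small cube
    truth = gs.sample_kernel_population(cfg)
    cube, refs, truth = gs.render_scene(truth, cfg)
    return cfg, truth, cube, refs


@pytest.fixture(scope="session")
def calibration_table():
    """Calibration-scale spectra table (fast path), shared by PLS tests."""
    cfg = gs.SceneConfig(n_batches=12, kernels_per_batch=10, seed=5)
    cfg.optics.n_bands = 128
    table, truth = gs.simulate_spectra_table(cfg)
    return cfg, table, truth


def absorbance_of(cube, refs):
    refl = gs.compute_reflectance(cube, refs)
    absorb, _ = gs.to_absorbance(refl)
    return absorb
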