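import numpy as np
import pytest

from paoxi.core import build_reference_spectra, default_grid
from paoxi.oximetry import UnmixConfig
from paoxi.phantom import PhantomConfig, attenuation_model, generate_study


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def ref(grid):
    return build_reference_spectra(grid)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return PhantomConfig(noise_rel_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_cfg):
    """Small noiseless study: 3 subjects, known venous trajectories."""
    return generate_study(n_subjects=3, per_subject_counts=(4, 3, 5),
                          cfg=noiseless_cfg, seed=42)


@pytest.fixture(scope="session")
def matched_unmix_cfg(noiseless_cfg, ref):
    return UnmixConfig(ref=ref, compensation=attenuation_model(noiseless_cfg))


@pytest.fixture(scope="session")
def small_study():
    """Tiny noisy study at reduced resolution for fast network tests."""
    cfg = PhantomConfig(image_h=32, image_w=48, sss_depth_mm=6.0,
                        sss_depth_jitter_mm=1.0, skin_band_depth_px=2,
                        curvature_rise_mm=2.0)
    return generate_study(n_subjects=3, per_subject_counts=(4, 4, 4),
                          cfg=cfg, seed=5)


def rng(seed=0):
    return np.random.default_rng(seed)
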