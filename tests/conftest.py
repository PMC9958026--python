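import numpy as np
import pytest

from ramanformer import preprocessing as pp
from ramanformer import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_axis():
    """Short grid (L=320) for fast model-shape tests."""
    return np.arange(400.0, 720.0)


@pytest.fixture(scope="session")
def separable_2class():
    """Two classes with disjoint discriminative peaks, preprocessed.

    Small (120 spectra, L=701) but realistic: Lorentzian peaks, fluorescence
    baseline, detector noise, occasional cosmic rays.
    """
    axis = sd.default_axis(400, 1800, 2.0)
    profiles = (
        sd.ClassProfile("a", ((600.0, 8.0, 1.5), (1004.0, 8.0, 1.0))),
        sd.ClassProfile("b", ((1400.0, 8.0, 1.5), (1004.0, 8.0, 1.0))),
    )
    cfg = sd.GeneratorConfig(n_classes=2, n_per_class=60, axis=axis, seed=7,
                             class_profiles=profiles)
    raw, truths = sd.generate_dataset(cfg)
    clean = pp.preprocess(raw)
    return {"axis": axis, "raw": raw, "clean": clean, "truths": truths, "cfg": cfg}


@pytest.fixture(scope="session")
def noise_free_truth_set():
    """Spike- and noise-free spectra (Lorentzian peaks + polynomial baseline)."""
    axis = sd.default_axis(step=2.0)
    noise = sd.NoiseModel(gaussian_sigma=0.0, cosmic_ray_rate=0.0)
    cfg = sd.GeneratorConfig(n_classes=2, n_per_class=5, axis=axis, seed=11,
                             noise=noise, amplitude_jitter=0.0)
    sset, truths = sd.generate_dataset(cfg)
    return {"axis": axis, "set": sset, "truths": truths}
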