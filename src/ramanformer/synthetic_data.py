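"""Synthetic single-cell Raman spectra with stored ground truth.

Emulates an 8-strain microbial Raman dataset: every class shares the three
carotenoid bands (1004, 1157, 1520 cm⁻¹) common to pigmented bacteria and
additionally carries a handful of class-specific vibrational peaks.  Each
rendered spectrum is

    clean Lorentzian peak sum × per-spectrum amplitude jitter
    + smooth random polynomial fluorescence baseline
    + white Gaussian detector noise
    + Poisson-count cosmic-ray spikes

and the generator records every component separately so preprocessing and
classification can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "ClassProfile",
    "NoiseModel",
    "GeneratorConfig",
    "SpectrumTruth",
    "CAROTENOID_BANDS",
    "default_axis",
    "make_default_profiles",
    "render_spectrum",
    "generate_dataset",
]

#: Carotenoid C=C stretching bands common to pigmented microorganisms (cm⁻¹).
CAROTENOID_BANDS = (1004.0, 1157.0, 1520.0)

#: Candidate class-discriminating band positions (cm⁻¹).  Includes the
#: 540/1380 cm⁻¹ bands that differ between Gram types, plus common protein /
#: nucleic-acid / lipid bands spread over the fingerprint and CH regions.
_DISCRIMINATIVE_BANDS = (
    540.0, 620.0, 720.0, 785.0, 850.0, 935.0, 1060.0, 1095.0,
    1230.0, 1310.0, 1380.0, 1440.0, 1580.0, 1660.0, 1740.0,
    2850.0, 2930.0, 3060.0,
)


def default_axis(low: float = 400.0, high: float = 3200.0, step: float = 1.0) -> np.ndarray:
    """Default wavenumber grid, 400–3200 cm⁻¹ at 1 cm⁻¹."""
    return np.arange(low, high + 0.5 * step, step)


@dataclass(frozen=True)
class ClassProfile:
    """Peak table of one class: (center cm⁻¹, half-width γ cm⁻¹, amplitude)."""

    class_name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for c, g, a in self.peaks:
            if g <= 0 or a < 0:
                raise ValueError("peak width must be > 0 and amplitude >= 0")

    def clean_signal(self, axis: np.ndarray) -> np.ndarray:
        """Noise-free Lorentzian sum A·γ²/((x−c)²+γ²) over the peak table."""
        y = np.zeros_like(axis, dtype=float)
        for c, g, a in self.peaks:
            y += a * g * g / ((axis - c) ** 2 + g * g)
        return y


@dataclass(frozen=True)
class NoiseModel:
    """Detector and background nuisance parameters.

    ``gaussian_sigma`` is in the same (arbitrary) intensity units as the peak
    amplitudes; peak amplitudes are O(1), so the default 0.05 gives a peak
    signal-to-noise around 20, typical of 5 s single-cell acquisitions.
    The baseline is a random polynomial of degree ≤ 3 whose coefficients are
    drawn uniformly within per-degree bounds; its magnitude is comparable to
    the peaks, as fluorescence backgrounds usually are.
    """

    gaussian_sigma: float = 0.05
    baseline_coeffs_range: tuple[tuple[float, float], ...] = (
        (0.5, 2.0),   # constant offset
        (-0.5, 0.5),  # linear
        (-0.5, 0.5),  # quadratic
        (-0.3, 0.3),  # cubic
    )
    cosmic_ray_rate: float = 0.1
    cosmic_ray_amplitude: float = 50.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.cosmic_ray_rate < 0 or self.cosmic_ray_amplitude < 0:
            raise ValueError("noise parameters must be non-negative")
        if len(self.baseline_coeffs_range) > 4:
            raise ValueError("baseline polynomial degree is capped at 3")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic dataset."""

    n_classes: int = 8
    n_per_class: int = 500
    axis: np.ndarray = field(default_factory=default_axis)
    seed: int = 0
    class_profiles: Optional[tuple[ClassProfile, ...]] = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    amplitude_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_classes < 2:
            raise ValueError("need n_per_class >= 1 and n_classes >= 2")
        if self.class_profiles is None:
            object.__setattr__(
                self,
                "class_profiles",
                tuple(make_default_profiles(self.n_classes, self.seed)),
            )
        if len(self.class_profiles) != self.n_classes:
            raise ValueError("n_classes must equal len(class_profiles)")


@dataclass
class SpectrumTruth:
    """Ground-truth decomposition of one rendered spectrum."""

    clean: np.ndarray
    baseline: np.ndarray
    noise: np.ndarray
    spikes: np.ndarray
    spike_channels: np.ndarray
    jitter: float

    def total(self) -> np.ndarray:
        return self.clean + self.baseline + self.noise + self.spikes


def make_default_profiles(n_classes: int, seed: int) -> list[ClassProfile]:
    """Reproducible peak tables: shared carotenoid triplet + distinct extras.

    Every profile carries the 1004/1157/1520 cm⁻¹ carotenoid bands; each
    class additionally receives 3–6 bands drawn without replacement from a
    fixed list of common microbial Raman bands, with the draw arranged so no
    two classes share the same extra-band set.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A55]))
    chosen: list[tuple[float, ...]] = []
    profiles: list[ClassProfile] = []
    for k in range(n_classes):
        for _ in range(1000):
            n_extra = int(rng.integers(3, 7))
            centers = tuple(
                sorted(rng.choice(_DISCRIMINATIVE_BANDS, size=n_extra, replace=False))
            )
            if centers not in chosen:
                break
        else:  # pragma: no cover - combinatorially unreachable for small n
            raise RuntimeError("could not find a distinct peak set")
        chosen.append(centers)
        peaks = [(c, 8.0, 1.0) for c in CAROTENOID_BANDS]
        for c in centers:
            amp = float(rng.uniform(0.4, 1.5))
            width = float(rng.uniform(6.0, 12.0))
            peaks.append((c, width, amp))
        profiles.append(ClassProfile(class_name=f"strain_{k}", peaks=tuple(peaks)))
    return profiles


def _spectrum_rng(cfg: GeneratorConfig, index: int) -> np.random.Generator:
    """Counter-based per-spectrum stream: order- and subset-independent."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, index]))


def render_spectrum(
    profile: ClassProfile,
    cfg: GeneratorConfig,
    stream: np.random.Generator,
    spectrum_id: str = "synthetic",
) -> tuple[Spectrum, SpectrumTruth]:
    """Render one spectrum from a class profile plus its truth record."""
    axis = np.asarray(cfg.axis, dtype=float)
    jitter = float(
        np.exp(stream.normal(0.0, cfg.amplitude_jitter)) if cfg.amplitude_jitter > 0 else 1.0
    )
    clean = profile.clean_signal(axis) * jitter

    x = (axis - axis.mean()) / max(np.ptp(axis), 1.0)
    coeffs = np.array(
        [stream.uniform(lo, hi) for lo, hi in cfg.noise.baseline_coeffs_range]
    )
    baseline = np.polynomial.polynomial.polyval(x, coeffs)

    noise = (
        stream.normal(0.0, cfg.noise.gaussian_sigma, size=axis.size)
        if cfg.noise.gaussian_sigma > 0
        else np.zeros_like(axis)
    )

    spikes = np.zeros_like(axis)
    n_spikes = int(stream.poisson(cfg.noise.cosmic_ray_rate)) if cfg.noise.cosmic_ray_rate > 0 else 0
    spike_channels = (
        stream.choice(axis.size, size=min(n_spikes, axis.size), replace=False)
        if n_spikes
        else np.empty(0, dtype=int)
    )
    for ch in spike_channels:
        spikes[ch] = cfg.noise.cosmic_ray_amplitude * max(cfg.noise.gaussian_sigma, 1e-3) * float(
            stream.uniform(0.5, 1.5)
        )

    truth = SpectrumTruth(
        clean=clean,
        baseline=baseline,
        noise=noise,
        spikes=spikes,
        spike_channels=np.sort(spike_channels),
        jitter=jitter,
    )
    return Spectrum(axis, truth.total(), id=spectrum_id), truth


def generate_dataset(cfg: GeneratorConfig) -> tuple[SpectrumSet, list[SpectrumTruth]]:
    """Render the full labeled dataset: n_classes × n_per_class spectra.

    Deterministic under (cfg, seed): each spectrum uses its own counter-keyed
    random stream, so generation order cannot change the output.
    """
    axis = np.asarray(cfg.axis, dtype=float)
    n_total = cfg.n_classes * cfg.n_per_class
    mat = np.empty((n_total, axis.size))
    labels = np.empty(n_total, dtype=int)
    ids = []
    truths: list[SpectrumTruth] = []
    i = 0
    for k, profile in enumerate(cfg.class_profiles):
        for j in range(cfg.n_per_class):
            stream = _spectrum_rng(cfg, i)
            sid = f"{profile.class_name}_{j}"
            spec, truth = render_spectrum(profile, cfg, stream, spectrum_id=sid)
            mat[i] = spec.intensities
            labels[i] = k
            ids.append(sid)
            truths.append(truth)
            i += 1
    sset = SpectrumSet(
        axis,
        mat,
        ids=ids,
        labels=labels,
        class_names=[p.class_name for p in cfg.class_profiles],
    )
    return sset, truths
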