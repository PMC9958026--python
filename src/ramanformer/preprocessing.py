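"""Three-step preprocessing of single-cell Raman spectra.

The chain — applied per spectrum, in order — is

1. **cosmic-ray removal**: channels whose second-difference robust z-score
   (median/MAD over the whole spectrum) exceeds a threshold are replaced by
   linear interpolation between the nearest unflagged neighbours;
2. **baseline correction**: an iterative modified polynomial fit
   (Lieber-style): fit a low-degree polynomial, clip intensities above the
   fit to the fit, refit until the fit stops moving — the final fit is the
   fluorescence background and is subtracted;
3. **min-max normalization**: an affine map of each spectrum onto a fixed
   range, [0, 1] by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "remove_cosmic_rays",
    "correct_baseline",
    "normalize_minmax",
    "preprocess",
]

logger = logging.getLogger(__name__)

# MAD → sigma for a normal distribution
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the preprocessing chain.

    Attributes
    ----------
    spike_zscore_threshold:
        Robust z-score of the second difference above which a channel is
        treated as a cosmic-ray hit.  Genuine Raman peaks are many channels
        wide on a 1 cm⁻¹ grid; 8 is conservative.
    spike_window:
        Odd neighbourhood size used when bridging flagged channels.
    poly_degree, poly_max_iter, poly_tol:
        Degree, iteration cap and relative-change stopping tolerance of the
        modified polynomial baseline fit.
    norm_low, norm_high:
        Target range of min-max normalization.
    """

    spike_zscore_threshold: float = 8.0
    spike_window: int = 5
    poly_degree: int = 5
    poly_max_iter: int = 100
    poly_tol: float = 1e-4
    norm_low: float = 0.0
    norm_high: float = 1.0

    def __post_init__(self) -> None:
        if self.norm_low >= self.norm_high:
            raise ValueError("norm_low must be < norm_high")
        if self.spike_window < 3 or self.spike_window % 2 == 0:
            raise ValueError("spike_window must be odd and >= 3")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if self.spike_zscore_threshold <= 0 or self.poly_tol <= 0:
            raise ValueError("thresholds must be positive")


def _flag_spikes(y: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of channels whose second difference is a robust outlier."""
    d2 = np.zeros_like(y)
    d2[1:-1] = y[2:] - 2.0 * y[1:-1] + y[:-2]
    med = np.median(d2)
    mad = np.median(np.abs(d2 - med))
    scale = _MAD_SCALE * mad
    if scale == 0.0:
        # flat spectrum apart from possible spikes: any nonzero curvature
        # channel is an outlier
        return np.abs(d2 - med) > 0
    return np.abs(d2 - med) / scale > threshold


def remove_cosmic_rays(s: Spectrum, cfg: PreprocessConfig | None = None) -> tuple[Spectrum, int]:
    """Detect and bridge cosmic-ray spikes in one spectrum.

    Returns the despiked spectrum and the number of channels replaced.
    A spike flagged by the second-difference test also flags its immediate
    neighbours within ``spike_window // 2`` channels when they too deviate,
    so multi-channel spikes are bridged as a block.
    """
    cfg = cfg or PreprocessConfig()
    y = s.intensities
    if y.size < cfg.spike_window:
        raise ValueError("spectrum shorter than spike_window")
    flagged = _flag_spikes(y, cfg.spike_zscore_threshold)
    if not flagged.any():
        return s, 0
    # the second difference of an isolated spike also fires on the two
    # neighbouring channels; keep only channels that are themselves extreme
    # relative to a local linear bridge
    idx = np.flatnonzero(flagged)
    keep = np.zeros_like(flagged)
    for i in idx:
        lo = max(i - cfg.spike_window // 2, 0)
        hi = min(i + cfg.spike_window // 2 + 1, y.size)
        window = np.concatenate([y[lo:i], y[i + 1 : hi]])
        if window.size == 0:
            keep[i] = True
            continue
        local = np.median(window)
        spread = _MAD_SCALE * np.median(np.abs(window - local))
        resid = abs(y[i] - local)
        keep[i] = resid > max(3.0 * spread, 1e-12)
    flagged = keep
    if flagged.all():
        raise ValueError("spectrum unrecoverable")
    if not flagged.any():
        return s, 0
    clean = ~flagged
    fixed = y.copy()
    fixed[flagged] = np.interp(
        s.axis[flagged], s.axis[clean], y[clean]
    )
    return Spectrum(s.axis, fixed, id=s.id), int(flagged.sum())


def _modpoly(axis: np.ndarray, y: np.ndarray, degree: int, max_iter: int, tol: float,
             iterates: list | None = None) -> np.ndarray:
    """Iterative modified polynomial fit; returns the baseline estimate.

    Points above the current fit are clipped to the fit before refitting, so
    the polynomial descends onto the background under the peaks.  The fitted
    baseline is pointwise non-increasing across iterations.
    """
    # orthonormal-ish scaling for conditioning
    x = (axis - axis.mean()) / max(np.ptp(axis), 1.0)
    design = np.vander(x, degree + 1, increasing=True)
    # hat matrix applied via precomputed pseudoinverse: fit = design @ pinv @ y
    pinv = np.linalg.pinv(design)
    work = y.astype(float).copy()
    fit = design @ (pinv @ work)
    scale = max(np.max(np.abs(y)), 1e-300)
    if iterates is not None:
        iterates.append(fit.copy())
    for _ in range(max_iter):
        work = np.minimum(work, fit)
        new_fit = design @ (pinv @ work)
        change = np.max(np.abs(new_fit - fit)) / scale
        fit = new_fit
        if iterates is not None:
            iterates.append(fit.copy())
        if change < tol:
            break
    else:
        logger.warning("baseline fit did not converge in %d iterations", max_iter)
    return fit


def correct_baseline(s: Spectrum, cfg: PreprocessConfig | None = None) -> tuple[Spectrum, Spectrum]:
    """Subtract the iteratively fitted polynomial background.

    Returns ``(corrected, baseline)`` with ``corrected + baseline == input``
    up to float round-off.
    """
    cfg = cfg or PreprocessConfig()
    if len(s) <= cfg.poly_degree + 1:
        raise ValueError("spectrum too short for polynomial degree")
    baseline = _modpoly(s.axis, s.intensities, cfg.poly_degree, cfg.poly_max_iter, cfg.poly_tol)
    corrected = s.intensities - baseline
    return Spectrum(s.axis, corrected, id=s.id), Spectrum(s.axis, baseline, id=f"{s.id}.baseline")


def normalize_minmax(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Affine map of the intensities onto [norm_low, norm_high]."""
    cfg = cfg or PreprocessConfig()
    lo, hi = s.intensities.min(), s.intensities.max()
    if hi == lo:
        raise ValueError("zero dynamic range")
    scaled = (s.intensities - lo) / (hi - lo)
    return Spectrum(
        s.axis, cfg.norm_low + scaled * (cfg.norm_high - cfg.norm_low), id=s.id
    )


def preprocess(sset: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """Full chain over a set: despike → baseline-correct → normalize each row."""
    cfg = cfg or PreprocessConfig()
    out = np.empty_like(sset.intensity_matrix)
    for i in range(sset.n_spectra):
        s = sset.spectrum(i)
        try:
            s, n_spikes = remove_cosmic_rays(s, cfg)
            s, _ = correct_baseline(s, cfg)
            s = normalize_minmax(s, cfg)
        except ValueError as exc:
            raise ValueError(f"spectrum {sset.ids[i]!r}: {exc}") from exc
        logger.debug("spectrum %s: %d cosmic-ray channels replaced", s.id, n_spikes)
        out[i] = s.intensities
    return SpectrumSet(
        sset.axis, out, ids=sset.ids, labels=sset.labels, class_names=sset.class_names
    )
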