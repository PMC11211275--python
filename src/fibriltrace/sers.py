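"""Preprocessing of surface-enhanced Raman spectra.

The pipeline mirrors the standard protocol for SERS spectra of protein
aggregates: replicate averaging, cosmic-ray despiking, Savitzky-Golay
smoothing, polynomial baseline subtraction with the analyte band regions
excluded from the baseline fit, and normalization to unit spectral area.
All operations are pure: they return new :class:`RamanSpectrum` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

__all__ = [
    "RamanSpectrum",
    "PreprocessConfig",
    "calibrate_shift_axis",
    "despike",
    "smooth",
    "subtract_baseline",
    "normalize_to_area",
    "preprocess",
    "preprocess_and_average",
]


@dataclass(frozen=True)
class RamanSpectrum:
    """A single Raman/SERS spectrum on a strictly ascending shift axis.

    Parameters
    ----------
    shift : array of Raman shifts in cm^-1, strictly increasing, uniform step.
    intensity : array of intensities (counts or normalized units), same length.
    """

    shift: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        shift = np.asarray(self.shift, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if shift.ndim != 1 or intensity.ndim != 1:
            raise ValueError("shift and intensity must be 1-D arrays")
        if shift.size != intensity.size:
            raise ValueError(
                f"length mismatch: {shift.size} shifts vs {intensity.size} intensities"
            )
        if shift.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(shift) > 0):
            raise ValueError("shift axis must be strictly increasing")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "shift", shift)
        object.__setattr__(self, "intensity", intensity)

    @property
    def step(self) -> float:
        """Median axis step in cm^-1 (the axis is nominally uniform)."""
        return float(np.median(np.diff(self.shift)))

    def crop(self, lo: float, hi: float) -> "RamanSpectrum":
        """Return the sub-spectrum with lo <= shift <= hi."""
        sel = (self.shift >= lo) & (self.shift <= hi)
        if sel.sum() < 2:
            raise ValueError(f"window ({lo}, {hi}) cm^-1 contains <2 samples")
        return RamanSpectrum(self.shift[sel], self.intensity[sel])

    def with_intensity(self, intensity: np.ndarray) -> "RamanSpectrum":
        return RamanSpectrum(self.shift, intensity)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    ``baseline_exclusion`` lists (lo, hi) cm^-1 windows that are *excluded*
    from the polynomial baseline fit; by default these cover the aromatic
    region, the CH deformation region, and the amide I/II region so that
    analyte bands do not bias the baseline.
    """

    si_reference: float = 520.8  # first-order Si phonon line, cm^-1
    despike_window: int = 5
    despike_z: float = 8.0  # threshold in robust (MAD-based) sd units
    smooth_window: int = 11
    smooth_polyorder: int = 3
    baseline_degree: int = 3
    baseline_exclusion: Tuple[Tuple[float, float], ...] = (
        (980.0, 1120.0),
        (1330.0, 1480.0),
        (1540.0, 1800.0),
    )

    def __post_init__(self) -> None:
        if self.despike_window < 3 or self.despike_window % 2 == 0:
            raise ValueError("despike_window must be odd and >= 3")
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        if self.smooth_polyorder >= self.smooth_window:
            raise ValueError("smooth_polyorder must be < smooth_window")
        if self.baseline_degree < 0:
            raise ValueError("baseline_degree must be >= 0")


def calibrate_shift_axis(
    s: RamanSpectrum, measured_si_peak: float, cfg: PreprocessConfig = PreprocessConfig()
) -> RamanSpectrum:
    """Shift the wavenumber axis so the silicon reference lands at 520.8 cm^-1.

    The offset (reference - measured) is added to every shift; intensities
    are untouched.
    """
    if not np.isfinite(measured_si_peak):
        raise ValueError("measured Si peak position must be finite")
    offset = cfg.si_reference - float(measured_si_peak)
    return RamanSpectrum(s.shift + offset, s.intensity)


def despike(s: RamanSpectrum, cfg: PreprocessConfig = PreprocessConfig()) -> RamanSpectrum:
    """Replace cosmic-ray spikes by the running median.

    A bin is a spike when its deviation from the running median exceeds
    ``despike_z`` robust standard deviations (1.4826 * MAD of the residual).
    """
    if cfg.despike_window > s.shift.size:
        raise ValueError("despike window longer than spectrum")
    running = median_filter(s.intensity, size=cfg.despike_window, mode="nearest")
    resid = s.intensity - running
    sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if sd == 0.0:
        # no noise scale to compare against (noise-free spectrum): leave as is
        return s
    spikes = np.abs(resid) > cfg.despike_z * sd
    out = s.intensity.copy()
    out[spikes] = running[spikes]
    return s.with_intensity(out)


def smooth(s: RamanSpectrum, cfg: PreprocessConfig = PreprocessConfig()) -> RamanSpectrum:
    """Savitzky-Golay smoothing with polynomial end-point extension."""
    if cfg.smooth_window > s.shift.size:
        raise ValueError("smoothing window longer than spectrum")
    out = savgol_filter(
        s.intensity, cfg.smooth_window, cfg.smooth_polyorder, mode="interp"
    )
    return s.with_intensity(out)


def _baseline_mask(shift: np.ndarray, exclusion: Sequence[Tuple[float, float]]) -> np.ndarray:
    mask = np.ones_like(shift, dtype=bool)
    for lo, hi in exclusion:
        mask &= ~((shift >= lo) & (shift <= hi))
    return mask


def subtract_baseline(
    s: RamanSpectrum, cfg: PreprocessConfig = PreprocessConfig()
) -> RamanSpectrum:
    """Fit and subtract a polynomial baseline.

    The polynomial (degree ``baseline_degree``) is least-squares fitted to
    the bins *outside* the exclusion windows and subtracted everywhere.
    """
    mask = _baseline_mask(s.shift, cfg.baseline_exclusion)
    if mask.sum() < cfg.baseline_degree + 1:
        raise ValueError(
            "insufficient baseline bins after exclusion "
            f"({int(mask.sum())} left, need {cfg.baseline_degree + 1})"
        )
    poly = np.polynomial.Polynomial.fit(
        s.shift[mask], s.intensity[mask], deg=cfg.baseline_degree
    )
    return s.with_intensity(s.intensity - poly(s.shift))


def normalize_to_area(s: RamanSpectrum) -> RamanSpectrum:
    """Divide intensities by the trapezoidal integral over the full axis.

    The output integrates to exactly 1. Degenerate spectra (zero, negative
    or non-finite integral) are rejected.
    """
    area = float(np.trapezoid(s.intensity, s.shift))
    if not np.isfinite(area) or area <= 0.0:
        raise ValueError(f"degenerate spectrum: spectral area {area!r}")
    return s.with_intensity(s.intensity / area)


def preprocess(s: RamanSpectrum, cfg: PreprocessConfig = PreprocessConfig()) -> RamanSpectrum:
    """Despike -> smooth -> baseline-subtract -> area-normalize one spectrum."""
    return normalize_to_area(subtract_baseline(smooth(despike(s, cfg), cfg), cfg))


def preprocess_and_average(
    replicates: Iterable[RamanSpectrum], cfg: PreprocessConfig = PreprocessConfig()
) -> RamanSpectrum:
    """Average replicate spectra bin-wise, then run the correction pipeline.

    The replicates must share one axis. The order (average first, then
    despike, smooth, baseline, normalize) follows the acquisition protocol.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("no replicate spectra given")
    axis = replicates[0].shift
    for r in replicates[1:]:
        if r.shift.size != axis.size or not np.allclose(r.shift, axis):
            raise ValueError("replicates do not share a common shift axis")
    mean = RamanSpectrum(axis, np.mean([r.intensity for r in replicates], axis=0))
    return preprocess(mean, cfg)
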