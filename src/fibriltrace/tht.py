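"""Thioflavin T aggregation kinetics.

ThT fluorescence rises when the dye binds cross-beta amyloid structure, so a
plate-reader trace of an aggregating sample follows the canonical sigmoid
with lag, exponential (elongation) and plateau phases. Traces are fitted
with a Boltzmann sigmoid

    F(t) = F0 + (Fmax - F0) / (1 + exp(-k (t - t_half)))

and phase boundaries are derived with the symmetric tangent-line convention:
the exponential phase begins at t_half - 2/k and the plateau at t_half + 2/k.

Times are minutes in traces/files and hours in all kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceTrace",
    "SigmoidFit",
    "PhaseOnsets",
    "boltzmann",
    "fit_sigmoid",
    "phase_onsets",
    "aggregate_wells",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """One well's fluorescence trace; time in minutes, intensity in a.u."""

    time: np.ndarray
    intensity: np.ndarray
    well_id: str = ""
    is_control: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.size != y.size:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly ascending")
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)

    @property
    def time_hours(self) -> np.ndarray:
        return self.time / 60.0


@dataclass(frozen=True)
class SigmoidFit:
    """Boltzmann sigmoid parameters; k in 1/h, t_half in h."""

    F0: float
    Fmax: float
    k: float
    t_half: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class PhaseOnsets:
    """Exponential-phase and plateau onset times in hours."""

    t_exponential: float
    t_plateau: float

    def __post_init__(self) -> None:
        if not self.t_exponential < self.t_plateau:
            raise ValueError("t_exponential must precede t_plateau")


def boltzmann(t_hours: np.ndarray, F0: float, Fmax: float, k: float, t_half: float) -> np.ndarray:
    """The Boltzmann sigmoid evaluated at times in hours."""
    return F0 + (Fmax - F0) / (1.0 + np.exp(-k * (np.asarray(t_hours, dtype=float) - t_half)))


def fit_sigmoid(trace: FluorescenceTrace) -> SigmoidFit:
    """Least-squares Boltzmann fit of one trace.

    Initial values come from the data: F0 = mean of the first decile,
    Fmax = mean of the last decile, t_half = first half-range crossing.
    Traces whose relative amplitude (Fmax - F0) / F0 is below 0.2 are
    flagged as non-aggregating (control-like) with ``converged=False``
    and are not fitted.
    """
    t = trace.time_hours
    y = trace.intensity
    if t.size < 20:
        raise ValueError("need at least 20 samples to fit a sigmoid")
    if t[-1] - t[0] <= 1.0:
        raise ValueError("trace must span more than 1 h")

    n10 = max(t.size // 10, 1)
    f0 = float(np.mean(y[:n10]))
    fmax = float(np.mean(y[-n10:]))
    if f0 <= 0 or (fmax - f0) / abs(f0) < 0.2:
        return SigmoidFit(F0=f0, Fmax=fmax, k=np.nan, t_half=np.nan,
                          rss=float(np.sum((y - np.mean(y)) ** 2)), converged=False)

    half_level = f0 + 0.5 * (fmax - f0)
    above = np.nonzero(y >= half_level)[0]
    t_half0 = float(t[above[0]]) if above.size else float(np.median(t))
    k0 = 4.0 / max((t[-1] - t[0]) / 4.0, 1e-3)

    try:
        popt, _ = curve_fit(
            boltzmann,
            t,
            y,
            p0=[f0, fmax, k0, t_half0],
            bounds=([-np.inf, -np.inf, 1e-6, t[0] - (t[-1] - t[0])],
                    [np.inf, np.inf, np.inf, t[-1] + (t[-1] - t[0])]),
            maxfev=20000,
        )
    except RuntimeError:
        return SigmoidFit(F0=f0, Fmax=fmax, k=np.nan, t_half=np.nan,
                          rss=np.inf, converged=False)
    resid = y - boltzmann(t, *popt)
    return SigmoidFit(
        F0=float(popt[0]),
        Fmax=float(popt[1]),
        k=float(popt[2]),
        t_half=float(popt[3]),
        rss=float(np.sum(resid**2)),
        converged=True,
    )


def phase_onsets(fit: SigmoidFit) -> PhaseOnsets:
    """Phase boundaries t_half -/+ 2/k (hours) from a converged fit."""
    if not fit.converged:
        raise ValueError("phase onsets require a converged sigmoid fit")
    return PhaseOnsets(fit.t_half - 2.0 / fit.k, fit.t_half + 2.0 / fit.k)


class WellAggregate(NamedTuple):
    mean: FluorescenceTrace
    controls: List[FluorescenceTrace]


def aggregate_wells(traces: Iterable[FluorescenceTrace]) -> WellAggregate:
    """Sample-wise mean over non-control wells; controls returned alongside.

    Control (buffer-only) wells are excluded from the mean but never
    subtracted from it.
    """
    traces = list(traces)
    samples = [tr for tr in traces if not tr.is_control]
    controls = [tr for tr in traces if tr.is_control]
    if not samples:
        raise ValueError("no non-control traces to aggregate")
    grid = samples[0].time
    for tr in samples[1:]:
        if tr.time.size != grid.size or not np.allclose(tr.time, grid):
            raise ValueError("sample wells do not share a common time grid")
    mean = FluorescenceTrace(
        time=grid,
        intensity=np.mean([tr.intensity for tr in samples], axis=0),
        well_id="mean",
        is_control=False,
    )
    return WellAggregate(mean=mean, controls=controls)
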