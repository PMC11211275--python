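"""Amide I band deconvolution into secondary-structure components.

The amide I region (1590-1720 cm^-1, dominated by backbone C=O stretching)
is fitted with a sum of pseudo-Voigt (Gauss-Lorentz) components: three
structure bands near 1650 (alpha-helix), 1670 (beta-sheet) and 1680 cm^-1
(random coil), plus an optional aromatic (Phe/Tyr) band near 1592 cm^-1
that overlaps the window edge but carries no structural information.
Percentage structure fractions are the relative *areas* of the three
structure components; the aromatic band is excluded from both numerator
and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import lmfit
import numpy as np

from .sers import RamanSpectrum

__all__ = [
    "BandComponent",
    "AmideBandModel",
    "AmideFitResult",
    "pseudo_voigt",
    "fit_amide_band",
    "structure_fractions",
]

_STRUCTURES = ("alpha", "beta", "coil")


@dataclass(frozen=True)
class BandComponent:
    """One spectral band: unit-area pseudo-Voigt scaled by ``area``.

    ``eta`` is the Lorentzian mixing fraction (0 = pure Gaussian,
    1 = pure Lorentzian); Gaussian and Lorentzian parts share the FWHM.
    """

    center: float  # cm^-1
    fwhm: float  # cm^-1
    eta: float  # Lorentzian fraction in [0, 1]
    area: float  # integrated intensity

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.area < 0:
            raise ValueError("area must be >= 0")


def pseudo_voigt(x: np.ndarray, c: BandComponent) -> np.ndarray:
    """Evaluate an area-normalized pseudo-Voigt band scaled by its area.

    Returns ``area * [eta * L + (1 - eta) * G]`` where L and G are
    unit-area Lorentzian and Gaussian profiles sharing center and FWHM,
    so the integral over the whole real line equals ``area``.
    """
    x = np.asarray(x, dtype=float)
    return _pv(x, c.center, c.fwhm, c.eta, c.area)


def _pv(x, center, fwhm, eta, area):
    gamma = fwhm / 2.0
    lorentz = gamma / (np.pi * ((x - center) ** 2 + gamma**2))
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return area * (eta * lorentz + (1.0 - eta) * gauss)


@dataclass(frozen=True)
class AmideBandModel:
    """Model configuration for the amide I fit.

    ``initial_centers`` maps structure labels to starting band positions;
    the fitted centers are confined to a +/- ``center_bound`` box around
    them, which keeps the heavily overlapping components from swapping
    roles during optimisation.

    With ``share_eta`` and ``share_fwhm`` (both on by default) the three
    structure bands form a single line-shape family: one Gauss/Lorentz
    mixing fraction and one intrinsic width, fitted jointly. The 1670 and
    1680 cm^-1 bands are separated by barely half their width, and with
    fully independent shapes the area decomposition is a degenerate
    inverse problem -- a narrow small band plus a wide large one fits the
    data as well as the truth, so small noise produces large swings in the
    beta/coil split. Amide I sub-bands arise from one backbone C=O mode,
    so a common intrinsic line shape is the physically motivated
    constraint; set both flags to False for fully independent components.

    ``fit_offset`` adds a linear intercept+slope term over the window to
    absorb residual baseline left by the global polynomial subtraction
    (the Lorentzian wings of strong bands bias any finite-degree
    baseline); it is excluded from the component areas.
    """

    window: Tuple[float, float] = (1590.0, 1720.0)
    initial_centers: Tuple[float, float, float] = (1650.0, 1670.0, 1680.0)
    include_aromatic: bool = True
    aromatic_center: float = 1592.0
    center_bound: float = 8.0  # +/- box around initial centers, cm^-1
    fwhm_bounds: Tuple[float, float] = (5.0, 60.0)
    initial_fwhm: float = 18.0
    initial_eta: float = 0.5
    share_eta: bool = True
    share_fwhm: bool = True
    fit_offset: bool = True
    center_jitter: float = 3.0  # multi-start uniform jitter on centers, cm^-1

    def component_names(self) -> Tuple[str, ...]:
        names = list(_STRUCTURES)
        if self.include_aromatic:
            names.append("aromatic")
        return tuple(names)


@dataclass(frozen=True)
class AmideFitResult:
    """Fitted amide I components and derived structure fractions."""

    components: Dict[str, BandComponent]
    fractions: Tuple[float, float, float]  # (alpha %, beta %, coil %)
    residual_rms: float
    converged: bool
    n_starts_used: int

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


def _model_eval(params: lmfit.Parameters, x: np.ndarray, names, x_mid: float) -> np.ndarray:
    out = np.zeros_like(x)
    if "offset_const" in params:
        out += params["offset_const"].value + params["offset_slope"].value * (x - x_mid)
    for n in names:
        out += _pv(
            x,
            params[f"{n}_center"].value,
            params[f"{n}_fwhm"].value,
            params[f"{n}_eta"].value,
            params[f"{n}_area"].value,
        )
    return out


def _make_params(model: AmideBandModel, centers: Dict[str, float], area0: float) -> lmfit.Parameters:
    params = lmfit.Parameters()
    names = model.component_names()
    if model.share_eta:
        params.add("eta_shared", value=model.initial_eta, min=0.0, max=1.0)
    if model.share_fwhm:
        params.add(
            "fwhm_shared",
            value=model.initial_fwhm,
            min=model.fwhm_bounds[0],
            max=model.fwhm_bounds[1],
        )
    if model.fit_offset:
        params.add("offset_const", value=0.0)
        params.add("offset_slope", value=0.0)
    for n in names:
        c0 = centers[n]
        init = model.initial_centers[_STRUCTURES.index(n)] if n in _STRUCTURES else model.aromatic_center
        params.add(f"{n}_center", value=c0, min=init - model.center_bound, max=init + model.center_bound)
        if model.share_fwhm and n in _STRUCTURES:
            params.add(f"{n}_fwhm", expr="fwhm_shared")
        else:
            params.add(f"{n}_fwhm", value=model.initial_fwhm, min=model.fwhm_bounds[0], max=model.fwhm_bounds[1])
        if model.share_eta and n in _STRUCTURES:
            params.add(f"{n}_eta", expr="eta_shared")
        else:
            params.add(f"{n}_eta", value=model.initial_eta, min=0.0, max=1.0)
        a0 = area0 / len(names) if n in _STRUCTURES else area0 / (4 * len(names))
        params.add(f"{n}_area", value=max(a0, 1e-12), min=0.0)
    return params


def fit_amide_band(
    s: RamanSpectrum,
    model: AmideBandModel = AmideBandModel(),
    n_starts: int = 10,
    seed: int = 0,
) -> AmideFitResult:
    """Multi-start bounded least-squares fit of the amide I window.

    The spectrum should already be baseline-subtracted and area-normalized.
    Starting centers are jittered uniformly (+/- ``center_jitter`` cm^-1)
    across restarts; the fit with the lowest residual sum of squares wins.
    Structure labels are reassigned to fitted components by ascending
    center, which enforces center(alpha) < center(beta) < center(coil).
    If no start converges, the best-effort parameters are returned with
    ``converged=False`` rather than raising.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = model.window
    win = s.crop(lo, hi)
    x, y = win.shift, win.intensity
    names = model.component_names()
    area0 = max(float(np.trapezoid(np.clip(y, 0, None), x)), 1e-12)
    x_mid = float(x.mean())

    rng = np.random.default_rng(seed)
    best = None
    best_rss = np.inf
    any_converged = False
    n_used = 0

    def residual(params):
        return _model_eval(params, x, names, x_mid) - y

    for start in range(n_starts):
        centers = {}
        for n in names:
            init = (
                model.initial_centers[_STRUCTURES.index(n)]
                if n in _STRUCTURES
                else model.aromatic_center
            )
            jit = 0.0 if start == 0 else rng.uniform(-model.center_jitter, model.center_jitter)
            centers[n] = float(np.clip(init + jit, init - model.center_bound, init + model.center_bound))
        params = _make_params(model, centers, area0)
        n_used = start + 1
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if rss < best_rss:
            best_rss = rss
            best = res
            any_converged = any_converged or bool(res.success)
        # a near-perfect fit: no need for more restarts
        if rss < (1e-10 * max(np.abs(y).max(), 1.0)) ** 2 * y.size:
            break

    if best is None:  # every start blew up (pathological input)
        raise RuntimeError("amide I fit failed on every start")

    p = best.params
    fitted = {
        n: BandComponent(
            center=float(p[f"{n}_center"].value),
            fwhm=float(p[f"{n}_fwhm"].value),
            eta=float(p[f"{n}_eta"].value),
            area=float(p[f"{n}_area"].value),
        )
        for n in names
    }
    # relabel structure components by ascending fitted center
    structure = sorted((fitted[n] for n in _STRUCTURES), key=lambda c: c.center)
    components = dict(zip(_STRUCTURES, structure))
    if model.include_aromatic:
        components["aromatic"] = fitted["aromatic"]

    rms = float(np.sqrt(best_rss / x.size))
    result = AmideFitResult(
        components=components,
        fractions=_fractions_from_components(components),
        residual_rms=rms,
        converged=any_converged,
        n_starts_used=n_used,
    )
    return result


def _fractions_from_components(components: Dict[str, BandComponent]) -> Tuple[float, float, float]:
    areas = np.array([components[n].area for n in _STRUCTURES], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all structure areas are zero; fractions undefined")
    f = 100.0 * areas / total
    return (float(f[0]), float(f[1]), float(f[2]))


def structure_fractions(r: AmideFitResult) -> Tuple[float, float, float]:
    """Percentage (alpha, beta, coil) contributions to the amide I band.

    Computed from component areas; the aromatic component, if fitted, is
    excluded. Always sums to 100.
    """
    return _fractions_from_components(r.components)
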